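"""NMF consensus clustering of the peritumor differential proteome.

Repeated seeded non-negative matrix factorizations assign each peritumor
sample to its dominant metagene; the co-assignment frequencies across
restarts form a per-k consensus matrix.  Cluster-number selection maximizes
the cophenetic correlation of the consensus matrices (the CDF area and its
increments are reported alongside), and final subtype labels come from
average-linkage hierarchical clustering of the consensus dissimilarity.  A
"weak structure" flag is raised when the chosen consensus is dominated by
ambiguous co-assignment frequencies, as happens on structure-free input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform

from . import stats as core
from .containers import ClinicalTable

__all__ = ["nmf_factorize", "consensus_cluster", "subtype_feature_tests", "ConsensusResult"]

#: Consensus entries inside this open interval count as ambiguous (PAC score).
PAC_BOUNDS = (0.1, 0.9)
WEAK_PAC_THRESHOLD = 0.3


def nmf_factorize(
    V: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 2000,
    tol: float = 1e-6,
    objective: str = "frobenius",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Multiplicative-update NMF: V (m x n) ~ W (m x k) @ H (k x n).

    Initialization is uniform(0, 1] scaled to the data magnitude and is
    deterministic given ``seed``.  Iteration stops when the relative change
    of the reconstruction error drops below ``tol`` or after ``max_iter``
    updates.  ``objective`` is ``"frobenius"`` (default) or ``"kl"``
    (generalized Kullback-Leibler divergence).
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a matrix")
    if np.any(V < 0) or np.isnan(V).any():
        raise ValueError("V must be non-negative with no missing entries")
    m, n = V.shape
    if not (1 <= k < min(m, n)):
        raise ValueError("k must satisfy 1 <= k < min(V.shape)")
    if objective not in ("frobenius", "kl"):
        raise ValueError(f"unknown objective: {objective!r}")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(V.mean(), np.finfo(float).tiny) / k)
    # uniform on (0, 1] so no factor entry starts at exactly zero
    W = scale * (1.0 - rng.random((m, k)))
    H = scale * (1.0 - rng.random((k, n)))
    eps = np.finfo(float).eps

    def frob_error():
        return float(np.linalg.norm(V - W @ H))

    def kl_error():
        WH = np.maximum(W @ H, eps)
        Vp = np.maximum(V, eps)
        return float(np.sum(V * np.log(Vp / WH) - V + WH))

    error = frob_error() if objective == "frobenius" else kl_error()
    for _ in range(max_iter):
        if objective == "frobenius":
            H *= (W.T @ V) / np.maximum(W.T @ W @ H, eps)
            W *= (V @ H.T) / np.maximum(W @ (H @ H.T), eps)
            new_error = frob_error()
        else:
            WH = np.maximum(W @ H, eps)
            H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], eps)
            WH = np.maximum(W @ H, eps)
            W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], eps)
            new_error = kl_error()
        if error > 0 and (error - new_error) / error < tol:
            error = new_error
            break
        error = new_error
    return W, H, error


@dataclass
class ConsensusResult:
    """Per-k consensus clustering summary and the selected subtype labels."""

    k_range: tuple[int, ...]
    consensus: dict[int, np.ndarray]
    cophenetic: dict[int, float]
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    pac: dict[int, float]
    best_error: dict[int, float]
    chosen_k: int
    labels: pd.Series                 # subtype (1..chosen_k) per sample
    weak_structure: bool
    n_runs: int
    seed: int

    def sizes(self) -> dict[int, int]:
        return self.labels.value_counts().sort_index().to_dict()


def _consensus_summary(C: np.ndarray) -> tuple[np.ndarray, float]:
    """Average linkage of the consensus dissimilarity + cophenetic correlation."""
    dist = squareform(1.0 - C, checks=False)
    link = average(dist)
    if np.allclose(dist, dist[0]):
        return link, 0.0
    coph, _ = cophenet(link, dist)
    return link, float(coph)


def _cdf_area(C: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    entries = np.sort(squareform(C, checks=False))
    n = entries.size
    grid = np.r_[entries, 1.0]
    cdf = np.arange(1, n + 1) / n
    return float(np.sum(np.diff(grid) * cdf))


def consensus_cluster(
    V: np.ndarray,
    sample_ids,
    k_range=(2, 3, 4, 5, 6),
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    objective: str = "frobenius",
) -> ConsensusResult:
    """Consensus NMF over ``k_range`` with ``n_runs`` seeded restarts per k.

    Each run assigns every sample to the metagene with the largest H entry;
    the consensus matrix is the co-assignment frequency across runs.
    ``chosen_k`` maximizes the cophenetic correlation; CDF areas and their
    increments are reported so the alternative selection convention can be
    applied by the caller.
    """
    V = np.asarray(V, dtype=float)
    n = V.shape[1]
    if len(sample_ids) != n:
        raise ValueError("sample_ids must match the number of columns of V")
    k_range = tuple(int(k) for k in k_range)
    if any(k < 2 or k >= min(V.shape) for k in k_range):
        raise ValueError("every k must satisfy 2 <= k < min(V.shape)")

    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs * len(k_range)) % (2**31)
    consensus: dict[int, np.ndarray] = {}
    cophenetic: dict[int, float] = {}
    cdf_area: dict[int, float] = {}
    pac: dict[int, float] = {}
    best_error: dict[int, float] = {}
    links: dict[int, np.ndarray] = {}

    for ki, k in enumerate(k_range):
        co = np.zeros((n, n))
        errors = []
        for r in range(n_runs):
            s = int(run_seeds[ki * n_runs + r])
            _, H, err = nmf_factorize(V, k, seed=s, max_iter=max_iter, objective=objective)
            errors.append(err)
            assign = np.argmax(H, axis=0)
            co += assign[:, None] == assign[None, :]
        C = co / n_runs
        np.fill_diagonal(C, 1.0)
        consensus[k] = C
        links[k], cophenetic[k] = _consensus_summary(C)
        cdf_area[k] = _cdf_area(C)
        off = squareform(C, checks=False)
        pac[k] = float(np.mean((off > PAC_BOUNDS[0]) & (off < PAC_BOUNDS[1])))
        best_error[k] = float(min(errors))

    ks = sorted(k_range)
    delta_area = {ks[0]: cdf_area[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        denom = cdf_area[prev]
        delta_area[k] = (cdf_area[k] - denom) / denom if denom > 0 else 0.0

    chosen_k = max(k_range, key=lambda k: (cophenetic[k], -k))
    labels = fcluster(links[chosen_k], t=chosen_k, criterion="maxclust")
    weak = pac[chosen_k] > WEAK_PAC_THRESHOLD
    return ConsensusResult(
        k_range=k_range,
        consensus=consensus,
        cophenetic=cophenetic,
        cdf_area=cdf_area,
        delta_area=delta_area,
        pac=pac,
        best_error=best_error,
        chosen_k=int(chosen_k),
        labels=pd.Series(labels, index=list(sample_ids), name="subtype"),
        weak_structure=bool(weak),
        n_runs=n_runs,
        seed=seed,
    )


def subtype_feature_tests(
    labels: pd.Series,
    clinical: ClinicalTable,
    risk_profiles: pd.DataFrame | None = None,
    numeric_features=("survival_days", "cyp2e1_activity", "afp_ng_ml"),
    categorical_features=("cirrhosis_stage", "multiple_tumors"),
    min_group: int = 2,
) -> pd.DataFrame:
    """Compare clinical covariates and category risk indices across subtypes.

    Numeric features use one-way ANOVA when a Levene test accepts variance
    homogeneity (p > 0.05) and Kruskal-Wallis otherwise; categorical
    features use a chi-square test of the subtype x level table.  Subtypes
    with fewer than ``min_group`` samples are excluded.
    """
    counts = labels.value_counts()
    valid = counts[counts >= min_group].index
    if len(valid) < 2:
        raise ValueError("need at least two subtypes with enough samples")
    lab = labels[labels.isin(valid)]

    feature_values: dict[str, pd.Series] = {}
    clin = clinical.df.set_index("sample_id")
    for feat in numeric_features:
        if feat in clin.columns:
            feature_values[feat] = clin[feat].reindex(lab.index)
    if risk_profiles is not None:
        rp = risk_profiles.set_index("sample_id")
        for col in rp.columns:
            if (col.startswith("ri_") and col != "ri_group") or col == "total_ri":
                feature_values[col] = rp[col].reindex(lab.index)

    rows = []
    for feat, series in feature_values.items():
        groups = [
            series[lab == s].dropna().to_numpy(dtype=float) for s in sorted(valid)
        ]
        groups = [g for g in groups if g.size >= min_group]
        if len(groups) < 2:
            continue
        if all(np.ptp(g) == 0 for g in groups):
            # every subtype is internally constant: either no signal at all or
            # a feature that is an exact function of the label
            means = {float(g[0]) for g in groups}
            test, p = "degenerate", (1.0 if len(means) == 1 else 0.0)
        else:
            levene_p = sps.levene(*groups).pvalue
            if levene_p > 0.05:
                test, p = "anova", float(sps.f_oneway(*groups).pvalue)
            else:
                test, p = "kruskal", float(sps.kruskal(*groups).pvalue)
        rows.append(
            {
                "feature": feat,
                "test": test,
                "p_value": p,
                **{
                    f"mean_s{s}": float(series[lab == s].dropna().mean())
                    for s in sorted(valid)
                },
            }
        )

    for feat in categorical_features:
        if feat not in clin.columns:
            continue
        series = clin[feat].reindex(lab.index).dropna()
        if series.nunique() < 2:
            continue
        table = pd.crosstab(lab.loc[series.index], series).to_numpy()
        table = table[:, table.sum(axis=0) > 0]
        table = table[table.sum(axis=1) > 0]
        if min(table.shape) < 2:
            continue
        _, _, p = core.chi_square_test(table)
        rows.append({"feature": feat, "test": "chi_square", "p_value": float(p)})

    return pd.DataFrame(rows)
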