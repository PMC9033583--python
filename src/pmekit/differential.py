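"""Two-group differential expression between normal and peritumor tissue.

Significance follows the study rule: a linear fold change beyond 1.2 in
either direction together with an unadjusted two-sided P < 0.05.  Both a
plain equal-variance Student t test and an empirical-Bayes moderated t
(variance shrinkage toward a pooled prior, method-of-moments hyperparameters)
are provided; Benjamini-Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import AbundanceMatrix, ClinicalTable

__all__ = ["count_identified", "differential_test", "volcano_table"]

DEFAULT_FC = 1.2
DEFAULT_P = 0.05


def count_identified(m: AbundanceMatrix, clinical: ClinicalTable) -> tuple[pd.DataFrame, float]:
    """Per-sample detected-protein counts and a two-group Student t comparison.

    Expects the pre-imputation matrix (missingness intact).
    """
    counts = m.data.notna().sum(axis=0)
    groups = {s: g for s, g in zip(clinical.df["sample_id"], clinical.df["group"])}
    table = pd.DataFrame(
        {
            "sample_id": counts.index,
            "n_identified": counts.to_numpy(),
            "group": [groups[s] for s in counts.index],
        }
    )
    a = table.loc[table["group"] == "normal", "n_identified"].to_numpy(dtype=float)
    b = table.loc[table["group"] == "peritumor", "n_identified"].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be present to compare identified counts")
    p = float(sps.ttest_ind(a, b, equal_var=True).pvalue)
    return table, p


def _moment_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Under the hierarchical model s^2 / s0^2 ~ F(df, d0); solve d0 and s0^2
    from the sample mean and variance of the per-protein variances.
    """
    s2 = s2[s2 > 0]
    m = s2.mean()
    v = s2.var(ddof=1)
    if m == 0 or v == 0:
        return 1e6, float(m)
    ratio = v / m**2
    denom = ratio * df - 2.0
    if denom <= 0:
        d0 = 1e6
    else:
        d0 = (2.0 * df - 4.0 + 4.0 * ratio * df) / denom
        d0 = float(np.clip(d0, 1.0, 1e6))
    s0_sq = m * (d0 - 2.0) / d0 if d0 > 2 else m
    return d0, float(s0_sq)


def differential_test(
    m: AbundanceMatrix,
    clinical: ClinicalTable,
    method: str = "student",
    fc_threshold: float = DEFAULT_FC,
    p_threshold: float = DEFAULT_P,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-protein differential test on a preprocessed log2 matrix.

    Returns one row per protein: linear fold change (peritumor / normal group
    means on the linear scale), log2fc, two-sided p, direction, and the
    significance call ``(fc > fc_threshold or fc < 1/fc_threshold) and
    p < p_threshold``.  ``method`` is ``"student"`` (equal-variance t) or
    ``"moderated"`` (empirical-Bayes shrunk variance).  With ``adjust=True``
    the p used for the call is Benjamini-Hochberg adjusted.
    """
    if m.scale != "log2":
        raise ValueError("differential test expects a log2-scale matrix")
    labels = clinical.group_labels(m.sample_ids)
    n1 = int(labels.sum())        # peritumor
    n0 = labels.size - n1         # normal
    if n0 < 2 or n1 < 2:
        raise ValueError("both groups need at least 2 samples")

    vals = m.values()
    peri = vals[:, labels == 1]
    norm = vals[:, labels == 0]
    mean_p = peri.mean(axis=1)
    mean_n = norm.mean(axis=1)
    var_p = peri.var(axis=1, ddof=1)
    var_n = norm.var(axis=1, ddof=1)
    df = n0 + n1 - 2
    pooled = ((n1 - 1) * var_p + (n0 - 1) * var_n) / df
    diff = mean_p - mean_n
    se_factor = 1.0 / n1 + 1.0 / n0

    zero_var = pooled <= 0
    pvals = np.ones(vals.shape[0])
    if method == "student":
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(pooled * se_factor)
        ok = ~zero_var
        pvals[ok] = 2 * sps.t.sf(np.abs(t[ok]), df=df)
    elif method == "moderated":
        d0, s0_sq = _moment_prior(pooled, df)
        shrunk = (d0 * s0_sq + df * pooled) / (d0 + df)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(shrunk * se_factor)
        ok = shrunk > 0
        pvals[ok] = 2 * sps.t.sf(np.abs(t[ok]), df=min(df + d0, 1e6))
        zero_var = ~ok
    else:
        raise ValueError(f"unknown method: {method!r}")

    # fold change on linear-scale group means
    lin = np.exp2(vals)
    fc = lin[:, labels == 1].mean(axis=1) / lin[:, labels == 0].mean(axis=1)
    log2fc = np.log2(fc)

    p_for_call = pvals
    p_adj = None
    if adjust:
        p_adj = _benjamini_hochberg(pvals)
        p_for_call = p_adj

    significant = ((fc > fc_threshold) | (fc < 1.0 / fc_threshold)) & (p_for_call < p_threshold)
    records = pd.DataFrame(
        {
            "protein_id": m.protein_ids,
            "fold_change": fc,
            "log2fc": log2fc,
            "p_value": pvals,
            "direction": np.where(fc > 1.0, "up", "down"),
            "significant": significant,
            "zero_variance": zero_var,
        }
    )
    if p_adj is not None:
        records["p_adjusted"] = p_adj
    return records


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    return out


def volcano_table(records: pd.DataFrame) -> pd.DataFrame:
    """(log2fc, -log10 p, significant) per protein, no filtering."""
    with np.errstate(divide="ignore"):
        neg_log_p = -np.log10(records["p_value"].to_numpy())
    return pd.DataFrame(
        {
            "protein_id": records["protein_id"],
            "log2fc": records["log2fc"],
            "neg_log10_p": neg_log_p,
            "significant": records["significant"],
        }
    )
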