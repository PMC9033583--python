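"""Occurrence (PME-O) and progression (PME-P) protein signatures and
per-patient risk indices.

The occurrence arm ranks significant differential proteins by how well they
discriminate peritumor from normal tissue (Mann-Whitney AUC); the
progression arm retains those whose median-split Kaplan-Meier curves differ
by a log-rank test.  Each signature protein carries one of six functional
factor categories (immunity, inflammation, angiogenesis, metabolism,
proliferation & invasion, DNA damage & repair) supplied by an annotation
map.

The per-patient risk index (RI) aggregates, per category, weighted
direction-aligned abundances rescaled to [0, 10] across the peritumor
cohort; weights are 2*(AUC - 0.5) for occurrence proteins and -log10 of the
log-rank p (capped at 4) for progression proteins.  This weighted-sum
construction is a parameterized stand-in for the study's supplementary
workflow, so printed RI ranges are not expected to be reproduced
numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as core
from .containers import AbundanceMatrix, ClinicalTable
from .simulate import CATEGORIES

__all__ = [
    "SignatureProtein",
    "select_occurrence_signature",
    "select_progression_signature",
    "signature_overlap",
    "compute_risk_profiles",
    "ri_clinical_association",
    "compare_category_ri",
    "signature_to_frame",
]

OCCURRENCE = "occurrence"
PROGRESSION = "progression"
PROGRESSION_WEIGHT_CAP = 4.0
RI_SCALE_MAX = 10.0


@dataclass(frozen=True)
class SignatureProtein:
    """One selected marker: its arm, functional category and selection scores."""

    protein_id: str
    arm: str                      # occurrence | progression
    category: str                 # one of the six factor categories
    direction: str                # up | down in peritumor
    auc: float | None = None      # occurrence arm
    logrank_p: float | None = None  # progression arm

    def __post_init__(self):
        if self.arm not in (OCCURRENCE, PROGRESSION):
            raise ValueError(f"unknown arm: {self.arm!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category: {self.category!r}")
        if self.arm == OCCURRENCE and self.auc is None:
            raise ValueError("occurrence protein requires an AUC")
        if self.arm == PROGRESSION and self.logrank_p is None:
            raise ValueError("progression protein requires a log-rank p")

    @property
    def weight(self) -> float:
        if self.arm == OCCURRENCE:
            return 2.0 * (max(self.auc, 1.0 - self.auc) - 0.5)
        return min(-np.log10(max(self.logrank_p, 1e-300)), PROGRESSION_WEIGHT_CAP)


def _lookup_category(protein_id: str, category_map: dict[str, str]) -> str | None:
    cat = category_map.get(protein_id)
    if cat is None or cat not in CATEGORIES:
        return None
    return cat


def select_occurrence_signature(
    diff: pd.DataFrame,
    m: AbundanceMatrix,
    clinical: ClinicalTable,
    category_map: dict[str, str],
    auc_min: float = 0.8,
    max_n: int = 40,
) -> list[SignatureProtein]:
    """Rank significant differential proteins by normal-vs-peritumor AUC.

    The discriminative score is max(AUC, 1-AUC); proteins at or above
    ``auc_min`` are retained, capped at ``max_n``.  Ranking is by AUC, then
    (perfect discriminators tie at 1.0 in a cohort of this size) by the
    differential p-value as a weight surrogate, then protein ID.
    """
    sig = diff[diff["significant"]]
    if sig.empty:
        warnings.warn("no significant differential proteins; empty occurrence signature", stacklevel=2)
        return []
    labels = clinical.group_labels(m.sample_ids)
    sub = m.subset_proteins(sig["protein_id"])
    aucs = core.auc_many(sub.values(), labels)
    eff = np.maximum(aucs, 1.0 - aucs)
    direction = dict(zip(diff["protein_id"], diff["direction"]))

    rows = []
    for pid, auc, e, p in zip(sig["protein_id"], aucs, eff, sig["p_value"]):
        if e < auc_min:
            continue
        cat = _lookup_category(pid, category_map)
        if cat is None:
            warnings.warn(f"protein {pid} lacks a category annotation; dropped", stacklevel=2)
            continue
        rows.append((e, p, pid, auc, cat))
    rows.sort(key=lambda r: (-r[0], r[1], r[2]))
    out = [
        SignatureProtein(pid, OCCURRENCE, cat, direction[pid], auc=float(auc))
        for _, _, pid, auc, cat in rows[:max_n]
    ]
    if not out:
        warnings.warn("occurrence signature is empty at the requested AUC cutoff", stacklevel=2)
    return out


def select_progression_signature(
    diff: pd.DataFrame,
    m: AbundanceMatrix,
    clinical: ClinicalTable,
    category_map: dict[str, str],
    p_max: float = 0.05,
    max_n: int = 52,
) -> list[SignatureProtein]:
    """Median-split each significant protein over the peritumor cohort and
    keep those whose high/low Kaplan-Meier curves differ (log-rank p <=
    ``p_max``), ranked by p ascending, capped at ``max_n``."""
    sig = diff[diff["significant"]]
    if sig.empty:
        warnings.warn("no significant differential proteins; empty progression signature", stacklevel=2)
        return []
    peri_ids = clinical.peritumor_ids
    surv = clinical.survival(peri_ids)
    if surv.n_events == 0:
        raise ValueError("no events among peritumor samples")
    sub = m.subset_proteins(sig["protein_id"]).subset_samples(peri_ids)
    vals = sub.values()

    rows = []
    for pid, row in zip(sig["protein_id"], vals):
        median = np.median(row)
        high = row > median          # values at the median go to "low"
        if high.sum() == 0 or high.sum() == high.size:
            continue                 # constant protein: no valid split
        try:
            res = core.logrank_test(surv.subset(high), surv.subset(~high))
        except ValueError:
            continue
        if res.p_value <= p_max:
            cat = _lookup_category(pid, category_map)
            if cat is None:
                warnings.warn(f"protein {pid} lacks a category annotation; dropped", stacklevel=2)
                continue
            # risk-aligned direction: "up" when the high-abundance arm has
            # excess deaths, so the RI accumulates toward worse prognosis
            direction = "up" if res.o_minus_e_a >= 0 else "down"
            rows.append((res.p_value, pid, cat, direction))
    rows.sort(key=lambda r: (r[0], r[1]))
    return [
        SignatureProtein(pid, PROGRESSION, cat, direction, logrank_p=float(p))
        for p, pid, cat, direction in rows[:max_n]
    ]


def signature_overlap(
    occ: list[SignatureProtein], prog: list[SignatureProtein]
) -> dict:
    """Shared proteins between the two arms and the overlap percentage
    100 * |intersection| / |union| (reported to 2 decimals)."""
    occ_ids = {p.protein_id for p in occ}
    prog_ids = {p.protein_id for p in prog}
    shared = occ_ids & prog_ids
    union = occ_ids | prog_ids
    percent = 100.0 * len(shared) / len(union) if union else 0.0
    return {
        "shared": sorted(shared),
        "n_shared": len(shared),
        "n_union": len(union),
        "overlap_percent": round(percent, 2),
    }


def compute_risk_profiles(
    signature: list[SignatureProtein],
    m: AbundanceMatrix,
    clinical: ClinicalTable,
) -> tuple[pd.DataFrame, dict]:
    """Per-patient category and total risk indices over the peritumor cohort.

    Each protein contributes weight * scaled abundance, where the abundance
    is min-max rescaled to [0, 10] across peritumor samples and reversed for
    down-regulated proteins; the category RI sums that category's proteins
    and the total RI sums all categories.  Patients are split into high/low
    RI groups at the cohort median (values equal to the median go to
    "low").  Returns the per-patient table and a cohort summary
    (range, IQR, mean, median).
    """
    if not signature:
        raise ValueError("empty signature")
    peri_ids = clinical.peritumor_ids
    sub = m.subset_proteins([p.protein_id for p in signature]).subset_samples(peri_ids)
    vals = sub.values()

    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = RI_SCALE_MAX * (vals - lo) / span
    for i, prot in enumerate(signature):
        if prot.direction == "down":
            scaled[i] = RI_SCALE_MAX - scaled[i]

    weights = np.array([p.weight for p in signature])
    contrib = weights[:, None] * scaled

    profile = pd.DataFrame({"sample_id": peri_ids})
    for cat in CATEGORIES:
        idx = [i for i, p in enumerate(signature) if p.category == cat]
        profile[f"ri_{cat}"] = contrib[idx].sum(axis=0) if idx else 0.0
    profile["total_ri"] = profile[[f"ri_{c}" for c in CATEGORIES]].sum(axis=1)

    median = float(profile["total_ri"].median())
    profile["ri_group"] = np.where(profile["total_ri"] > median, "high", "low")
    degenerate = profile["total_ri"].nunique() == 1
    if degenerate:
        warnings.warn("all patients share one total RI; median split is degenerate", stacklevel=2)

    total = profile["total_ri"]
    summary = {
        "min": float(total.min()),
        "max": float(total.max()),
        "iqr": [float(total.quantile(0.25)), float(total.quantile(0.75))],
        "mean": float(total.mean()),
        "median": median,
        "degenerate_split": bool(degenerate),
    }
    return profile, summary


def ri_clinical_association(
    profiles: pd.DataFrame,
    clinical: ClinicalTable,
    covariate: str,
    cutoff: float,
) -> dict:
    """Cross-tabulate the RI group against a dichotomized covariate
    (value > cutoff = high) and test with chi-square and Fisher exact."""
    merged = profiles.merge(
        clinical.df[["sample_id", covariate]], on="sample_id", how="left"
    )
    n_total = len(merged)
    merged = merged.dropna(subset=[covariate])
    n_excluded = n_total - len(merged)
    high_cov = merged[covariate] > cutoff
    high_ri = merged["ri_group"] == "high"
    table = np.array(
        [
            [int((high_ri & high_cov).sum()), int((high_ri & ~high_cov).sum())],
            [int((~high_ri & high_cov).sum()), int((~high_ri & ~high_cov).sum())],
        ]
    )
    degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    fisher_p = core.fisher_exact(table)
    chi_p = None
    if not degenerate:
        _, _, chi_p = core.chi_square_test(table)
    return {
        "covariate": covariate,
        "cutoff": cutoff,
        "table": table.tolist(),
        "chi_square_p": chi_p,
        "fisher_p": fisher_p,
        "n_excluded_missing": n_excluded,
        "degenerate": bool(degenerate),
    }


def compare_category_ri(profiles: pd.DataFrame) -> dict:
    """Compare the per-category RIs across patients: category means/medians
    (descending), Kruskal-Wallis omnibus, pairwise Mann-Whitney with
    Bonferroni correction."""
    cats = [c for c in CATEGORIES if f"ri_{c}" in profiles.columns]
    arrays = {c: profiles[f"ri_{c}"].to_numpy(dtype=float) for c in cats}
    means = {c: float(v.mean()) for c, v in arrays.items()}
    medians = {c: float(np.median(v)) for c, v in arrays.items()}
    order = sorted(cats, key=lambda c: -means[c])

    result = {
        "category_order": order,
        "means": means,
        "medians": medians,
        "omnibus_p": None,
        "pairwise": {},
    }
    groups = [arrays[c] for c in cats]
    if len(cats) < 2:
        return result
    if all(np.allclose(g, groups[0]) for g in groups[1:]):
        result["omnibus_p"] = 1.0
        return result
    result["omnibus_p"] = float(sps.kruskal(*groups).pvalue)
    n_pairs = len(cats) * (len(cats) - 1) // 2
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            p = float(sps.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided").pvalue)
            result["pairwise"][f"{a}|{b}"] = min(1.0, p * n_pairs)
    return result


def signature_to_frame(signature: list[SignatureProtein]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [p.protein_id for p in signature],
            "arm": [p.arm for p in signature],
            "category": [p.category for p in signature],
            "auc": [p.auc for p in signature],
            "logrank_p": [p.logrank_p for p in signature],
            "direction": [p.direction for p in signature],
        }
    )
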