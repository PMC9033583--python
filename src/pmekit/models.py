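"""Three-marker occurrence and prognostic prediction models, and the
occurrence <-> progression cross-evaluation.

The occurrence model is a logistic regression of group (peritumor vs
normal) on log2 marker abundances with a Youden-optimal probability cut.
The prognostic model is a Cox proportional-hazards fit on the peritumor
cohort; the prognostic index (PI) is the Cox linear predictor, whose
cohort-median split stratifies the Kaplan-Meier curves.  A ROC for the
prognostic model uses death before the cohort's median follow-up as the
positive outcome (subjects censored before that horizon are excluded and
counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as core
from .containers import AbundanceMatrix, ClinicalTable
from .signatures import SignatureProtein

__all__ = [
    "OccurrenceModel",
    "PrognosticModel",
    "fit_occurrence_model",
    "apply_occurrence_model",
    "fit_prognostic_model",
    "apply_prognostic_model",
    "cross_evaluate",
    "DEFAULT_OCCURRENCE_MARKERS",
    "DEFAULT_PROGRESSION_MARKERS",
]

#: The study's marker panels (functional category in parentheses):
#: occurrence - HSPA4L (immunity), VIL1 (inflammation), TYMP (angiogenesis);
#: progression - CMPK2 (inflammation), TYMP (angiogenesis), NADSYN1 (metabolism).
DEFAULT_OCCURRENCE_MARKERS = ("HSPA4L", "VIL1", "TYMP")
DEFAULT_PROGRESSION_MARKERS = ("CMPK2", "TYMP", "NADSYN1")


def _marker_matrix(m: AbundanceMatrix, markers, sample_ids) -> np.ndarray:
    missing = [mk for mk in markers if mk not in m.data.index]
    if missing:
        raise ValueError(f"markers absent from abundance matrix: {missing}")
    return m.subset_proteins(markers).subset_samples(sample_ids).values().T


@dataclass
class OccurrenceModel:
    marker_ids: tuple[str, ...]
    fit: core.LogisticResult
    threshold: float                      # probability cut (Youden)
    train_metrics: core.RocResult
    validation_metrics: core.RocResult | None = None

    def predict_proba(self, m: AbundanceMatrix, sample_ids) -> np.ndarray:
        X = _marker_matrix(m, self.marker_ids, sample_ids)
        return self.fit.predict(X)

    def to_dict(self) -> dict:
        out = {
            "markers": list(self.marker_ids),
            "intercept": self.fit.intercept,
            "coefficients": self.fit.coef.tolist(),
            "threshold": self.threshold,
            "flagged": self.fit.flagged,
            "train": self.train_metrics.to_dict(),
        }
        if self.validation_metrics is not None:
            out["validation"] = self.validation_metrics.to_dict()
        return out


@dataclass
class PrognosticModel:
    marker_ids: tuple[str, ...]
    cox: core.CoxResult
    pi: pd.Series                         # per-patient prognostic index
    pi_group: pd.Series                   # high | low by cohort median PI
    logrank: core.LogrankResult
    km_high: core.KaplanMeierResult
    km_low: core.KaplanMeierResult
    roc: core.RocResult | None            # death before median follow-up
    n_roc_excluded: int

    def to_dict(self) -> dict:
        return {
            "markers": list(self.marker_ids),
            "cox_betas": self.cox.coef.tolist(),
            "cox_se": self.cox.se.tolist(),
            "flagged": self.cox.flagged,
            "logrank_statistic": self.logrank.statistic,
            "logrank_p": self.logrank.p_value,
            "median_survival_high": self.km_high.median,
            "median_survival_low": self.km_low.median,
            "roc": None if self.roc is None else self.roc.to_dict(),
            "n_roc_excluded": self.n_roc_excluded,
        }


def fit_occurrence_model(
    m: AbundanceMatrix,
    clinical: ClinicalTable,
    markers=DEFAULT_OCCURRENCE_MARKERS,
    validation: tuple[AbundanceMatrix, ClinicalTable] | None = None,
) -> OccurrenceModel:
    """Logistic occurrence model on log2 marker abundances.

    Training metrics are the ROC of fitted probabilities against group; when
    a validation cohort is supplied the frozen model is applied to it (no
    refit) and scored the same way.
    """
    sample_ids = m.sample_ids
    labels = clinical.group_labels(sample_ids)
    X = _marker_matrix(m, markers, sample_ids)
    fit = core.logistic_fit(X, labels)
    train = core.roc_auc(fit.fitted, labels)
    model = OccurrenceModel(
        marker_ids=tuple(markers),
        fit=fit,
        threshold=train.threshold,
        train_metrics=train,
    )
    if validation is not None:
        vm, vc = validation
        probs = model.predict_proba(vm, vm.sample_ids)
        model.validation_metrics = core.roc_auc(probs, vc.group_labels(vm.sample_ids))
    return model


def apply_occurrence_model(
    model: OccurrenceModel, m: AbundanceMatrix, clinical: ClinicalTable
) -> core.RocResult:
    """Score a frozen occurrence model on an external cohort."""
    probs = model.predict_proba(m, m.sample_ids)
    return core.roc_auc(probs, clinical.group_labels(m.sample_ids))


def _progression_roc(
    pi: np.ndarray, surv: core.SurvivalData
) -> tuple[core.RocResult | None, int]:
    """ROC of a risk score against death before the median follow-up.

    Positives die before the horizon; negatives survive past it (event or
    censoring after the horizon); subjects censored before the horizon are
    uninformative and excluded.
    """
    horizon = float(np.median(surv.time))
    died_before = (surv.time < horizon) & (surv.event == 1)
    past_horizon = surv.time >= horizon
    keep = died_before | past_horizon
    labels = died_before[keep].astype(int)
    excluded = int((~keep).sum())
    if labels.sum() == 0 or labels.sum() == labels.size:
        return None, excluded
    return core.roc_auc(pi[keep], labels), excluded


def fit_prognostic_model(
    m: AbundanceMatrix,
    clinical: ClinicalTable,
    markers=DEFAULT_PROGRESSION_MARKERS,
) -> PrognosticModel:
    """Cox prognostic model on the peritumor cohort; PI = linear predictor."""
    peri_ids = clinical.peritumor_ids
    surv = clinical.survival(peri_ids)
    X = _marker_matrix(m, markers, peri_ids)
    cox = core.cox_fit(X, surv)
    pi = pd.Series(cox.linear_predictor, index=peri_ids, name="pi")
    median = float(pi.median())
    group = pd.Series(np.where(pi > median, "high", "low"), index=peri_ids, name="pi_group")

    high = (group == "high").to_numpy()
    surv_high = surv.subset(high)
    surv_low = surv.subset(~high)
    logrank = core.logrank_test(surv_high, surv_low)
    roc, n_excl = _progression_roc(pi.to_numpy(), surv)
    return PrognosticModel(
        marker_ids=tuple(markers),
        cox=cox,
        pi=pi,
        pi_group=group,
        logrank=logrank,
        km_high=core.km_estimate(surv_high),
        km_low=core.km_estimate(surv_low),
        roc=roc,
        n_roc_excluded=n_excl,
    )


def apply_prognostic_model(
    model: PrognosticModel, m: AbundanceMatrix, clinical: ClinicalTable
) -> dict:
    """Apply frozen Cox betas to an external cohort and evaluate the
    median-PI split there."""
    peri_ids = clinical.peritumor_ids
    surv = clinical.survival(peri_ids)
    X = _marker_matrix(m, model.marker_ids, peri_ids)
    pi = X @ model.cox.coef
    high = pi > np.median(pi)
    logrank = core.logrank_test(surv.subset(high), surv.subset(~high))
    roc, n_excl = _progression_roc(pi, surv)
    return {
        "logrank_p": logrank.p_value,
        "logrank_statistic": logrank.statistic,
        "roc": None if roc is None else roc.to_dict(),
        "n_roc_excluded": n_excl,
    }


def cross_evaluate(
    occ_sig: list[SignatureProtein],
    prog_sig: list[SignatureProtein],
    m: AbundanceMatrix,
    clinical: ClinicalTable,
    auc_min: float = 0.8,
    p_max: float = 0.05,
) -> dict:
    """Test whether each signature arm is specific to its own criterion.

    Every protein in either arm is scored on both criteria: occurrence
    discrimination (max(AUC, 1-AUC) >= ``auc_min`` for normal vs peritumor)
    and progression association (median-split log-rank p <= ``p_max``).  Two
    arm x criterion four-fold tables are returned with chi-square and
    Fisher exact p-values (chi-square omitted on degenerate margins).
    """
    if not occ_sig or not prog_sig:
        raise ValueError("both signatures must be non-empty")
    labels = clinical.group_labels(m.sample_ids)
    peri_ids = clinical.peritumor_ids
    surv = clinical.survival(peri_ids)

    def occurrence_criterion(pid: str) -> bool:
        vals = m.data.loc[pid].to_numpy(dtype=float)
        auc = core.roc_auc(vals, labels).auc
        return max(auc, 1.0 - auc) >= auc_min

    peri = m.subset_samples(peri_ids)

    def progression_criterion(pid: str) -> bool:
        row = peri.data.loc[pid].to_numpy(dtype=float)
        high = row > np.median(row)
        if high.sum() in (0, high.size):
            return False
        try:
            return core.logrank_test(surv.subset(high), surv.subset(~high)).p_value <= p_max
        except ValueError:
            return False

    arms = [(p.protein_id, "occurrence") for p in occ_sig] + [
        (p.protein_id, "progression") for p in prog_sig
    ]

    def build_table(criterion) -> dict:
        counts = np.zeros((2, 2), dtype=int)
        for pid, arm in arms:
            row = 0 if arm == "occurrence" else 1
            col = 0 if criterion(pid) else 1
            counts[row, col] += 1
        degenerate = (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any()
        out = {
            "table": counts.tolist(),
            "fisher_p": core.fisher_exact(counts),
            "chi_square_p": None,
            "degenerate": bool(degenerate),
        }
        if not degenerate:
            _, _, out["chi_square_p"] = core.chi_square_test(counts)
        return out

    return {
        "occurrence_criterion": build_table(occurrence_criterion),
        "progression_criterion": build_table(progression_criterion),
        "auc_min": auc_min,
        "p_max": p_max,
    }
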