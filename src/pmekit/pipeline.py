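"""End-to-end orchestration: simulate-or-load, preprocess, differential
analysis, signature selection and risk indices, prediction models, consensus
subtyping, and a reproducible report bundle.

One global seed fans out to per-stage seeds through a spawned
``numpy.random.SeedSequence`` so each stage is independently reproducible;
every artifact is written once and the summary JSON is byte-identical across
reruns of the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as core
from .containers import AbundanceMatrix, ClinicalTable
from .differential import count_identified, differential_test
from .models import cross_evaluate, fit_occurrence_model, fit_prognostic_model
from .preprocess import preprocess_pipeline
from .signatures import (
    compare_category_ri,
    compute_risk_profiles,
    ri_clinical_association,
    select_occurrence_signature,
    select_progression_signature,
    signature_overlap,
    signature_to_frame,
)
from .simulate import CohortConfig, GroundTruth, generate_cohort, read_ground_truth, write_fixture
from .subtyping import consensus_cluster, subtype_feature_tests

__all__ = ["RunConfig", "run_pipeline", "validate_against_cohort", "load_category_map"]

#: Clinical dichotomization cutoffs used for RI association tables.
AFP_CUTOFF_NG_ML = 300.0
CYP2E1_CUTOFF = 1350.0
SURVIVAL_CUTOFF_DAYS = 344.0


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults follow the study's stated values."""

    # input: either file paths or a synthetic cohort spec
    abundance_path: str | None = None
    clinical_path: str | None = None
    category_map_path: str | None = None
    ground_truth_path: str | None = None
    cohort: CohortConfig | None = None

    # stage parameters
    min_detect: float = 0.5
    quantile: bool = True
    diff_method: str = "student"
    fc_threshold: float = 1.2
    p_threshold: float = 0.05
    auc_min: float = 0.8
    occ_max_n: int = 40
    prog_p_max: float = 0.05
    prog_max_n: int = 52
    occurrence_markers: tuple[str, ...] | None = None   # default: top-3 occurrence signature
    progression_markers: tuple[str, ...] | None = None  # default: top-3 progression signature
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_runs: int = 50
    nmf_top_n: int = 300        # most-variable significant proteins fed to NMF
    nmf_max_iter: int = 2000
    seed: int = 0

    @classmethod
    def synthetic(cls, seed: int = 0, **kwargs) -> "RunConfig":
        cohort_kwargs = kwargs.pop("cohort_kwargs", {})
        return cls(cohort=CohortConfig(seed=seed, **cohort_kwargs), seed=seed, **kwargs)


def load_category_map(path) -> dict[str, str]:
    """Two-column TSV: protein_id <tab> category."""
    df = pd.read_csv(path, sep="\t", header=None, names=["protein_id", "category"])
    return dict(zip(df["protein_id"], df["category"]))


def _load_inputs(config: RunConfig, outdir: Path, log: list[str]):
    if config.cohort is not None:
        matrix, clinical, truth = generate_cohort(config.cohort)
        write_fixture(matrix, clinical, truth, outdir / "cohort")
        log.append(f"synthetic cohort generated with seed {config.cohort.seed}")
        category_map = truth.category_map
    else:
        if not (config.abundance_path and config.clinical_path):
            raise ValueError("either a synthetic cohort or input paths are required")
        matrix = AbundanceMatrix.read_tsv(config.abundance_path)
        clinical = ClinicalTable.read_csv(config.clinical_path)
        truth = (
            read_ground_truth(config.ground_truth_path)
            if config.ground_truth_path
            else None
        )
        if config.category_map_path is None:
            raise ValueError("a category map is required when loading cohort files")
        category_map = load_category_map(config.category_map_path)
        log.append(f"loaded cohort from {config.abundance_path}")
    return matrix, clinical, truth, category_map


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage and write the report bundle to ``outdir``.

    Returns the summary dictionary (also written as ``summary.json``).
    Stage failures abort with the stage name in the exception message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"global seed: {config.seed}"]
    stage_seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    log.append("per-stage seeds spawned from the global seed (subtyping uses slot 0)")

    summary: dict = {"seed": config.seed}

    def stage(name):
        log.append(f"stage: {name}")

    try:
        stage("load")
        matrix, clinical, truth, category_map = _load_inputs(config, outdir, log)

        stage("identified-counts")
        counts, counts_p = count_identified(matrix, clinical)
        counts.to_csv(outdir / "identified_counts.tsv", sep="\t", index=False)
        summary["identified_counts"] = {
            "mean_normal": float(counts.loc[counts.group == "normal", "n_identified"].mean()),
            "mean_peritumor": float(counts.loc[counts.group == "peritumor", "n_identified"].mean()),
            "t_test_p": counts_p,
        }

        stage("preprocess")
        log.append(
            f"preprocess order: detection filter (>= {config.min_detect}) -> half-minimum "
            f"imputation -> quantile normalization ({'on' if config.quantile else 'off'}) -> log2"
        )
        pre = preprocess_pipeline(matrix, min_frac=config.min_detect, quantile=config.quantile)
        pre.write_tsv(outdir / "preprocessed_log2.tsv")
        summary["n_proteins_retained"] = pre.n_proteins

        stage("differential")
        log.append(
            f"differential: method={config.diff_method}, fold-change threshold "
            f"{config.fc_threshold} (two-sided), raw p < {config.p_threshold}; "
            "fold change on linear-scale group means of imputed data"
        )
        diff = differential_test(
            pre,
            clinical,
            method=config.diff_method,
            fc_threshold=config.fc_threshold,
            p_threshold=config.p_threshold,
        )
        diff.to_csv(outdir / "differential.tsv", sep="\t", index=False)
        summary["n_differential_significant"] = int(diff["significant"].sum())

        stage("signatures")
        occ_sig = select_occurrence_signature(
            diff, pre, clinical, category_map, auc_min=config.auc_min, max_n=config.occ_max_n
        )
        prog_sig = select_progression_signature(
            diff, pre, clinical, category_map, p_max=config.prog_p_max, max_n=config.prog_max_n
        )
        signature_to_frame(occ_sig + prog_sig).to_csv(
            outdir / "signatures.tsv", sep="\t", index=False
        )
        overlap = signature_overlap(occ_sig, prog_sig)
        summary["occurrence_signature_size"] = len(occ_sig)
        summary["progression_signature_size"] = len(prog_sig)
        summary["signature_overlap"] = overlap

        stage("risk-indices")
        occ_profiles = prog_profiles = None
        if occ_sig:
            occ_profiles, occ_summary = compute_risk_profiles(occ_sig, pre, clinical)
            occ_profiles.to_csv(outdir / "risk_profiles_occurrence.tsv", sep="\t", index=False)
            summary["occurrence_ri"] = occ_summary
            summary["occurrence_ri_by_category"] = compare_category_ri(occ_profiles)
            summary["ri_clinical"] = {
                "afp": ri_clinical_association(occ_profiles, clinical, "afp_ng_ml", AFP_CUTOFF_NG_ML),
                "cyp2e1": ri_clinical_association(
                    occ_profiles, clinical, "cyp2e1_activity", CYP2E1_CUTOFF
                ),
            }
        if prog_sig:
            prog_profiles, prog_summary = compute_risk_profiles(prog_sig, pre, clinical)
            prog_profiles.to_csv(outdir / "risk_profiles_progression.tsv", sep="\t", index=False)
            summary["progression_ri"] = prog_summary
            summary["progression_ri_by_category"] = compare_category_ri(prog_profiles)

        stage("occurrence-model")
        occ_markers = config.occurrence_markers or tuple(
            p.protein_id for p in occ_sig[:3]
        )
        if len(occ_markers) >= 1:
            occ_model = fit_occurrence_model(pre, clinical, markers=occ_markers)
            summary["occurrence_model"] = occ_model.to_dict()
            log.append(f"occurrence model markers: {list(occ_markers)}")
        else:
            occ_model = None
            log.append("occurrence model skipped: no markers available")

        stage("prognostic-model")
        prog_markers = config.progression_markers or tuple(
            p.protein_id for p in prog_sig[:3]
        )
        if len(prog_markers) >= 1:
            prog_model = fit_prognostic_model(pre, clinical, markers=prog_markers)
            summary["prognostic_model"] = prog_model.to_dict()
            log.append(
                f"prognostic model markers: {list(prog_markers)}; PI = Cox linear predictor; "
                "progression ROC outcome = death before median follow-up "
                f"({prog_model.n_roc_excluded} censored-before-horizon subjects excluded)"
            )
        else:
            prog_model = None
            log.append("prognostic model skipped: no markers available")

        stage("cross-evaluation")
        if occ_sig and prog_sig:
            summary["cross_evaluation"] = cross_evaluate(
                occ_sig, prog_sig, pre, clinical, auc_min=config.auc_min, p_max=config.prog_p_max
            )

        stage("subtyping")
        sig_ids = list(diff.loc[diff["significant"], "protein_id"])
        if len(sig_ids) > max(config.k_range) + 1:
            peri = pre.subset_proteins(sig_ids).subset_samples(clinical.peritumor_ids)
            vals = peri.values()
            if len(sig_ids) > config.nmf_top_n:
                var_order = np.argsort(-vals.var(axis=1))[: config.nmf_top_n]
                vals = vals[np.sort(var_order)]
                log.append(
                    f"subtyping input reduced to the {config.nmf_top_n} most variable "
                    "significant proteins"
                )
            shifted = vals - vals.min()  # global shift into the non-negative orthant
            consensus = consensus_cluster(
                shifted,
                peri.sample_ids,
                k_range=config.k_range,
                n_runs=config.n_runs,
                seed=int(stage_seeds[0]),
                max_iter=config.nmf_max_iter,
            )
            consensus.labels.rename("subtype").to_csv(outdir / "subtype_labels.tsv", sep="\t")
            summary["subtyping"] = {
                "chosen_k": consensus.chosen_k,
                "sizes": {str(k): v for k, v in consensus.sizes().items()},
                "cophenetic": {str(k): v for k, v in consensus.cophenetic.items()},
                "cdf_area": {str(k): v for k, v in consensus.cdf_area.items()},
                "weak_structure": consensus.weak_structure,
            }
            if consensus.weak_structure:
                log.append("subtyping: weak structure flagged (ambiguous consensus)")
            feature_tests = subtype_feature_tests(
                consensus.labels, clinical, risk_profiles=prog_profiles
            )
            feature_tests.to_csv(outdir / "subtype_feature_tests.tsv", sep="\t", index=False)
            summary["subtype_feature_p"] = dict(
                zip(feature_tests["feature"], feature_tests["p_value"])
            )
            if truth is not None and truth.subtype_labels:
                from sklearn.metrics import adjusted_rand_score

                true = [truth.subtype_labels[s] for s in consensus.labels.index]
                summary["subtyping"]["ari_vs_truth"] = float(
                    adjusted_rand_score(true, consensus.labels.to_numpy())
                )
        else:
            log.append("subtyping skipped: too few significant proteins")

    except Exception as exc:  # annotate with the failing stage
        failed = log[-1] if log else "unknown"
        raise RuntimeError(f"pipeline aborted at {failed!r}: {exc}") from exc

    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return summary


def validate_against_cohort(
    occ_model,
    prog_model,
    matrix: AbundanceMatrix,
    clinical: ClinicalTable,
    min_detect: float = 0.5,
    quantile: bool = True,
) -> dict:
    """Apply frozen models (no refit) to an external cohort.

    The cohort is preprocessed with the same conditioning steps; a missing
    marker raises an error naming it.
    """
    from .models import apply_occurrence_model, apply_prognostic_model

    pre = preprocess_pipeline(matrix, min_frac=min_detect, quantile=quantile)
    out: dict = {}
    if occ_model is not None:
        out["occurrence"] = apply_occurrence_model(occ_model, pre, clinical).to_dict()
    if prog_model is not None:
        out["prognostic"] = apply_prognostic_model(prog_model, pre, clinical)
    return out
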