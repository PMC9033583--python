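"""Synthetic HCC peritumor-microenvironment cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes in a
label-free proteomic study of peritumor liver tissue: log-normal protein
abundances with planted fold changes between normal and peritumor groups,
planted occurrence markers (strong, low-noise discriminators), planted
progression markers whose abundance drives an exponential
proportional-hazards survival model, latent peritumor subtypes expressed as
block-structured abundance signatures, detection-limit (left-censored)
missingness, and clinical covariates coupled to the planted risk burden
through a rank-preserving Gaussian copula.

Defaults mirror the study layout: 34 normal and 61 peritumor samples, 5000
proteins, 40 occurrence and 52 progression markers sharing 3 proteins, and a
baseline survival scale giving a median follow-up near one year.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import NORMAL, PERITUMOR, AbundanceMatrix, ClinicalTable

#: The six functional factor categories used for both signature arms.
CATEGORIES = (
    "immunity",
    "inflammation",
    "angiogenesis",
    "metabolism",
    "proliferation_invasion",
    "dna_damage_repair",
)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Counts and planted-effect sizes default to the study conditions; fold
    changes are linear-scale magnitudes (> 1), hazard effects are per-SD
    log-hazard ratios.
    """

    n_normal: int = 34
    n_peritumor: int = 61
    n_proteins: int = 5000
    n_de: int = 300
    fc_range: tuple[float, float] = (1.5, 4.0)
    n_occurrence_markers: int = 40
    n_progression_markers: int = 52
    n_shared_markers: int = 3
    occ_marker_fc: float = 3.0
    occ_marker_sd: float = 0.2
    #: fold change of progression-only markers: modest, so they carry survival
    #: signal without doubling as strong occurrence discriminators
    prog_marker_fc: float = 1.5
    hazard_beta_range: tuple[float, float] = (0.1, 0.3)
    hazard_betas: tuple[float, ...] | None = None  # explicit per-marker magnitudes
    n_subtypes: int = 3
    subtype_block_size: int = 40
    subtype_block_shift: float = 1.5  # log2 units
    baseline_median_days: float = 400.0
    censor_rate: float = 0.38        # censoring hazard / baseline hazard (~30% censored)
    missing_rate: float = 0.10
    peritumor_missing_factor: float = 0.8  # peritumor detects slightly more proteins
    coupling_rho: float = 0.5        # copula coupling of covariates to risk burden
    base_mean: float = 20.0          # log2 iBAQ-like location
    base_mean_sd: float = 2.0
    protein_sd_range: tuple[float, float] = (0.3, 0.8)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_normal, self.n_peritumor, self.n_proteins) <= 0:
            raise ValueError("sample and protein counts must be positive")
        if not (0 <= self.n_de <= self.n_proteins):
            raise ValueError("n_de must be between 0 and n_proteins")
        if self.fc_range[0] <= 1 or self.fc_range[1] < self.fc_range[0]:
            raise ValueError("fold changes must exceed 1 and be ordered")
        n_marked = self.n_occurrence_markers + self.n_progression_markers - self.n_shared_markers
        if self.n_de and n_marked > self.n_de:
            raise ValueError("marker sets must fit inside the planted DE proteins")
        if self.n_shared_markers > min(self.n_occurrence_markers, self.n_progression_markers):
            raise ValueError("shared markers exceed an arm size")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_subtypes < 1:
            raise ValueError("need at least one subtype")
        if self.hazard_betas is not None and len(self.hazard_betas) != self.n_progression_markers:
            raise ValueError("hazard_betas length must equal n_progression_markers")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort.

    ``de_log2fc`` maps each planted differential protein to its signed log2
    fold change (peritumor vs normal); marker maps carry the functional
    category (and, for progression markers, the true per-SD log-hazard);
    ``subtype_labels`` assigns each peritumor sample its latent class; the
    true survival linear predictor is kept for recovery checks.
    """

    de_log2fc: dict[str, float]
    occurrence_markers: dict[str, str]
    progression_markers: dict[str, dict]
    subtype_labels: dict[str, int]
    category_map: dict[str, str]
    true_linear_predictor: dict[str, float]

    @property
    def de_proteins(self) -> set[str]:
        return set(self.de_log2fc)

    def to_json(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, obj: dict) -> "GroundTruth":
        return cls(**obj)


def generate_cohort(config: CohortConfig) -> tuple[AbundanceMatrix, ClinicalTable, GroundTruth]:
    """Draw one synthetic cohort; fully reproducible given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_n, n_p = config.n_normal, config.n_peritumor
    n_samples = n_n + n_p
    protein_ids = [f"P{i + 1:05d}" for i in range(config.n_proteins)]
    sample_ids = [f"N{i + 1:03d}" for i in range(n_n)] + [f"T{i + 1:03d}" for i in range(n_p)]
    is_peri = np.r_[np.zeros(n_n, bool), np.ones(n_p, bool)]

    base_mean = rng.normal(config.base_mean, config.base_mean_sd, config.n_proteins)
    protein_sd = rng.uniform(*config.protein_sd_range, config.n_proteins)

    # --- planted differential proteins and marker arms ---------------------
    de_idx = rng.choice(config.n_proteins, size=config.n_de, replace=False)
    fc_mag = rng.uniform(*config.fc_range, config.n_de)
    fc_sign = rng.choice([-1.0, 1.0], config.n_de)
    log2fc = fc_sign * np.log2(fc_mag)

    n_occ, n_prog, n_shared = (
        config.n_occurrence_markers,
        config.n_progression_markers,
        config.n_shared_markers,
    )
    # Markers are planted on well-detected (above-median abundance) DE
    # proteins so they behave like practical biomarkers rather than proteins
    # living at the detection limit; remaining DE slots fill in if needed.
    if config.n_de:
        de_base = base_mean[de_idx]
        abundant = np.nonzero(de_base >= np.median(de_base))[0]
        dim = np.nonzero(de_base < np.median(de_base))[0]
        perm = np.r_[rng.permutation(abundant), rng.permutation(dim)].astype(int)
    else:
        perm = np.array([], dtype=int)
    occ_pos = perm[:n_occ]
    prog_pos = np.r_[perm[:n_shared], perm[n_occ : n_occ + n_prog - n_shared]]
    occ_idx = de_idx[occ_pos] if config.n_de else np.array([], int)
    prog_idx = de_idx[prog_pos] if config.n_de else np.array([], int)

    # Occurrence markers: strong, tight discriminators.
    if occ_idx.size:
        log2fc[occ_pos] = np.sign(log2fc[occ_pos]) * np.log2(config.occ_marker_fc)
        protein_sd[occ_idx] = config.occ_marker_sd
    # Progression-only markers: modest differential shift (arm-specific effects).
    prog_only_pos = prog_pos[n_shared:]
    if prog_only_pos.size:
        log2fc[prog_only_pos] = np.sign(log2fc[prog_only_pos]) * np.log2(config.prog_marker_fc)

    # --- latent subtypes among peritumor samples ---------------------------
    subtype = rng.integers(0, config.n_subtypes, n_p) + 1
    block_idx: list[np.ndarray] = []
    if config.n_subtypes > 1 and config.n_de:
        marked = set(occ_pos) | set(prog_pos)
        free = np.array([i for i in range(config.n_de) if i not in marked])
        rng.shuffle(free)
        per = min(config.subtype_block_size, free.size // config.n_subtypes)
        for s in range(config.n_subtypes):
            block_idx.append(de_idx[free[s * per : (s + 1) * per]])

    # --- abundance matrix on the log2 scale --------------------------------
    log2m = base_mean[:, None] + rng.normal(0, 1, (config.n_proteins, n_samples)) * protein_sd[:, None]
    if config.n_de:
        log2m[np.ix_(de_idx, np.nonzero(is_peri)[0])] += log2fc[:, None]
    for s, idx in enumerate(block_idx, start=1):
        cols = np.nonzero(is_peri)[0][subtype == s]
        if idx.size and cols.size:
            log2m[np.ix_(idx, cols)] += config.subtype_block_shift

    # --- survival from a proportional-hazards model ------------------------
    if prog_idx.size:
        mags = (
            np.asarray(config.hazard_betas, float)
            if config.hazard_betas is not None
            else rng.uniform(*config.hazard_beta_range, prog_idx.size)
        )
        beta = mags * rng.choice([-1.0, 1.0], prog_idx.size)
        marker_vals = log2m[np.ix_(prog_idx, np.nonzero(is_peri)[0])]
        z = (marker_vals - marker_vals.mean(axis=1, keepdims=True)) / marker_vals.std(axis=1, keepdims=True)
        lp = beta @ z
    else:
        beta = np.array([])
        lp = np.zeros(n_p)
    lam0 = np.log(2) / config.baseline_median_days
    t_event = rng.exponential(1.0 / (lam0 * np.exp(lp)))
    if config.censor_rate > 0:
        t_censor = rng.exponential(1.0 / (lam0 * config.censor_rate), n_p)
    else:
        t_censor = np.full(n_p, np.inf)
    surv_days = np.ceil(np.minimum(t_event, t_censor)).astype(int)
    surv_days = np.maximum(surv_days, 1)
    event = (t_event <= t_censor).astype(int)

    # --- clinical covariates via a Gaussian copula on the risk burden ------
    if occ_idx.size:
        occ_vals = log2m[np.ix_(occ_idx, np.nonzero(is_peri)[0])]
        zocc = (occ_vals - occ_vals.mean(axis=1, keepdims=True)) / occ_vals.std(axis=1, keepdims=True)
        occ_burden = (np.sign(log2fc[occ_pos]) @ zocc) / np.sqrt(occ_idx.size)
    else:
        occ_burden = np.zeros(n_p)
    lp_sd = lp.std()
    burden = occ_burden + (lp / lp_sd if lp_sd > 0 else 0.0)
    bsd = burden.std()
    burden_z = (burden - burden.mean()) / bsd if bsd > 0 else np.zeros(n_p)

    rho = config.coupling_rho

    def coupled_latent():
        return rho * burden_z + np.sqrt(1 - rho**2) * rng.normal(0, 1, n_p)

    afp = np.exp(np.log(100.0) + 1.5 * coupled_latent())
    cyp = 1350.0 + 250.0 * coupled_latent()
    lat = coupled_latent()
    cirrhosis = np.digitize(lat, np.quantile(lat, [0.15, 0.4, 0.7, 0.9]))
    diameter = np.exp(np.log(5.0) + 0.45 * coupled_latent())
    multiple = (coupled_latent() > 0.6).astype(int)

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": [NORMAL] * n_n + [PERITUMOR] * n_p,
            "survival_days": [np.nan] * n_n + list(surv_days.astype(float)),
            "event": [np.nan] * n_n + list(event.astype(float)),
            "afp_ng_ml": list(np.exp(np.log(12.0) + 0.6 * rng.normal(0, 1, n_n))) + list(afp),
            "cirrhosis_stage": list(rng.integers(0, 2, n_n)) + list(cirrhosis),
            "max_tumor_diameter_cm": [np.nan] * n_n + list(diameter),
            "multiple_tumors": [np.nan] * n_n + list(multiple.astype(float)),
            "cyp2e1_activity": list(1500.0 + 200.0 * rng.normal(0, 1, n_n)) + list(cyp),
        }
    )

    # --- detection-limit missingness (low-abundance biased) ----------------
    if config.missing_rate > 0:
        rates = np.clip(
            rng.normal(config.missing_rate, 0.02, n_samples), 0.0, 0.5
        )
        rates[is_peri] *= config.peritumor_missing_factor
        for j in range(n_samples):
            if rates[j] <= 0:
                continue
            cutoff = np.quantile(log2m[:, j], rates[j])
            log2m[log2m[:, j] <= cutoff, j] = np.nan

    matrix = AbundanceMatrix(
        pd.DataFrame(np.exp2(log2m), index=protein_ids, columns=sample_ids),
        scale="linear",
    )

    category_map = {
        pid: CATEGORIES[c]
        for pid, c in zip(protein_ids, rng.integers(0, len(CATEGORIES), config.n_proteins))
    }
    peri_ids = sample_ids[n_n:]
    truth = GroundTruth(
        de_log2fc={protein_ids[i]: float(f) for i, f in zip(de_idx, log2fc)},
        occurrence_markers={protein_ids[i]: category_map[protein_ids[i]] for i in occ_idx},
        progression_markers={
            protein_ids[i]: {"category": category_map[protein_ids[i]], "beta": float(b)}
            for i, b in zip(prog_idx, beta)
        },
        subtype_labels={s: int(lbl) for s, lbl in zip(peri_ids, subtype)},
        category_map=category_map,
        true_linear_predictor={s: float(v) for s, v in zip(peri_ids, lp)},
    )
    return matrix, ClinicalTable(clinical), truth


def write_fixture(
    matrix: AbundanceMatrix,
    clinical: ClinicalTable,
    truth: GroundTruth,
    directory,
) -> dict[str, Path]:
    """Write the cohort to disk: abundance TSV, clinical CSV, ground-truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": directory / "abundance.tsv",
        "clinical": directory / "clinical.csv",
        "ground_truth": directory / "ground_truth.json",
    }
    matrix.write_tsv(paths["abundance"])
    clinical.write_csv(paths["clinical"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth.to_json(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_json(json.load(fh))
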