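"""In-memory containers for the abundance matrix and the clinical table.

Both are thin wrappers around pandas DataFrames that enforce the pipeline's
conventions: proteins are rows and samples are columns of the abundance
matrix (missing = NaN, linear iBAQ-like scale unless log2-transformed), and
the clinical table carries one row per sample with group membership and
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import SurvivalData

NORMAL = "normal"
PERITUMOR = "peritumor"

#: Clinical covariate columns (units documented in the file writers).
CLINICAL_COLUMNS = [
    "sample_id",
    "group",                 # normal | peritumor
    "survival_days",         # follow-up, days (peritumor only)
    "event",                 # 1 = death observed, 0 = censored
    "afp_ng_ml",             # serum alpha-fetoprotein, ng/mL
    "cirrhosis_stage",       # ordinal 0-4
    "max_tumor_diameter_cm",
    "multiple_tumors",       # 1 = multiple, 0 = single
    "cyp2e1_activity",       # pmol/min/mg microsomal protein
]


@dataclass
class AbundanceMatrix:
    """Protein x sample intensity matrix.

    ``data``: DataFrame indexed by protein ID with sample IDs as columns;
    NaN marks a value below the detection limit.  ``scale`` is ``"linear"``
    (non-negative intensities) or ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self):
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale: {self.scale!r}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("protein and sample IDs must be unique")
        if self.scale == "linear":
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("negative intensity on linear scale")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.loc[:, list(sample_ids)], scale=self.scale)

    def subset_proteins(self, protein_ids) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.loc[list(protein_ids)], scale=self.scale)

    # -- TSV dialect: proteins as rows, first column "protein_id", header =
    #    sample IDs, empty cell = missing -----------------------------------

    def write_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t", na_rep="", float_format="%.6g")

    @classmethod
    def read_tsv(cls, path, scale: str = "linear") -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="protein_id")
        return cls(df, scale=scale)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations (group, survival, covariates)."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in ("sample_id", "group") if c not in self.df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if self.df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample IDs in clinical table")
        bad = set(self.df["group"]) - {NORMAL, PERITUMOR}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    @property
    def normal_ids(self) -> list[str]:
        return list(self.df.loc[self.df["group"] == NORMAL, "sample_id"])

    @property
    def peritumor_ids(self) -> list[str]:
        return list(self.df.loc[self.df["group"] == PERITUMOR, "sample_id"])

    def group_labels(self, sample_ids) -> np.ndarray:
        """1 for peritumor, 0 for normal, aligned to ``sample_ids``."""
        lookup = dict(zip(self.df["sample_id"], self.df["group"]))
        return np.array([1 if lookup[s] == PERITUMOR else 0 for s in sample_ids])

    def survival(self, sample_ids=None) -> SurvivalData:
        """Survival outcomes for the peritumor samples (or a subset of them)."""
        sub = self.df[self.df["group"] == PERITUMOR]
        if sample_ids is not None:
            sub = sub.set_index("sample_id").loc[list(sample_ids)].reset_index()
        sub = sub.dropna(subset=["survival_days", "event"])
        return SurvivalData(
            sub["survival_days"].to_numpy(dtype=float),
            sub["event"].to_numpy(dtype=int),
        )

    def covariate(self, name: str, sample_ids) -> np.ndarray:
        lookup = dict(zip(self.df["sample_id"], self.df[name]))
        return np.array([lookup[s] for s in sample_ids], dtype=float)

    def write_csv(self, path) -> None:
        cols = [c for c in CLINICAL_COLUMNS if c in self.df.columns]
        cols += [c for c in self.df.columns if c not in cols]
        self.df[cols].to_csv(path, index=False, na_rep="")

    @classmethod
    def read_csv(cls, path) -> "ClinicalTable":
        return cls(pd.read_csv(path))
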