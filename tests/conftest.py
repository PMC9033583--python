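import numpy as np
import pandas as pd
import pytest

from pmekit.containers import AbundanceMatrix, ClinicalTable
from pmekit.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort exercising every planted structure."""
    cfg = CohortConfig(
        n_proteins=600,
        n_de=150,
        n_occurrence_markers=20,
        n_progression_markers=26,
        n_shared_markers=2,
        subtype_block_size=25,
        seed=11,
    )
    matrix, clinical, truth = generate_cohort(cfg)
    return cfg, matrix, clinical, truth


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort):
    from pmekit.preprocess import preprocess_pipeline

    cfg, matrix, clinical, truth = small_cohort
    return cfg, preprocess_pipeline(matrix), clinical, truth


@pytest.fixture
def toy_matrix():
    """4 proteins x 4 samples with missingness, linear scale."""
    data = pd.DataFrame(
        {
            "s1": [2.0, np.nan, 4.0, 1.0],
            "s2": [np.nan, 5.0, 4.0, 2.0],
            "s3": [8.0, np.nan, 4.0, 3.0],
            "s4": [4.0, np.nan, 4.0, 4.0],
        },
        index=["pA", "pB", "pC", "pD"],
    )
    return AbundanceMatrix(data)


def make_clinical(n_normal, n_peritumor, rng=None):
    rng = rng or np.random.default_rng(0)
    n = n_normal + n_peritumor
    ids = [f"N{i}" for i in range(n_normal)] + [f"T{i}" for i in range(n_peritumor)]
    df = pd.DataFrame(
        {
            "sample_id": ids,
            "group": ["normal"] * n_normal + ["peritumor"] * n_peritumor,
            "survival_days": [np.nan] * n_normal
            + list(rng.integers(30, 1600, n_peritumor).astype(float)),
            "event": [np.nan] * n_normal + list(rng.integers(0, 2, n_peritumor).astype(float)),
            "afp_ng_ml": rng.lognormal(4, 1, n),
            "cirrhosis_stage": rng.integers(0, 5, n),
            "cyp2e1_activity": rng.normal(1350, 250, n),
        }
    )
    return ClinicalTable(df)
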