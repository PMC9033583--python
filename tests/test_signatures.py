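"""Signature selection, overlap arithmetic and risk-index aggregation."""

import numpy as np
import pandas as pd
import pytest

from pmekit.differential import differential_test
from pmekit.signatures import (
    SignatureProtein,
    compare_category_ri,
    compute_risk_profiles,
    ri_clinical_association,
    select_occurrence_signature,
    select_progression_signature,
    signature_overlap,
)


def make_sig(ids, arm, category="immunity", direction="up"):
    kw = {"auc": 0.9} if arm == "occurrence" else {"logrank_p": 0.01}
    return [SignatureProtein(i, arm, category, direction, **kw) for i in ids]


class TestOverlap:
    def test_study_arithmetic(self):
        occ = make_sig([f"o{i}" for i in range(37)] + ["s1", "s2", "s3"], "occurrence")
        prog = make_sig([f"p{i}" for i in range(49)] + ["s1", "s2", "s3"], "progression")
        ov = signature_overlap(occ, prog)
        assert (ov["n_shared"], ov["n_union"]) == (3, 89)
        assert ov["overlap_percent"] == 3.37

    def test_disjoint_and_identical(self):
        occ = make_sig(["a", "b"], "occurrence")
        assert signature_overlap(occ, make_sig(["c"], "progression"))["overlap_percent"] == 0.0
        same = make_sig(["a", "b"], "progression")
        assert signature_overlap(occ, same)["overlap_percent"] == 100.0


@pytest.fixture(scope="module")
def diffed(small_preprocessed):
    cfg, pre, clinical, truth = small_preprocessed
    return cfg, pre, clinical, truth, differential_test(pre, clinical)


class TestOccurrenceSelection:
    def test_planted_markers_rank_first(self):
        """At the study scale the planted markers dominate the signature."""
        from pmekit.preprocess import preprocess_pipeline
        from pmekit.simulate import CohortConfig, generate_cohort

        cfg = CohortConfig(seed=11)
        matrix, clinical, truth = generate_cohort(cfg)
        pre = preprocess_pipeline(matrix)
        diff = differential_test(pre, clinical)
        sig = select_occurrence_signature(
            diff, pre, clinical, truth.category_map, auc_min=0.8, max_n=cfg.n_occurrence_markers
        )
        assert 0 < len(sig) <= cfg.n_occurrence_markers
        picked = {p.protein_id for p in sig}
        planted = set(truth.occurrence_markers) & set(pre.protein_ids)
        recall = len(picked & planted) / len(planted)
        assert recall >= 0.9

    def test_auc_floor_enforced(self, diffed):
        cfg, pre, clinical, truth, diff = diffed
        sig = select_occurrence_signature(diff, pre, clinical, truth.category_map, auc_min=0.8)
        assert all(max(p.auc, 1 - p.auc) >= 0.8 for p in sig)

    def test_noisy_data_with_impossible_floor_warns_empty(self):
        rng = np.random.default_rng(0)
        from pmekit.containers import AbundanceMatrix
        from conftest import make_clinical

        clin = make_clinical(10, 10)
        m = AbundanceMatrix(
            pd.DataFrame(rng.normal(10, 1, (5, 20)), columns=clin.sample_ids,
                         index=[f"p{i}" for i in range(5)]),
            scale="log2",
        )
        diff = pd.DataFrame(
            {
                "protein_id": m.protein_ids,
                "fold_change": 2.0,
                "log2fc": 1.0,
                "p_value": 0.001,
                "direction": "up",
                "significant": True,
            }
        )
        cmap = {p: "immunity" for p in m.protein_ids}
        with pytest.warns(UserWarning, match="empty"):
            out = select_occurrence_signature(diff, m, clin, cmap, auc_min=0.999)
        assert out == []

    def test_cap_respected(self, diffed):
        cfg, pre, clinical, truth, diff = diffed
        sig = select_occurrence_signature(diff, pre, clinical, truth.category_map, max_n=5)
        assert len(sig) <= 5


class TestProgressionSelection:
    def test_planted_hazard_markers_recovered(self):
        """Strong planted hazards are recovered by the median-split log-rank screen."""
        from pmekit.preprocess import preprocess_pipeline
        from pmekit.simulate import CohortConfig, generate_cohort

        hits, total = 0, 0
        for seed in range(3):
            cfg = CohortConfig(
                n_proteins=400, n_de=80, n_occurrence_markers=5,
                n_progression_markers=3, n_shared_markers=1,
                hazard_betas=(1.2, 1.2, 1.2),
                n_subtypes=1, seed=100 + seed,
            )
            matrix, clinical, truth = generate_cohort(cfg)
            pre = preprocess_pipeline(matrix)
            diff = differential_test(pre, clinical)
            sig = select_progression_signature(diff, pre, clinical, truth.category_map)
            picked = {p.protein_id for p in sig}
            planted = set(truth.progression_markers) & set(pre.protein_ids)
            hits += len(picked & planted)
            total += len(planted)
        assert hits / total >= 0.8

    def test_shuffled_survival_false_positive_rate(self, diffed):
        cfg, pre, clinical, truth, diff = diffed
        from pmekit.containers import ClinicalTable

        rng = np.random.default_rng(0)
        shuffled = clinical.df.copy()
        peri = shuffled["group"] == "peritumor"
        perm = rng.permutation(np.nonzero(peri.to_numpy())[0])
        shuffled.loc[peri, "survival_days"] = shuffled["survival_days"].to_numpy()[perm]
        shuffled.loc[peri, "event"] = shuffled["event"].to_numpy()[perm]
        sig = select_progression_signature(
            diff, pre, ClinicalTable(shuffled), truth.category_map, max_n=10**6
        )
        n_sig_diff = int(diff["significant"].sum())
        rate = len(sig) / n_sig_diff
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sig_diff)

    def test_constant_protein_excluded(self, small_preprocessed):
        cfg, pre, clinical, truth = small_preprocessed
        m2 = pre.data.copy()
        m2.iloc[0] = 5.0  # constant across samples
        from pmekit.containers import AbundanceMatrix

        mat = AbundanceMatrix(m2, scale="log2")
        diff = pd.DataFrame(
            {
                "protein_id": [m2.index[0]],
                "fold_change": [2.0],
                "log2fc": [1.0],
                "p_value": [0.001],
                "direction": ["up"],
                "significant": [True],
            }
        )
        sig = select_progression_signature(diff, mat, clinical, truth.category_map)
        assert sig == []


class TestRiskProfiles:
    def test_monotonicity_and_bounds(self, diffed):
        cfg, pre, clinical, truth, diff = diffed
        sig = select_occurrence_signature(diff, pre, clinical, truth.category_map)
        profiles, summary = compute_risk_profiles(sig, pre, clinical)
        assert len(profiles) == len(clinical.peritumor_ids)
        cat_cols = [c for c in profiles.columns if c.startswith("ri_") and c != "ri_group"]
        assert np.allclose(profiles[cat_cols].sum(axis=1), profiles["total_ri"])
        assert (profiles[cat_cols] >= -1e-9).all().all()
        max_possible = sum(p.weight * 10 for p in sig)
        assert (profiles["total_ri"] <= max_possible + 1e-9).all()
        assert summary["min"] <= summary["mean"] <= summary["max"]

    def test_extreme_patient_attains_maximum(self):
        sig = make_sig(["pa", "pb"], "occurrence")
        vals = pd.DataFrame(
            {"T1": [1.0, 2.0], "T2": [5.0, 9.0], "T3": [3.0, 4.0]}, index=["pa", "pb"]
        )
        from pmekit.containers import AbundanceMatrix, ClinicalTable

        m = AbundanceMatrix(vals, scale="log2")
        clin = ClinicalTable(
            pd.DataFrame(
                {
                    "sample_id": ["T1", "T2", "T3"],
                    "group": ["peritumor"] * 3,
                    "survival_days": [100.0, 200.0, 300.0],
                    "event": [1.0, 1.0, 0.0],
                }
            )
        )
        profiles, _ = compute_risk_profiles(sig, m, clin)
        # T2 is at the cohort maximum for both up-regulated markers
        assert profiles.set_index("sample_id")["total_ri"].idxmax() == "T2"

    def test_identical_patients_flagged_degenerate(self):
        sig = make_sig(["pa"], "occurrence")
        vals = pd.DataFrame({"T1": [3.0], "T2": [3.0], "T3": [3.0]}, index=["pa"])
        from pmekit.containers import AbundanceMatrix, ClinicalTable

        m = AbundanceMatrix(vals, scale="log2")
        clin = ClinicalTable(
            pd.DataFrame(
                {
                    "sample_id": ["T1", "T2", "T3"],
                    "group": ["peritumor"] * 3,
                    "survival_days": [10.0, 20.0, 30.0],
                    "event": [1.0, 0.0, 1.0],
                }
            )
        )
        with pytest.warns(UserWarning, match="degenerate"):
            profiles, summary = compute_risk_profiles(sig, m, clin)
        assert summary["degenerate_split"]

    def test_empty_signature_errors(self, small_preprocessed):
        _, pre, clinical, _ = small_preprocessed
        with pytest.raises(ValueError, match="empty"):
            compute_risk_profiles([], pre, clinical)

    def test_planted_risk_enrichment(self):
        """Patients in the top tercile of the generating linear predictor land
        in the high-RI group more often than chance (pooled over seeds)."""
        from pmekit.preprocess import preprocess_pipeline
        from pmekit.simulate import CohortConfig, generate_cohort
        from pmekit.stats import fisher_exact

        pooled = np.zeros((2, 2), dtype=int)
        for seed in (11, 12, 13):
            cfg = CohortConfig(
                n_proteins=800, n_de=150, n_occurrence_markers=10,
                n_progression_markers=8, n_shared_markers=1,
                hazard_betas=(0.9,) * 8, n_subtypes=1, seed=seed,
            )
            matrix, clinical, truth = generate_cohort(cfg)
            pre = preprocess_pipeline(matrix)
            diff = differential_test(pre, clinical)
            sig = select_progression_signature(diff, pre, clinical, truth.category_map)
            profiles, _ = compute_risk_profiles(sig, pre, clinical)
            lp = np.array([truth.true_linear_predictor[s] for s in profiles["sample_id"]])
            top = lp >= np.quantile(lp, 2 / 3)
            high = (profiles["ri_group"] == "high").to_numpy()
            pooled += np.array(
                [
                    [int((top & high).sum()), int((top & ~high).sum())],
                    [int((~top & high).sum()), int((~top & ~high).sum())],
                ]
            )
        assert fisher_exact(pooled) < 0.01


class TestClinicalAssociation:
    def test_self_association_is_certain(self, diffed):
        cfg, pre, clinical, truth, diff = diffed
        sig = select_occurrence_signature(diff, pre, clinical, truth.category_map)
        profiles, _ = compute_risk_profiles(sig, pre, clinical)
        proxy = clinical.df.copy()
        lookup = dict(zip(profiles["sample_id"], profiles["total_ri"]))
        proxy["ri_proxy"] = proxy["sample_id"].map(lookup)
        from pmekit.containers import ClinicalTable

        cutoff = float(np.nanmedian(proxy["ri_proxy"]))
        res = ri_clinical_association(profiles, ClinicalTable(proxy), "ri_proxy", cutoff)
        assert res["fisher_p"] < 1e-6

    def test_cutoff_outside_range_flagged(self, diffed):
        cfg, pre, clinical, truth, diff = diffed
        sig = select_occurrence_signature(diff, pre, clinical, truth.category_map)
        profiles, _ = compute_risk_profiles(sig, pre, clinical)
        res = ri_clinical_association(profiles, clinical, "afp_ng_ml", 1e12)
        assert res["degenerate"]
        assert res["fisher_p"] == 1.0


class TestCategoryComparison:
    def test_equal_categories_give_null(self):
        profiles = pd.DataFrame(
            {
                "sample_id": [f"T{i}" for i in range(8)],
                "ri_immunity": np.arange(8.0),
                "ri_inflammation": np.arange(8.0),
            }
        )
        res = compare_category_ri(profiles)
        assert res["omnibus_p"] == 1.0

    def test_dominant_category_ranks_first(self):
        """A category whose proteins carry 3x the selection weight tops the
        ranking in (almost) every seed."""
        from pmekit.containers import AbundanceMatrix, ClinicalTable
        from pmekit.simulate import CATEGORIES

        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(400 + seed)
            n_prot, n_pat = 12, 30
            ids = [f"p{i}" for i in range(n_prot)]
            # 2 proteins per category; immunity carries weight 0.9, others 0.3
            sig = []
            for i, pid in enumerate(ids):
                cat = CATEGORIES[i % 6]
                auc = 0.95 if cat == "immunity" else 0.65
                sig.append(SignatureProtein(pid, "occurrence", cat, "up", auc=auc))
            vals = pd.DataFrame(
                rng.normal(10, 1, (n_prot, n_pat)),
                index=ids, columns=[f"T{j}" for j in range(n_pat)],
            )
            m = AbundanceMatrix(vals, scale="log2")
            clin = ClinicalTable(
                pd.DataFrame(
                    {
                        "sample_id": vals.columns,
                        "group": "peritumor",
                        "survival_days": rng.integers(30, 1000, n_pat).astype(float),
                        "event": rng.integers(0, 2, n_pat).astype(float),
                    }
                )
            )
            profiles, _ = compute_risk_profiles(sig, m, clin)
            res = compare_category_ri(profiles)
            if res["category_order"][0] == "immunity":
                wins += 1
            assert res["means"][res["category_order"][0]] == max(res["means"].values())
        assert wins >= n_seeds - 1
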