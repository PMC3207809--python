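"""Spearman-filter integration: pair correlations, retention decisions,
assembly, and the training-only (no-leakage) guarantees."""

import numpy as np
import pandas as pd
import pytest

from omicox import (
    FeatureMatrix,
    IntegrationConfig,
    SimConfig,
    SpearmanIntegrator,
    assemble_integrated,
    filter_features,
    simulate_cohort,
    spearman_pairs,
)


def _fm(values, platform, samples=None, features=None):
    values = np.asarray(values, float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    features = features or [f"f{j}" for j in range(values.shape[1])]
    return FeatureMatrix(pd.DataFrame(values, index=samples, columns=features), platform)


class TestSpearmanPairs:
    def test_exact_copy_has_rho_one(self, rng):
        vals = rng.standard_normal((20, 3))
        mrna = _fm(vals, "mRNA")
        cna = _fm(vals, "CNA")
        tab = spearman_pairs(mrna, cna)
        assert np.allclose(tab["rho"], 1.0)

    def test_negation_has_rho_minus_one(self, rng):
        vals = rng.standard_normal((20, 2))
        tab = spearman_pairs(_fm(vals, "mRNA"), _fm(-vals, "METH"))
        assert np.allclose(tab["rho"], -1.0)

    def test_matches_rank_then_pearson_on_toy_pair(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        tab = spearman_pairs(_fm(a[:, None], "mRNA"), _fm(b[:, None], "CNA"))
        ra = pd.Series(a).rank().to_numpy()
        rb = pd.Series(b).rank().to_numpy()
        expected = np.corrcoef(ra, rb)[0, 1]
        assert tab["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_unmapped_features_excluded(self, rng):
        mrna = _fm(rng.standard_normal((10, 2)), "mRNA", features=["g1", "g2"])
        cna = _fm(rng.standard_normal((10, 3)), "CNA", features=["g1", "g2", "g9"])
        tab = spearman_pairs(mrna, cna)
        assert set(tab["feature"]) == {"g1", "g2"}

    def test_mirna_requires_pairing(self, rng):
        mrna = _fm(rng.standard_normal((10, 2)), "mRNA")
        mir = _fm(rng.standard_normal((10, 2)), "miRNA")
        with pytest.raises(ValueError):
            spearman_pairs(mrna, mir, pairing=None)


class TestFilterFeatures:
    def test_cutoff_zero_retains_all_mapped(self, rng):
        tab = pd.DataFrame({"feature": ["a", "b"], "gene": ["g", "g"],
                            "rho": [0.01, -0.9]})
        cfg = IntegrationConfig(cutoff_cna=0.0)
        out = filter_features(tab, "CNA", cfg)
        assert out["retained"].all()

    def test_cutoff_one_retains_only_perfect_rank_duplicates(self, rng):
        tab = pd.DataFrame({"feature": ["a", "b"], "gene": ["g", "g"],
                            "rho": [1.0, 0.999]})
        out = filter_features(tab, "CNA", IntegrationConfig(cutoff_cna=1.0))
        assert bool(out.loc["a", "retained"]) and not bool(out.loc["b", "retained"])

    def test_signed_policy_rejects_wrong_sign(self):
        tab = pd.DataFrame({"feature": ["a", "b"], "gene": ["g", "g"],
                            "rho": [0.8, -0.8]})
        out = filter_features(tab, "CNA",
                              IntegrationConfig(cutoff_cna=0.5, sign_policy="signed"))
        assert bool(out.loc["a", "retained"]) and not bool(out.loc["b", "retained"])

    def test_best_match_is_max_abs_rho(self):
        tab = pd.DataFrame({"feature": ["m"] * 3, "gene": ["g1", "g2", "g3"],
                            "rho": [-0.6, 0.2, 0.5]})
        out = filter_features(tab, "miRNA", IntegrationConfig(cutoff_mirna=0.55))
        assert out.loc["m", "best_gene"] == "g1"
        assert bool(out.loc["m", "retained"])

    def test_causal_cna_retained_under_generator(self):
        hits = 0
        for seed in range(5):
            cfg = SimConfig(n_samples=300, n_genes=20, n_mirnas=0,
                            causal_features=[("CNA", 0, 0.5)], rho_cna=0.9, seed=seed)
            cohort = simulate_cohort(cfg)
            fms = {p: FeatureMatrix(df, p) for p, df in cohort.platforms.items()}
            integ = SpearmanIntegrator(IntegrationConfig(cutoff_cna=0.5)).fit(fms)
            if "G0000" in integ.retained_["CNA"]:
                hits += 1
        assert hits == 5


class TestAssemble:
    def test_single_platform_identity_pass_through(self, rng):
        from omicox import SurvivalOutcome

        vals = rng.standard_normal((10, 4))
        fms = {"mRNA": _fm(vals, "mRNA")}
        y = SurvivalOutcome(rng.exponential(40, 10) + 0.1, np.ones(10, int))
        ds = assemble_integrated(fms, {}, y, np.ones(10, bool))
        assert np.allclose(ds.features.to_numpy(), vals)

    def test_feature_count_conservation(self, rng):
        from omicox import SurvivalOutcome

        fms = {
            "mRNA": _fm(rng.standard_normal((12, 5)), "mRNA"),
            "CNA": _fm(rng.standard_normal((12, 5)), "CNA"),
        }
        y = SurvivalOutcome(rng.exponential(40, 12) + 0.1, np.ones(12, int))
        ds = assemble_integrated(fms, {"CNA": ["f0", "f3"]}, y, np.ones(12, bool))
        assert ds.features.shape[1] == 5 + 2

    def test_sample_axis_mismatch_lists_offenders(self, rng):
        from omicox import SurvivalOutcome

        fms = {
            "mRNA": _fm(rng.standard_normal((5, 2)), "mRNA"),
            "CNA": _fm(rng.standard_normal((5, 2)), "CNA",
                       samples=[f"x{i}" for i in range(5)]),
        }
        y = SurvivalOutcome(np.ones(5), np.ones(5, int))
        with pytest.raises(ValueError, match="x0"):
            assemble_integrated(fms, {"CNA": ["f0"]}, y, np.ones(5, bool))

    def test_missing_values_imputed_with_training_medians(self, rng):
        from omicox import SurvivalOutcome

        vals = rng.standard_normal((10, 2))
        vals[7, 0] = np.nan  # test-side missing entry
        fms = {"mRNA": _fm(vals, "mRNA")}
        y = SurvivalOutcome(rng.exponential(40, 10) + 0.1, np.ones(10, int))
        mask = np.r_[np.ones(6, bool), np.zeros(4, bool)]
        ds = assemble_integrated(fms, {}, y, mask)
        assert ds.features.iloc[7, 0] == pytest.approx(np.median(vals[:6, 0]))


class TestNoLeakage:
    def _cohort_fms(self, seed=0):
        cfg = SimConfig(n_samples=120, n_genes=15, n_mirnas=5, seed=seed)
        cohort = simulate_cohort(cfg)
        fms = {p: FeatureMatrix(df.copy(), p) for p, df in cohort.platforms.items()}
        return cohort, fms

    def test_test_samples_never_influence_retention_or_standardization(self):
        cohort, fms = self._cohort_fms()
        n = len(cohort.outcomes)
        mask = np.zeros(n, bool)
        mask[: n // 2] = True
        integ1 = SpearmanIntegrator().fit_transform(fms, cohort.outcomes,
                                                    cohort.pairing, mask)
        # perturb every test-sample value
        fms2 = {
            p: FeatureMatrix(
                fm.values.mask(~pd.Series(mask, index=fm.values.index),
                               fm.values + 5.0),
                p,
            )
            for p, fm in fms.items()
        }
        integ2 = SpearmanIntegrator().fit_transform(fms2, cohort.outcomes,
                                                    cohort.pairing, mask)
        pd.testing.assert_frame_equal(integ1.retention, integ2.retention)
        pd.testing.assert_series_equal(integ1.train_mean, integ2.train_mean)
        pd.testing.assert_series_equal(integ1.train_std, integ2.train_std)

    def test_retained_set_invariant_to_feature_order(self):
        cohort, fms = self._cohort_fms(seed=1)
        mask = np.ones(len(cohort.outcomes), bool)
        r1 = SpearmanIntegrator().fit(fms, cohort.pairing, mask).retained_
        fms_rev = {
            p: FeatureMatrix(fm.values[list(fm.values.columns)[::-1]], p)
            for p, fm in fms.items()
        }
        r2 = SpearmanIntegrator().fit(fms_rev, cohort.pairing, mask).retained_
        for p in r1:
            assert sorted(r1[p]) == sorted(r2[p])


class TestConfigValidation:
    def test_cutoffs_must_be_in_unit_interval(self):
        with pytest.raises(ValueError):
            IntegrationConfig(cutoff_meth=1.2)

    def test_unknown_sign_policy_rejected(self):
        with pytest.raises(ValueError):
            IntegrationConfig(sign_policy="positive")
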