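"""Per-SNP trio associations, harmonization, and summary-data estimators."""

import numpy as np
import pandas as pd
import pytest

from triomr import SimConfig, simulate_trio_cohort
from triomr.snpmr import (SnpAssociationSet, estimate_snp_outcome_associations,
                          harmonize, ivw, mr_egger, run_all_estimators,
                          wald_ratio, wald_ratios, weighted_median,
                          weighted_mode)


def _assoc(bx, by, sx=None, sy=None, alleles=None):
    k = len(bx)
    return SnpAssociationSet(pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(k)],
        "beta_exposure": bx, "se_exposure": sx or [0.01] * k,
        "beta_outcome": by, "se_outcome": sy or [0.02] * k,
        "effect_allele": alleles or ["G"] * k}))


class TestSnpOutcomeAssociations:
    def test_null_outcome_is_calibrated(self):
        cfg = SimConfig(n_couples=3000, n_snps=40, exposure_effect=0.0,
                        dynastic_effect_mother=0.0, dynastic_effect_father=0.0,
                        seed=17)
        cohort = simulate_trio_cohort(cfg)
        out = estimate_snp_outcome_associations(cohort, "mother")
        z = out["beta"] / out["se"]
        assert abs(out["beta"].mean()) < 0.02
        assert (np.abs(z) > 1.96).mean() < 0.20  # ~5% expected, 40 SNPs

    def test_planted_mother_signal_recovered(self):
        cfg = SimConfig(n_couples=4000, n_snps=3, exposure_effect=0.0,
                        dynastic_effect_mother=0.0, dynastic_effect_father=0.0,
                        noise_sd_outcome=0.1, seed=23)
        cohort = simulate_trio_cohort(cfg)
        ph = cohort.phenotypes.copy()
        ph["outcome_child"] = (0.3 * cohort.dosage_mother[:, 0]
                               + 0.1 * np.random.default_rng(0).normal(
                                   size=cfg.n_couples))
        cohort.phenotypes = ph
        out = estimate_snp_outcome_associations(cohort, "mother")
        assert out.loc[0, "beta"] == pytest.approx(0.3, abs=0.02)
        assert np.allclose(out.loc[1:, "beta"], 0.0, atol=0.02)

    def test_eight_row_fixture_matches_normal_equations(self):
        cfg = SimConfig(n_couples=8, n_snps=2, seed=5)
        cohort = simulate_trio_cohort(cfg)
        cohort.validate_transmission()
        out = estimate_snp_outcome_associations(cohort, "father")
        y = cohort.phenotypes["outcome_child"].to_numpy()
        for _, row in out.iterrows():
            j = cohort.variant_ids.index(row["variant_id"])
            X = np.column_stack([np.ones(8),
                                 cohort.dosage_child[:, j],
                                 cohort.dosage_mother[:, j],
                                 cohort.dosage_father[:, j]])
            beta = np.linalg.inv(X.T @ X) @ X.T @ y
            assert row["beta"] == pytest.approx(beta[3], abs=1e-10)

    def test_monomorphic_variant_dropped_not_fatal(self, caplog):
        cfg = SimConfig(n_couples=50, n_snps=2, seed=1)
        cohort = simulate_trio_cohort(cfg)
        for d in (cohort.dosage_mother, cohort.dosage_father,
                  cohort.dosage_child):
            d[:, 0] = 1  # force monomorphic first variant
        out = estimate_snp_outcome_associations(cohort, "mother")
        assert out["variant_id"].tolist() == ["snp2"]


class TestHarmonize:
    def _panel(self, ea="G", oa="A", freq=0.3):
        return pd.DataFrame({"variant_id": ["rs1"], "effect_allele": [ea],
                             "other_allele": [oa], "weight": [0.2],
                             "se": [0.01], "effect_allele_freq": [freq]})

    def _outcome(self, ea=None, oa=None):
        d = {"variant_id": ["rs1"], "beta": [0.1], "se": [0.02]}
        if ea:
            d["effect_allele"] = [ea]
            d["other_allele"] = [oa]
        return pd.DataFrame(d)

    def test_identical_alleles_unchanged(self):
        a = harmonize(self._panel(), self._outcome("G", "A"))
        assert a.table.loc[0, "beta_outcome"] == 0.1
        assert a.n_flipped == 0

    def test_swapped_alleles_negate_outcome_beta(self):
        a = harmonize(self._panel(), self._outcome("A", "G"))
        assert a.table.loc[0, "beta_outcome"] == -0.1
        assert a.n_flipped == 1

    def test_strand_complement_recognised(self):
        a = harmonize(self._panel("G", "A"), self._outcome("C", "T"))
        assert a.table.loc[0, "beta_outcome"] == 0.1

    def test_palindrome_at_half_frequency_dropped(self):
        a = harmonize(self._panel("A", "T", freq=0.5), self._outcome())
        assert len(a) == 0 and a.n_dropped == 1

    def test_palindrome_with_informative_frequency_kept(self):
        a = harmonize(self._panel("A", "T", freq=0.10), self._outcome())
        assert len(a) == 1

    def test_irreconcilable_alleles_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="irreconcilable"):
            a = harmonize(self._panel("G", "A"), self._outcome("G", "C"))
        assert len(a) == 0 and a.n_dropped == 1


class TestIvw:
    def test_single_snp_reduces_to_wald_ratio(self):
        a = _assoc([0.2], [0.1])
        r = ivw(a)
        assert r.estimate == pytest.approx(0.5)
        assert r.se == pytest.approx(0.02 / 0.2)

    def test_homogeneous_set_recovers_common_ratio(self):
        a = _assoc([0.1, 0.2, 0.4], [0.05, 0.10, 0.20])
        r = ivw(a)
        assert r.estimate == pytest.approx(0.5, abs=1e-12)
        assert r.q_statistic == pytest.approx(0.0, abs=1e-18)

    def test_five_snp_hand_sigma_formula(self, five_snp_table):
        a = SnpAssociationSet(five_snp_table)
        bx = five_snp_table["beta_exposure"].to_numpy()
        by = five_snp_table["beta_outcome"].to_numpy()
        w = 1 / five_snp_table["se_outcome"].to_numpy() ** 2
        slope = np.sum(w * bx * by) / np.sum(w * bx ** 2)
        q = np.sum(w * (by - slope * bx) ** 2)
        se = np.sqrt(max(1.0, q / 4) / np.sum(w * bx ** 2))
        r = ivw(a)
        assert r.estimate == pytest.approx(slope, abs=1e-14)
        assert r.se == pytest.approx(se, abs=1e-14)
        assert r.q_statistic == pytest.approx(q, abs=1e-12)


class TestEgger:
    def test_requires_three_snps(self):
        with pytest.raises(ValueError):
            mr_egger(_assoc([0.1, 0.2], [0.05, 0.1]))

    def test_no_pleiotropy_limit_matches_ivw(self):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.1, 0.4, 30)
        by = 0.7 * bx + rng.normal(0, 0.02, 30)
        a = _assoc(bx.tolist(), by.tolist())
        e, i_ = mr_egger(a), ivw(a)
        assert e.intercept == pytest.approx(0.0, abs=3 * e.intercept_se)
        assert e.estimate == pytest.approx(i_.estimate, abs=0.15)

    def test_fixture_matches_weighted_least_squares_closed_form(self, five_snp_table):
        a = SnpAssociationSet(five_snp_table)
        r = mr_egger(a)
        bx = five_snp_table["beta_exposure"].to_numpy()
        by = five_snp_table["beta_outcome"].to_numpy()
        w = 1 / five_snp_table["se_outcome"].to_numpy() ** 2
        X = np.column_stack([np.ones(5), bx])
        xtx = X.T @ (X * w[:, None])
        coef = np.linalg.solve(xtx, (X * w[:, None]).T @ by)
        assert r.intercept == pytest.approx(coef[0], abs=1e-14)
        assert r.estimate == pytest.approx(coef[1], abs=1e-14)

    def test_planted_directional_pleiotropy_recovered(self):
        # alpha_j = 0.05 on every SNP: Egger intercept ~ 0.05, slope less
        # biased than IVW (200-rep Monte Carlo)
        rng = np.random.default_rng(42)
        icpts, egger_err, ivw_err = [], [], []
        for _ in range(200):
            bx = rng.uniform(0.1, 0.5, 25)
            by = 1.0 * bx + 0.05 + rng.normal(0, 0.02, 25)
            a = _assoc(bx.tolist(), by.tolist())
            e = mr_egger(a)
            icpts.append(e.intercept)
            egger_err.append(e.estimate - 1.0)
            ivw_err.append(ivw(a).estimate - 1.0)
        assert np.mean(icpts) == pytest.approx(0.05, abs=0.01)
        assert abs(np.mean(egger_err)) < abs(np.mean(ivw_err))

    def test_orientation_invariance(self):
        # flipping a variant's alleles (bx, by both negated) changes nothing
        bx = [0.1, -0.2, 0.3, 0.25]
        by = [0.05, -0.11, 0.16, 0.12]
        a = _assoc(bx, by)
        b = _assoc([abs(v) for v in bx], [s * (1 if x > 0 else -1)
                                          for s, x in zip(by, bx)])
        assert mr_egger(a).estimate == pytest.approx(mr_egger(b).estimate)
        assert mr_egger(a).intercept == pytest.approx(mr_egger(b).intercept)


class TestWeightedMedian:
    def test_equal_weight_odd_set_is_middle_ratio(self):
        a = _assoc([0.1, 0.1, 0.1], [0.1, 0.2, 0.9])  # ratios 1, 2, 9
        r = weighted_median(a, n_boot=200, seed=1)
        assert r.estimate == pytest.approx(2.0)

    def test_four_snp_cumulative_interpolation_hand_example(self):
        # ratios 1,2,3,4 with weights 0.1,0.2,0.3,0.4 (via se_outcome);
        # normalized cumulative midpoints 0.05,0.20,0.45,0.80;
        # 0.5 interpolates between ratios 3 and 4: 3 + (0.5-0.45)/0.35
        bx = [1.0, 1.0, 1.0, 1.0]
        by = [1.0, 2.0, 3.0, 4.0]
        sy = [np.sqrt(1 / w) for w in (0.1, 0.2, 0.3, 0.4)]
        r = weighted_median(_assoc(bx, by, sy=sy), n_boot=200, seed=1)
        assert r.estimate == pytest.approx(3 + 0.05 / 0.35, abs=1e-10)

    def test_breakdown_bound_49_percent_invalid_weight(self):
        # 49 of 100 equal-weight SNPs are pleiotropic (ratio 1.5), 51 are
        # valid (ratio exactly 1).  Below the 50% breakdown the weighted
        # median sits entirely inside the valid mass and recovers the
        # truth exactly, while IVW is dragged toward the invalid group.
        bx = [1.0] * 100
        by = [1.0] * 51 + [1.5] * 49
        a = _assoc(bx, by, sy=[0.1] * 100)
        assert weighted_median(a, n_boot=100, seed=2).estimate == \
            pytest.approx(1.0, abs=1e-12)
        assert ivw(a).estimate == pytest.approx(1.0 + 0.49 * 0.5, abs=1e-12)

    def test_less_biased_than_ivw_under_noisy_invalid_minority(self):
        # noisy version of the breakdown scenario, 200-rep Monte Carlo:
        # the median's bias is a small fraction of IVW's
        import warnings as _w
        rng = np.random.default_rng(7)
        med_est, ivw_est = [], []
        for _ in range(200):
            bx = np.full(20, 1.0)
            by = np.concatenate([1.0 + rng.normal(0, 0.05, 11),
                                 1.5 + rng.normal(0, 0.05, 9)])
            a = _assoc(bx.tolist(), by.tolist(), sy=[0.05] * 20)
            with _w.catch_warnings():
                _w.simplefilter("ignore", UserWarning)
                med_est.append(weighted_median(a, n_boot=1, seed=1).estimate)
            ivw_est.append(ivw(a).estimate)
        med_bias = abs(np.mean(med_est) - 1.0)
        ivw_bias = abs(np.mean(ivw_est) - 1.0)
        assert ivw_bias > 0.15
        assert med_bias < 0.4 * ivw_bias

    def test_boot_validation(self):
        a = _assoc([0.1, 0.2, 0.3], [0.05, 0.1, 0.15])
        with pytest.raises(ValueError):
            weighted_median(a, n_boot=0)
        with pytest.warns(UserWarning, match="n_boot"):
            weighted_median(a, n_boot=50, seed=0)


class TestWeightedMode:
    def test_identical_ratios_for_any_bandwidth(self):
        a = _assoc([0.1, 0.2, 0.4], [0.05, 0.10, 0.20])  # all ratios 0.5
        for bw in (0.3, 1.0, 3.0):
            r = weighted_mode(a, bandwidth_factor=bw, n_boot=50, seed=0)
            assert r.estimate == pytest.approx(0.5, abs=1e-6)

    def test_plurality_at_ratio_one_wins(self):
        rng = np.random.default_rng(9)
        bx = np.full(20, 0.2)
        by = np.concatenate([0.2 * np.ones(12) + rng.normal(0, 0.002, 12),
                             0.2 * rng.uniform(2, 6, 8)])
        r = weighted_mode(_assoc(bx.tolist(), by.tolist()), n_boot=50, seed=0)
        assert r.estimate == pytest.approx(1.0, abs=0.1)

    def test_bandwidth_sensitivity_is_continuous(self):
        a = _assoc([0.1, 0.15, 0.2, 0.3, 0.25],
                   [0.06, 0.08, 0.09, 0.2, 0.11])
        e1 = weighted_mode(a, bandwidth_factor=1.0, n_boot=10, seed=0).estimate
        e2 = weighted_mode(a, bandwidth_factor=2.0, n_boot=10, seed=0).estimate
        assert e1 != e2
        assert abs(e1 - e2) < 1.0

    def test_zero_bandwidth_rejected(self):
        a = _assoc([0.1, 0.2, 0.3], [0.05, 0.1, 0.15])
        with pytest.raises(ValueError):
            weighted_mode(a, bandwidth_factor=0.0)


class TestCrossEstimatorProperties:
    def test_all_estimators_reduce_to_wald_ratio_on_one_snp(self):
        a = _assoc([0.25], [0.1])
        expected = 0.4
        assert wald_ratio(a).estimate == pytest.approx(expected)
        assert ivw(a).estimate == pytest.approx(expected)
        assert weighted_median(a, n_boot=100, seed=0).estimate == \
            pytest.approx(expected)
        assert weighted_mode(a, n_boot=100, seed=0).estimate == \
            pytest.approx(expected)

    def test_scaling_exposure_betas_inversely_scales_estimates(self, five_snp_table):
        a = SnpAssociationSet(five_snp_table)
        t = five_snp_table.copy()
        c = 2.5
        t["beta_exposure"] *= c
        t["se_exposure"] *= c
        b = SnpAssociationSet(t)
        for fn in (ivw, mr_egger):
            assert fn(b).estimate == pytest.approx(fn(a).estimate / c)
        for fn in (weighted_median, weighted_mode):
            assert fn(b, n_boot=10, seed=0).estimate == pytest.approx(
                fn(a, n_boot=10, seed=0).estimate / c, rel=1e-3)

    def test_run_all_estimators_table(self, five_snp_table):
        out = run_all_estimators(SnpAssociationSet(five_snp_table),
                                 n_boot=100, seed=3)
        assert out["estimator"].tolist() == ["ivw", "egger", "weighted_median",
                                             "weighted_mode"]
        assert (out["se"] > 0).all()

    def test_se_validation(self):
        with pytest.raises(ValueError, match="standard errors"):
            _assoc([0.1, 0.2], [0.1, 0.2], sy=[0.0, 0.1])

    def test_egger_intercept_type_i_error_calibrated(self):
        # no directional pleiotropy: intercept test rejects ~5% at alpha=.05
        rng = np.random.default_rng(123)
        rejections = 0
        reps = 200
        for _ in range(reps):
            bx = rng.uniform(0.1, 0.5, 25)
            by = 0.5 * bx + rng.normal(0, 0.02, 25)
            rejections += mr_egger(_assoc(bx.tolist(), by.tolist())).intercept_p < 0.05
        rate = rejections / reps
        assert 0.005 <= rate <= 0.105  # 3 binomial SEs around 0.05
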