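"""Univariable estimators: Wald, IVW, Egger, weighted median, cML."""

import numpy as np
import pytest

from mrkit.instruments import InstrumentRecord
from mrkit.synthetic_data import SimulationConfig, simulate_two_sample
from mrkit.uvmr import cml, egger, ivw, run_uvmr, wald_ratio, weighted_median

from conftest import make_record, make_records


class TestWaldRatio:
    def test_arithmetic(self):
        rec = make_record(exposure_beta=0.1, outcome_beta=0.05, outcome_se=0.02)
        est = wald_ratio(rec)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)
        assert est.ci_low == pytest.approx(np.exp(0.5 - 1.959964 * 0.2))

    def test_null_outcome_gives_or_one(self):
        est = wald_ratio(make_record(exposure_beta=0.2, outcome_beta=0.0, outcome_se=0.01))
        assert est.beta == 0.0 and est.or_ == 1.0

    def test_sign_follows_exposure_orientation(self):
        est = wald_ratio(make_record(exposure_beta=-0.1, outcome_beta=0.05, outcome_se=0.02))
        assert est.beta == pytest.approx(-0.5)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(make_record(exposure_beta=0.0))


class TestIVW:
    def test_single_record_refused(self):
        with pytest.raises(ValueError, match="wald"):
            ivw([make_record()])

    def test_identical_ratios_no_heterogeneity(self):
        recs = make_records([0.3, 0.3, 0.3], [100, 50, 10])
        est = ivw(recs)
        assert est.beta == pytest.approx(0.3)
        assert est.extra["q"] == pytest.approx(0.0, abs=1e-20)
        assert est.extra["overdispersion"] == 1.0

    def test_weighted_mean_oracle(self):
        """(rho, w) = (0.1, 100), (0.2, 25), (0.4, 4) -> 16.6/129."""
        recs = make_records([0.1, 0.2, 0.4], [100, 25, 4])
        assert ivw(recs).beta == pytest.approx(16.6 / 129, rel=1e-12)

    def test_equal_weights_equal_mean_of_ratios(self, rng):
        ratios = rng.normal(0.2, 0.1, 7)
        recs = make_records(list(ratios), [5.0] * 7)
        assert ivw(recs).beta == pytest.approx(float(np.mean(ratios)), rel=1e-10)

    def test_invariant_to_joint_sign_flip(self, consistent_records):
        flipped = [r.flipped() for r in consistent_records[:3]] + consistent_records[3:]
        a, b = ivw(consistent_records), ivw(flipped)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)

    def test_multiplicative_scaling_never_shrinks_se(self, rng):
        recs = make_records(list(rng.normal(0.2, 0.5, 10)), [10.0] * 10)
        est = ivw(recs)
        x = np.array([r.exposure_beta for r in recs])
        sy = np.array([r.outcome_se for r in recs])
        se_fixed = 1.0 / np.sqrt(np.sum(x**2 / sy**2))
        assert est.se >= se_fixed


class TestEgger:
    def _linear_records(self, intercept, slope, rng, n=10):
        x = rng.uniform(0.05, 0.3, n)
        return [
            make_record(
                f"rs{i+1}",
                exposure_beta=float(xi),
                outcome_beta=float(intercept + slope * xi),
                outcome_se=0.001,
            )
            for i, xi in enumerate(x)
        ]

    def test_recovers_constructed_line(self, rng):
        recs = self._linear_records(0.02, 0.1, rng)
        est = egger(recs)
        assert est.beta == pytest.approx(0.1, abs=1e-10)
        assert est.extra["egger_intercept"] == pytest.approx(0.02, abs=1e-10)

    def test_matches_ivw_under_symmetric_pleiotropy(self, rng):
        # pairs of SNPs at the same exposure beta with +/-a pleiotropy:
        # the fitted intercept is exactly 0, so slope == ivw slope
        x = [0.1, 0.1, 0.2, 0.2]
        a = 0.03
        y = [0.1 * 0.1 + a, 0.1 * 0.1 - a, 0.1 * 0.2 + a, 0.1 * 0.2 - a]
        recs = [
            make_record(f"rs{i+1}", exposure_beta=xi, outcome_beta=yi, outcome_se=0.01)
            for i, (xi, yi) in enumerate(zip(x, y))
        ]
        assert egger(recs).beta == pytest.approx(ivw(recs).beta, abs=1e-6)

    def test_collinear_design_rejected(self):
        recs = make_records([0.1, 0.2, 0.3], [100, 100, 100])  # all exposure betas 1
        with pytest.raises(ValueError, match="degenerate"):
            egger(recs)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            egger(make_records([0.1, 0.2], [1, 1]))


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        recs = make_records([0.1, 0.2, 0.3], [4, 4, 4])
        assert weighted_median(recs, n_boot=50, seed=0).beta == pytest.approx(0.2)

    def test_outlier_with_small_weight_ignored(self):
        recs = make_records([0.19, 0.2, 0.21, 5.0], [100, 100, 100, 0.01])
        assert weighted_median(recs, n_boot=50, seed=0).beta == pytest.approx(0.2, abs=0.02)

    def test_dominant_weight_pulls_estimate(self):
        recs = make_records([0.1, 0.2, 0.4], [1, 1, 100])
        assert weighted_median(recs, n_boot=50, seed=0).beta == pytest.approx(0.4, abs=0.01)

    def test_bootstrap_se_reproducible(self, consistent_records):
        a = weighted_median(consistent_records, seed=7)
        b = weighted_median(consistent_records, seed=7)
        assert a.se == b.se


class TestCML:
    def test_clean_data_selects_k0(self):
        exp, out, truth = simulate_two_sample(SimulationConfig(n_snp=30, theta=0.2, seed=3))
        from mrkit.instruments import harmonize

        recs, _ = harmonize(exp, out, list(exp.table["variant_id"]))
        est = cml(recs)
        assert est.extra["cml_k_invalid"] == 0
        assert est.beta == pytest.approx(0.2, abs=3 * est.se)

    def test_planted_pleiotropy_flagged(self):
        exp, out, truth = simulate_two_sample(
            SimulationConfig(
                n_snp=20, theta=0.2, pleiotropy_frac=0.1, pleiotropy_mean=0.3,
                pleiotropy_sd=0.0, seed=11,
            )
        )
        from mrkit.instruments import harmonize

        recs, _ = harmonize(exp, out, list(exp.table["variant_id"]))
        est = cml(recs)
        planted = {f"rs{i+1}" for i in truth["pleiotropy_idx"]}
        assert est.extra["cml_k_invalid"] == len(planted)
        assert set(est.extra["invalid_ids"]) == planted

    def test_null_truth_not_rejected_too_often(self):
        from mrkit.instruments import harmonize

        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            exp, out, _ = simulate_two_sample(SimulationConfig(n_snp=20, theta=0.0, seed=500 + rep))
            recs, _ = harmonize(exp, out, list(exp.table["variant_id"]))
            est = cml(recs)
            hits += abs(est.beta) < 3 * est.se
        assert hits / n_rep >= 0.95


class TestDispatch:
    def test_single_snp_wald_only(self):
        out = run_uvmr([make_record(ratio=0.3, weight=4)])
        assert set(out) == {"wald"}

    def test_two_snps_wald_table_plus_ivw(self):
        out = run_uvmr(make_records([0.1, 0.2], [1, 1]))
        assert set(out) == {"wald", "ivw_mre"}
        assert isinstance(out["wald"], list) and len(out["wald"]) == 2

    def test_all_methods_consistent_on_clean_simulation(self):
        from mrkit.instruments import harmonize

        exp, out_s, _ = simulate_two_sample(SimulationConfig(n_snp=40, theta=0.15, seed=21))
        recs, _ = harmonize(exp, out_s, list(exp.table["variant_id"]))
        results = run_uvmr(recs, n_boot=200, seed=0)
        assert set(results) == {"wald", "ivw_mre", "egger", "weighted_median", "cml"}
        point_methods = [m for m in results if m != "wald"]
        for m in point_methods:
            est = results[m]
            assert est.n_snp == len(recs)
            # every method's CI overlaps every other method's CI
            for m2 in point_methods:
                other = results[m2]
                assert est.ci_low <= other.ci_high and other.ci_low <= est.ci_high

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            run_uvmr([])
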