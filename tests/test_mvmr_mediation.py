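"""Multivariable MR and mediation decomposition."""

import numpy as np
import pandas as pd
import pytest

from mrkit.mvmr_mediation import (
    build_mvmr_table,
    classify_mediator,
    effect_from_ci,
    mediation,
    mvmr_ivw,
)
from mrkit.synthetic_data import SimulationConfig, simulate_mediation
from mrkit.instruments import harmonize
from mrkit.uvmr import ivw

from conftest import make_records


class TestMVMR:
    def test_recovers_constructed_coefficients(self, rng):
        x1 = rng.uniform(0.05, 0.3, 12)
        x2 = rng.uniform(0.05, 0.3, 12)
        y = 0.5 * x1 + 0.0 * x2
        fit = mvmr_ivw(np.column_stack([x1, x2]), y, np.full(12, 1e-4), ["lipid", "bp"])
        assert fit.beta[0] == pytest.approx(0.5, abs=1e-9)
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-9)
        assert fit.exposures == ["lipid", "bp"]

    def test_zero_exposure_column_is_rank_deficient(self, rng):
        x1 = rng.uniform(0.05, 0.3, 10)
        with pytest.raises(ValueError, match="rank-deficient"):
            mvmr_ivw(np.column_stack([x1, np.zeros(10)]), x1, np.full(10, 0.01))

    def test_single_exposure_reduces_to_ivw(self, consistent_records):
        x = np.array([r.exposure_beta for r in consistent_records])
        y = np.array([r.outcome_beta for r in consistent_records])
        sy = np.array([r.outcome_se for r in consistent_records])
        fit = mvmr_ivw(x[:, None], y, sy, ["only"])
        uni = ivw(consistent_records)
        assert fit.beta[0] == pytest.approx(uni.beta, abs=1e-10)

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            mvmr_ivw(np.ones((3, 2)), np.ones(3), np.ones(3))

    def test_build_table_from_mediation_simulation(self):
        cfg = SimulationConfig(n_snp=40, mediator_chain=(0.2, 0.3, 0.08), seed=2)
        expo, medi, outc, truth = simulate_mediation(cfg)
        snps = list(expo.table["variant_id"])
        frame, yb, ys = build_mvmr_table({"x": expo, "m": medi}, outc, snps)
        assert list(frame.columns) == ["x", "m"]
        assert len(frame) == len(yb) == len(ys) == len(snps)
        fit = mvmr_ivw(frame, yb, ys)
        # direct effect of x given m is beta_x_direct
        assert fit.estimate("x").beta == pytest.approx(0.08, abs=3 * fit.se[0])
        assert fit.estimate("m").beta == pytest.approx(0.3, abs=3 * fit.se[1])


class TestMediation:
    # Printed effect sizes (95% CI) for total and direct effects of the
    # lipid exposure on the disease, adjusting for each mediator.
    SBP = ((0.089, 0.011, 0.167), (0.082, 0.004, 0.161), 0.007)
    IR = ((0.089, 0.011, 0.167), (0.098, 0.008, 0.188), -0.009)
    TT = ((0.089, 0.011, 0.167), (0.079, 0.001, 0.158), 0.010)

    @pytest.mark.parametrize("total_ci,direct_ci,expected", [SBP, IR, TT])
    def test_difference_method_printed_rows(self, total_ci, direct_ci, expected):
        res = mediation(effect_from_ci(*total_ci), effect_from_ci(*direct_ci))
        assert round(res.indirect, 3) == expected

    def test_total_equals_direct_gives_zero(self):
        res = mediation((0.1, 0.01), (0.1, 0.01))
        assert res.indirect == 0.0 and res.proportion == 0.0

    def test_zero_total_proportion_missing(self):
        res = mediation((0.0, 0.01), (0.05, 0.01))
        assert res.proportion is None and res.proportion_ci is None

    def test_difference_identity_exact(self, rng):
        for _ in range(20):
            t, d = rng.normal(size=2) * 0.1
            res = mediation((t, 0.02), (d, 0.03))
            assert res.indirect == pytest.approx(t - d, abs=1e-15)
            assert res.indirect_se == pytest.approx(np.hypot(0.02, 0.03))

    def test_linearity_in_scale(self):
        base = mediation((0.08, 0.01), (0.06, 0.01))
        scaled = mediation((0.24, 0.03), (0.18, 0.03))
        assert scaled.total == pytest.approx(3 * base.total)
        assert scaled.indirect == pytest.approx(3 * base.indirect)
        assert scaled.proportion == pytest.approx(base.proportion)

    def test_product_method_delta_se(self):
        res = mediation((0.1, 0.01), x_to_m=(0.2, 0.02), m_to_y_given_x=(0.3, 0.03), method="product")
        assert res.indirect == pytest.approx(0.06)
        assert res.indirect_se == pytest.approx(np.sqrt(0.2**2 * 0.03**2 + 0.3**2 * 0.02**2))

    def test_monte_carlo_proportion_ci_agrees_with_delta(self):
        delta = mediation((0.1, 0.005), (0.06, 0.005))
        mc = mediation((0.1, 0.005), (0.06, 0.005), proportion_ci_method="mc", seed=1)
        assert mc.proportion == delta.proportion
        assert mc.proportion_ci[0] == pytest.approx(delta.proportion_ci[0], abs=0.02)
        assert mc.proportion_ci[1] == pytest.approx(delta.proportion_ci[1], abs=0.02)
        again = mediation((0.1, 0.005), (0.06, 0.005), proportion_ci_method="mc", seed=1)
        assert mc.proportion_ci == again.proportion_ci

    def test_classification_follows_indirect_p(self):
        strong = mediation((0.1, 0.001), (0.05, 0.001))
        weak = mediation((0.1, 0.1), (0.09, 0.1))
        assert classify_mediator(strong) == "mediator"
        assert classify_mediator(weak) == "attenuator/confounder-like"


class TestEffectFromCI:
    def test_recovers_se(self):
        eff, se = effect_from_ci(0.089, 0.011, 0.167)
        assert eff == 0.089
        assert se == pytest.approx((0.167 - 0.011) / (2 * 1.959964))

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            effect_from_ci(0.1, 0.2, 0.3)

    def test_degenerate_ci_rejected(self):
        with pytest.raises(ValueError):
            effect_from_ci(0.1, 0.1, 0.1)


def test_difference_and_product_agree_on_clean_chain():
    """On a linear chain both decompositions estimate the same indirect path."""
    cfg = SimulationConfig(n_snp=60, mediator_chain=(0.2, 0.3, 0.08), seed=5)
    expo, medi, outc, truth = simulate_mediation(cfg)
    xsnps = truth["exposure_snps"]
    total = ivw(harmonize(expo, outc, xsnps)[0])
    frame, yb, ys = build_mvmr_table({"x": expo, "m": medi}, outc, list(expo.table["variant_id"]))
    fit = mvmr_ivw(frame, yb, ys)
    direct = fit.estimate("x")
    diff = mediation(total, (direct.beta, direct.se))
    a = ivw(harmonize(expo, medi, xsnps)[0])
    m2y = fit.estimate("m")
    prod = mediation(total, x_to_m=a, m_to_y_given_x=(m2y.beta, m2y.se), method="product")
    assert diff.indirect == pytest.approx(prod.indirect, abs=3 * diff.indirect_se)
    assert diff.proportion == pytest.approx(truth["proportion_mediated"], abs=0.15)
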