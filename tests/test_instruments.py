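"""Instrument selection, strength metrics, Steiger filtering, harmonization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit.instruments import (
    ClumpConfig,
    f_statistic,
    find_proxy,
    harmonize,
    select_instruments,
    snp_r2,
    steiger_filter,
)
from mrkit.io import LDMatrix

from conftest import make_record, stats_from_rows


def block_ld(ids, r):
    m = np.full((len(ids), len(ids)), r)
    np.fill_diagonal(m, 1.0)
    return LDMatrix(list(ids), m)


class TestClumping:
    def test_independent_snps_all_kept(self):
        stats = stats_from_rows(
            [{"position": 1000 * i, "p": 1e-9} for i in range(1, 4)]
        )
        ld = block_ld(["rs1", "rs2", "rs3"], 0.0)
        assert set(select_instruments(stats, ld, ClumpConfig())) == {"rs1", "rs2", "rs3"}

    def test_correlated_pair_keeps_smaller_p(self):
        stats = stats_from_rows(
            [{"position": 1000, "p": 1e-9}, {"position": 6000, "p": 1e-8}]
        )
        ld = block_ld(["rs1", "rs2"], np.sqrt(0.5))
        assert select_instruments(stats, ld, ClumpConfig()) == ["rs1"]

    def test_block_of_ten_keeps_exactly_argmin_p(self, rng):
        """Brute force over all pairwise-independent subsets confirms size 1."""
        pvals = rng.permutation(np.geomspace(1e-20, 1e-9, 10))
        stats = stats_from_rows(
            [{"position": 1000 + 100 * i, "p": p} for i, p in enumerate(pvals)]
        )
        ids = [f"rs{i + 1}" for i in range(10)]
        ld = block_ld(ids, np.sqrt(0.9))
        kept = select_instruments(stats, ld, ClumpConfig())
        # independent oracle: maximal subsets with all pairwise r2 < 0.001
        best = max(
            (
                s
                for k in range(1, 11)
                for s in itertools.combinations(range(10), k)
                if all(0.9 < 0.001 for a, b in itertools.combinations(s, 2)) or len(s) == 1
            ),
            key=len,
        )
        assert len(kept) == len(best) == 1
        assert kept[0] == ids[int(np.argmin(pvals))]

    def test_outside_window_not_clumped(self):
        stats = stats_from_rows(
            [{"position": 1000, "p": 1e-9}, {"position": 1000 + 10_001_000, "p": 1e-8}]
        )
        ld = block_ld(["rs1", "rs2"], 0.99)
        assert set(select_instruments(stats, ld, ClumpConfig())) == {"rs1", "rs2"}

    def test_none_significant_returns_empty(self):
        stats = stats_from_rows([{"p": 1e-4}])
        assert select_instruments(stats, None, ClumpConfig()) == []

    def test_kept_set_is_pairwise_valid(self, rng):
        n = 30
        a = rng.normal(size=(n, 3))
        r = np.corrcoef(a @ a.T + np.eye(n))
        ids = [f"rs{i + 1}" for i in range(n)]
        ld = LDMatrix(ids, r)
        stats = stats_from_rows(
            [{"position": 1000 + 5000 * i, "p": float(p)} for i, p in enumerate(rng.uniform(1e-20, 1e-9, n))]
        )
        cfg = ClumpConfig(r2_threshold=0.1)
        kept = select_instruments(stats, ld, cfg)
        for a_, b_ in itertools.combinations(kept, 2):
            assert ld.r2_between(a_, b_) < cfg.r2_threshold


class TestStrength:
    @pytest.mark.parametrize(
        "eaf,beta,expected",
        [(0.5, 0.0, 0.0), (0.5, 0.1, 0.005), (0.9, 0.2, 0.0072), (0.1, 0.2, 0.0072)],
    )
    def test_snp_r2_arithmetic(self, eaf, beta, expected):
        assert snp_r2(eaf, beta) == pytest.approx(expected, abs=1e-12)

    def test_snp_r2_rejects_boundary_eaf(self):
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                snp_r2(bad, 0.1)

    @pytest.mark.parametrize(
        "r2,n,k,expected",
        [(0.0, 100, 1, 0.0), (0.01, 1002, 1, 1000 * 0.01 / 0.99), (0.01, 500, 1, 498 * 0.01 / 0.99)],
    )
    def test_f_statistic_values(self, r2, n, k, expected):
        assert f_statistic(r2, n, k) == pytest.approx(expected, rel=1e-12)

    def test_weak_strong_threshold(self):
        assert f_statistic(0.01, 1002) > 10 > f_statistic(0.01, 500)

    @settings(max_examples=50, deadline=None)
    @given(
        r2=st.floats(0.001, 0.5),
        n=st.integers(10, 10**6),
        dr=st.floats(1e-4, 0.3),
        dn=st.integers(1, 10**5),
    )
    def test_f_statistic_strictly_increasing(self, r2, n, dr, dn):
        if r2 + dr < 1:
            assert f_statistic(r2 + dr, n) > f_statistic(r2, n)
        assert f_statistic(r2, n + dn) > f_statistic(r2, n)

    def test_f_statistic_domain_errors(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 100)
        with pytest.raises(ValueError):
            f_statistic(0.1, 2)


class TestSteiger:
    def test_directionality(self):
        # exposure z=10 vs outcome z=1: kept; reversed: dropped
        fwd = make_record(exposure_beta=0.1, exposure_se=0.01, outcome_beta=0.01, outcome_se=0.01)
        rev = make_record(exposure_beta=0.01, exposure_se=0.01, outcome_beta=0.1, outcome_se=0.01)
        kept, dropped = steiger_filter([fwd, rev])
        assert kept == [fwd] and dropped == [rev]

    def test_exact_tie_retained(self):
        rec = make_record(exposure_beta=0.1, exposure_se=0.01, outcome_beta=0.1, outcome_se=0.01)
        kept, dropped = steiger_filter([rec])
        assert kept == [rec] and dropped == []

    def test_missing_n_dropped_with_warning(self):
        rec = make_record(outcome_n=None)
        kept, dropped = steiger_filter([rec])
        assert kept == [] and dropped == [rec]

    def test_partition_property(self, consistent_records):
        kept, dropped = steiger_filter(consistent_records)
        assert len(kept) + len(dropped) == len(consistent_records)
        assert not set(id(r) for r in kept) & set(id(r) for r in dropped)


class TestFindProxy:
    def _setup(self, r2s):
        ids = ["target"] + [f"proxy{i}" for i in range(len(r2s))]
        m = np.eye(len(ids))
        for i, r2 in enumerate(r2s):
            m[0, i + 1] = m[i + 1, 0] = np.sqrt(r2)
        ld = LDMatrix(ids, m)
        outcome = stats_from_rows(
            [{"variant_id": f"proxy{i}", "position": 1000 + i} for i in range(len(r2s))]
        )
        return ld, outcome

    def test_best_proxy_wins(self):
        ld, outcome = self._setup([0.95, 0.85])
        assert find_proxy("target", outcome, ld) == "proxy0"

    def test_below_threshold_returns_none(self):
        ld, outcome = self._setup([0.7])
        assert find_proxy("target", outcome, ld) is None

    def test_target_present_is_precondition_error(self):
        ld, outcome = self._setup([0.95])
        outcome.table.loc[0, "variant_id"] = "target"
        with pytest.raises(ValueError):
            find_proxy("target", outcome, ld)


class TestHarmonize:
    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = stats_from_rows([{"effect_allele": "A", "other_allele": "G", "beta": 0.1, "eaf": 0.3}])
        out = stats_from_rows([{"effect_allele": "G", "other_allele": "A", "beta": -0.05, "eaf": 0.7}])
        recs, drops = harmonize(exp, out, ["rs1"])
        assert recs[0].outcome_beta == pytest.approx(0.05)
        assert recs[0].outcome_eaf == pytest.approx(0.3)
        assert not drops

    def test_identical_coding_unchanged(self):
        exp = stats_from_rows([{"beta": 0.1, "eaf": 0.3}])
        out = stats_from_rows([{"beta": -0.05, "eaf": 0.31}])
        recs, _ = harmonize(exp, out, ["rs1"])
        assert recs[0].outcome_beta == -0.05 and recs[0].outcome_eaf == 0.31

    def test_strand_flip_resolved(self):
        exp = stats_from_rows([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        out = stats_from_rows([{"effect_allele": "T", "other_allele": "C", "beta": 0.07}])
        recs, _ = harmonize(exp, out, ["rs1"])
        assert recs[0].outcome_beta == 0.07

    def test_palindromic_ambiguous_eaf_dropped(self):
        exp = stats_from_rows([{"effect_allele": "A", "other_allele": "T", "eaf": 0.49}])
        out = stats_from_rows([{"effect_allele": "A", "other_allele": "T", "eaf": 0.48, "beta": 0.05}])
        with pytest.raises(ValueError):
            harmonize(exp, out, ["rs1"])

    def test_palindromic_clear_eaf_frequency_inferred(self):
        exp = stats_from_rows([{"effect_allele": "C", "other_allele": "G", "eaf": 0.2, "beta": 0.1}])
        # outcome reports the complementary strand: its eaf refers to the
        # other physical allele, so frequencies disagree in direction
        out = stats_from_rows([{"effect_allele": "C", "other_allele": "G", "eaf": 0.8, "beta": 0.05}])
        recs, _ = harmonize(exp, out, ["rs1"])
        assert recs[0].outcome_beta == pytest.approx(-0.05)

    def test_irreconcilable_alleles_dropped_with_reason(self):
        exp = stats_from_rows([{"effect_allele": "A", "other_allele": "G"}, {"variant_id": "rs2", "position": 2000}])
        out = stats_from_rows([{"effect_allele": "A", "other_allele": "C", "beta": 0.05}, {"variant_id": "rs2", "position": 2000}])
        recs, drops = harmonize(exp, out, ["rs1", "rs2"])
        assert [d.variant_id for d in drops] == ["rs1"]
        assert drops[0].reason == "allele_mismatch"
        assert [r.variant_id for r in recs] == ["rs2"]

    def test_flip_is_involution(self, consistent_records):
        for rec in consistent_records:
            twice = rec.flipped().flipped()
            assert twice.effect_allele == rec.effect_allele
            assert twice.exposure_beta == rec.exposure_beta
            assert twice.outcome_beta == rec.outcome_beta
            assert twice.exposure_eaf == pytest.approx(rec.exposure_eaf)

    def test_f_stat_attached_and_consistent(self):
        exp = stats_from_rows([{"beta": 0.1, "eaf": 0.3, "n": 100_000}])
        out = stats_from_rows([{"beta": 0.05}])
        recs, _ = harmonize(exp, out, ["rs1"])
        r2 = snp_r2(0.3, 0.1)
        assert recs[0].f_stat == pytest.approx(f_statistic(r2, 100_000))
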