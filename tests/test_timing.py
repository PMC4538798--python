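"""Timing estimator: model inversion, MMAF weighting, F recovery, Wilcoxon."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from ovatime.core import GeneModel, ValidationError
from ovatime.simulate import simulate_timing_pairs
from ovatime.stats import wilcoxon_signed_rank_less
from ovatime.timing import (
    TimingPair,
    TimingSnvPolicy,
    compute_mmaf,
    estimate_f,
    expected_maf,
    purity_corrected_cna,
    select_timing_snvs,
    snp_weight,
    wilcoxon_less_than_one,
)
from .conftest import make_random_variant

GENE = GeneModel("TP53", (("chr1", 7_000_000, 7_100_000),))


class TestExpectedMaf:
    @pytest.mark.parametrize(
        "x,c,f,expected",
        [(1, 1, 1, 1.0), (1, 1, 0, 0.0), (0.5, 1, 1, 1 / 3), (0.6, 1, 1, 0.6 / 1.4)],
    )
    def test_closed_form(self, x, c, f, expected):
        assert expected_maf(x, c, f) == pytest.approx(expected)

    def test_arguments_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            expected_maf(1.2, 1, 1)


class TestSnpWeight:
    @pytest.mark.parametrize("cov,expected", [(0, 0.0), (1, 0.5), (10, 1023 / 1024)])
    def test_values(self, cov, expected):
        assert snp_weight(cov) == pytest.approx(expected)


class TestSelectTimingSnvs:
    def eligible(self, rng, **kw):
        base = dict(chrom="chr1", position=7_050_000, tumor_depth=20, tumor_alt=8,
                    alt_forward=4, alt_reverse=4, bq_mutant=(30,) * 8,
                    germline_depth=30, germline_alt=0, dbsnp_maf=None)
        base.update(kw)
        return make_random_variant(rng, **base)

    def test_within_one_mb_selected(self):
        rng = np.random.default_rng(0)
        v = self.eligible(rng, position=8_000_000)  # 0.9 Mb past gene end
        assert select_timing_snvs([v], GENE) == [v]

    def test_depth_fourteen_excluded(self):
        rng = np.random.default_rng(1)
        v = self.eligible(rng, tumor_depth=14, tumor_alt=5, alt_forward=3,
                          alt_reverse=2, bq_mutant=(30,) * 5)
        assert select_timing_snvs([v], GENE) == []

    def test_random_cohort_matches_brute_force_filter(self):
        rng = np.random.default_rng(2)
        policy = TimingSnvPolicy()
        variants = [
            make_random_variant(
                rng,
                chrom="chr1",
                position=int(rng.integers(5_000_000, 9_000_000)),
                dbsnp_maf=float(rng.uniform(0, 0.05)) if rng.random() < 0.3 else None,
            )
            for _ in range(400)
        ]
        chrom, start, end = GENE.span()
        expected = [
            v
            for v in variants
            if start - 1_000_000 < v.position <= end + 1_000_000
            and v.tumor_depth >= 15
            and v.germline_alt == 0
            and v.dbsnp_maf is None
            and v.germline_depth >= 10
        ]
        assert select_timing_snvs(variants, GENE, policy) == expected


class TestComputeMmaf:
    def test_symmetric_mean(self):
        rng = np.random.default_rng(3)
        a = make_random_variant(rng, tumor_depth=10, tumor_alt=4, alt_forward=2,
                                alt_reverse=2, bq_mutant=(30,) * 4, germline_depth=50)
        b = make_random_variant(rng, tumor_depth=10, tumor_alt=6, alt_forward=3,
                                alt_reverse=3, bq_mutant=(30,) * 6, germline_depth=50)
        m, n = compute_mmaf([a, b])
        assert m == pytest.approx(0.5) and n == 2

    def test_single_snv_identity(self):
        rng = np.random.default_rng(4)
        v = make_random_variant(rng, tumor_depth=100, tumor_alt=33, alt_forward=17,
                                alt_reverse=16, bq_mutant=(30,) * 33, germline_depth=40)
        m, _ = compute_mmaf([v])
        assert m == pytest.approx(0.33)

    def test_mixed_coverages_match_weighted_mean_oracle(self):
        rng = np.random.default_rng(5)
        variants = [make_random_variant(rng) for _ in range(50)]
        m, _ = compute_mmaf(variants)
        w = np.array([1 - 2.0 ** (-v.germline_depth) for v in variants])
        f = np.array([v.tumor_alt / v.tumor_depth for v in variants])
        assert m == pytest.approx(float((w * f).sum() / w.sum()))

    def test_no_variants_or_zero_weights_raise(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValidationError):
            compute_mmaf([])
        v = make_random_variant(rng, germline_depth=0, germline_alt=0)
        with pytest.raises(ValidationError, match="weights"):
            compute_mmaf([v])


class TestPurityCorrectedCna:
    @pytest.mark.parametrize(
        "log2,x,expected", [(-1.0, 1.0, 1.0), (-0.5, 0.5, 1.0), (0.0, 0.8, 0.0)]
    )
    def test_hemizygous_inversion(self, log2, x, expected):
        assert purity_corrected_cna(log2, x) == pytest.approx(expected)

    def test_zero_purity_rejected(self):
        with pytest.raises(ValidationError):
            purity_corrected_cna(-0.5, 0.0)

    def test_round_trip_through_forward_model(self):
        # segment log2 for a deletion in fraction cna of cells: log2(1 - cna/2)
        for cna in (0.2, 0.5, 0.9):
            log2 = np.log2(1 - cna / 2)
            assert purity_corrected_cna(log2, 1.0) == pytest.approx(cna, abs=1e-12)


class TestEstimateF:
    def test_single_pair_inverts_model_exactly(self):
        est = estimate_f([TimingPair("s", "g", m=1 / 3, cna=0.5)])
        assert est.F == pytest.approx(1.0)
        assert est.loo_range is None and est.p_wilcoxon is None

    def test_hand_computed_three_pair_case(self):
        pairs = [
            TimingPair("a", "g", m=1 / 3, cna=0.5),
            TimingPair("b", "g", m=0.2, cna=0.5),
            TimingPair("c", "g", m=0.25, cna=0.5),
        ]
        est = estimate_f(pairs)
        assert est.f_values == pytest.approx((1.0, 0.6, 0.75))
        assert est.F == pytest.approx(2.35 / 3)
        assert est.loo_range == pytest.approx((0.675, 0.875))

    def test_paper_verbatim_formula_preserved(self):
        est = estimate_f([TimingPair("a", "g", m=0.4, cna=0.5)], method="paper-verbatim")
        assert est.F == pytest.approx((0.4 - 0.5) * 2 * 0.5 / 0.5)

    def test_noise_free_round_trip_to_machine_precision(self):
        pairs = []
        expected = []
        for x in (0.4, 0.7, 1.0):
            for c in (0.5, 0.9):
                for f in (0.1, 0.6, 1.0):
                    m = expected_maf(x, c, f)
                    pairs.append(TimingPair("s", "g", m=m, cna=c * x))
                    expected.append(f)
        est = estimate_f(pairs)
        assert np.max(np.abs(np.array(est.f_values) - np.array(expected))) < 1e-12

    def test_f_monotone_in_m_at_fixed_cna(self):
        ms = np.linspace(0.01, 0.6, 20)
        fs = [estimate_f([TimingPair("s", "g", m=float(m), cna=0.6)]).F for m in ms]
        assert all(b > a for a, b in zip(fs, fs[1:]))

    def test_parameter_recovery_with_binomial_noise(self):
        rng = np.random.default_rng(11)
        pairs = simulate_timing_pairs(
            n_regions=50, depth=100, purity=0.6, clone_fraction=1.0, f_true=0.6, rng=rng
        )
        est = estimate_f(pairs)
        assert abs(est.F - 0.6) < 0.05

    def test_scenario_separation_before_vs_after(self):
        # f = 1 cohorts look timing-neutral; f = 0.5 cohorts reject at n = 7
        rng = np.random.default_rng(12)
        before = estimate_f(
            simulate_timing_pairs(7, 46, 0.6, 1.0, 1.0, rng, snvs_per_region=5)
        )
        after = estimate_f(
            simulate_timing_pairs(7, 46, 0.6, 1.0, 0.5, rng, snvs_per_region=5)
        )
        assert abs(before.F - 1.0) < 0.1
        assert before.p_wilcoxon > 0.05
        assert abs(after.F - 0.5) < 0.1
        assert after.p_wilcoxon < 0.05


class TestWilcoxon:
    def test_all_values_at_one_give_p_one(self):
        assert wilcoxon_less_than_one([1.0, 1.0, 1.0]) == 1.0

    def test_seven_low_values(self):
        p = wilcoxon_less_than_one([0.5, 0.6, 0.55, 0.6, 0.62, 0.58, 0.61])
        assert p == pytest.approx(1 / 2**7)

    def test_exact_p_matches_sign_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(3, 13))
            values = np.round(rng.normal(0.9, 0.2, size=n), 2)
            p = wilcoxon_less_than_one(values)
            d = values - 1.0
            d = d[d != 0]
            ranks = sps.rankdata(np.abs(d))
            obs = ranks[d > 0].sum()
            count = sum(
                1
                for signs in itertools.product((0, 1), repeat=len(d))
                if sum(r for s, r in zip(signs, ranks) if s) <= obs + 1e-9
            )
            assert p == pytest.approx(count / 2 ** len(d), abs=1e-12)

    def test_matches_scipy_on_tie_free_input(self):
        values = np.array([0.81, 0.93, 1.07, 0.64, 1.22, 0.55, 0.98, 1.31])
        p_ours, _ = wilcoxon_signed_rank_less(values, mu=1.0)
        p_scipy = sps.wilcoxon(values - 1.0, alternative="less", method="exact").pvalue
        assert p_ours == pytest.approx(p_scipy, abs=1e-12)

    def test_type_one_error_controlled_under_symmetric_null(self):
        rng = np.random.default_rng(14)
        n_reps = 2000
        rejections = 0
        for _ in range(n_reps):
            values = 1.0 + rng.normal(0, 0.1, size=10)
            if wilcoxon_less_than_one(values) < 0.05:
                rejections += 1
        assert rejections / n_reps <= 0.06

    def test_normal_approximation_regime_close_to_exact_tail(self):
        rng = np.random.default_rng(15)
        values = 1.0 - np.abs(rng.normal(0.05, 0.03, size=40))
        p, n = wilcoxon_signed_rank_less(values, mu=1.0)
        assert n == 40 and p < 1e-6


class TestTimingPairFromData:
    def test_pure_tumor_data_route_recovers_f(self):
        """At purity 1 the log2 correction is exact, so the full data route
        (select SNVs -> MMAF -> segment log2 -> cna -> f) inverts cleanly."""
        import math

        from ovatime.core import Segment
        from ovatime.timing import timing_pair_from_data

        rng = np.random.default_rng(21)
        f_true = 0.7  # with x = c = 1, expected MAF equals f
        variants = []
        for pos in (7_020_000, 7_050_000, 7_080_000, 7_400_000, 7_900_000):
            variants.append(
                make_random_variant(
                    rng, chrom="chr1", position=pos, tumor_depth=100, tumor_alt=70,
                    alt_forward=35, alt_reverse=35, bq_mutant=(30,) * 70,
                    germline_depth=40, germline_alt=0, dbsnp_maf=None,
                )
            )
        segments = [
            Segment("chr1", 5_000_000, 10_000_000, math.log2(0.5), loh=True, sample_id="T"),
        ]
        pair = timing_pair_from_data("T", GENE, variants, segments, purity=1.0)
        assert pair is not None and pair.n_snvs == 5
        assert pair.cna == pytest.approx(1.0)
        assert pair.m == pytest.approx(f_true)
        assert estimate_f([pair]).F == pytest.approx(f_true)

    def test_neutral_region_yields_no_pair(self):
        import math

        from ovatime.core import Segment
        from ovatime.timing import timing_pair_from_data

        rng = np.random.default_rng(22)
        v = make_random_variant(rng, chrom="chr1", position=7_050_000, tumor_depth=50,
                                tumor_alt=20, alt_forward=10, alt_reverse=10,
                                bq_mutant=(30,) * 20, germline_depth=40, germline_alt=0,
                                dbsnp_maf=None)
        segments = [Segment("chr1", 5_000_000, 10_000_000, 0.0, sample_id="T")]
        assert timing_pair_from_data("T", GENE, [v], segments, purity=1.0) is None


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=200)
    @given(
        x=st.floats(0.05, 1.0),
        c=st.floats(0.05, 1.0),
        f=st.floats(0.0, 1.0),
    )
    def test_inversion_recovers_f_for_any_model_parameters(x, c, f):
        """estimate_f inverts the expected-MAF model across the parameter cube."""
        pair = TimingPair("s", "g", m=expected_maf(x, c, f), cna=c * x)
        assert estimate_f([pair]).F == pytest.approx(f, abs=1e-9)

except ImportError:  # hypothesis is an optional test dependency
    pass
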