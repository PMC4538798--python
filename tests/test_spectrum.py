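"""Spectrum statistics: classification, tabulation, normalized rates, Ts/Tv, NS/S."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from ovatime import cohort_tables
from ovatime.core import DEFAULT_LAYOUT, ValidationError
from ovatime.simulate import default_exons, synthetic_opportunities
from ovatime.spectrum import (
    CategoryCountTable,
    Opportunities,
    SpectrumTable,
    build_spectrum,
    classify_substitution,
    context_normalized_rates,
    ns_s_ratio,
    regional_rate_comparison,
    tabulate_by_annotation,
    tstv_by_chromosome,
)
from .conftest import make_random_variant

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestClassifySubstitution:
    def test_c_to_t_in_cpg_context(self):
        assert classify_substitution("C", "T", "ACG") == ("C>T", True, True)

    def test_purine_reference_folds_to_pyrimidine_strand(self):
        # G>A in CGT is C>T in ACG on the other strand: CpG transition.
        assert classify_substitution("G", "A", "CGT") == ("C>T", True, True)

    def test_exactly_four_of_twelve_ordered_substitutions_are_transitions(self):
        transitions = 0
        for ref, alt in itertools.permutations("ACGT", 2):
            ctx = f"A{ref}A"
            _, is_ts, _ = classify_substitution(ref, alt, ctx)
            transitions += is_ts
        assert transitions == 4

    def test_invariant_under_joint_reverse_complement(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        for _ in range(200):
            ref = bases[rng.integers(4)]
            alt = bases[rng.integers(4)]
            if ref == alt:
                continue
            ctx = bases[rng.integers(4)] + ref + bases[rng.integers(4)]
            rc_ctx = "".join(_COMP[b] for b in reversed(ctx))
            assert classify_substitution(ref, alt, ctx) == classify_substitution(
                _COMP[ref], _COMP[alt], rc_ctx
            )

    def test_non_acgt_input_rejected(self):
        with pytest.raises(ValidationError):
            classify_substitution("C", "N", "ACA")


class TestCategoryTable:
    def test_published_patient_row_total(self):
        table = CategoryCountTable.from_counts(cohort_tables.mutation_count_table())
        assert table.row_total("A") == 7343

    def test_published_coding_total_excluding_ultramutated(self):
        table = CategoryCountTable.from_counts(cohort_tables.mutation_count_table())
        assert table.coding_total(exclude={"D"}) == 949

    def test_zero_variants_gives_all_zero_table(self):
        table = tabulate_by_annotation([], samples=["S1", "S2"])
        assert table.counts.values.sum() == 0
        assert table.grand_total() == 0

    def test_totals_consistent_and_permutation_invariant(self):
        rng = np.random.default_rng(1)
        cats = ["Missense", "Silent", "Intergenic", "Intron"]
        variants = [
            make_random_variant(
                rng,
                category=cats[int(rng.integers(4))],
                sample_id=f"S{int(rng.integers(3)) + 1}",
            )
            for _ in range(120)
        ]
        t1 = tabulate_by_annotation(variants)
        t2 = tabulate_by_annotation(list(reversed(variants)))
        assert t1.counts.equals(t2.counts)
        assert t1.grand_total() == sum(t1.row_total(s) for s in t1.counts.index) == 120

    def test_deduplicated_total_counts_distinct_sites(self):
        rng = np.random.default_rng(2)
        v1 = make_random_variant(rng, chrom="chr1", position=100, category="Missense")
        v2 = make_random_variant(rng, chrom="chr1", position=100, category="Silent")
        v3 = make_random_variant(rng, chrom="chr1", position=200, category="Intron")
        table = tabulate_by_annotation([v1, v2, v3])
        assert table.grand_total() == 3
        assert table.deduplicated_total() == 2


class TestNormalizedRates:
    def test_single_cpg_mutation_rate(self):
        counts = pd.DataFrame(
            [{"sample": "S1", "type": "C>T", "region": "exonic", "cpg": True, "count": 1}]
        )
        opp = Opportunities(n_c=100, n_t=100, n_cpg_c=10)
        table = SpectrumTable(counts, {"exonic": opp, "non_exonic": opp})
        rates = context_normalized_rates(table)
        cpg_row = rates[(rates.type == "C>T") & (rates.cpg == True)]  # noqa: E712
        assert cpg_row.rate.iloc[0] == pytest.approx(0.1)

    def test_rates_match_brute_force_and_scale_linearly(self):
        rng = np.random.default_rng(3)
        exons = default_exons(DEFAULT_LAYOUT)
        opps = synthetic_opportunities(DEFAULT_LAYOUT, exons)
        bases = "ACGT"
        variants = []
        for _ in range(300):
            ref = "CT"[rng.integers(2)]
            alt = rng.permuted([b for b in bases if b != ref])[0]
            ctx = bases[rng.integers(4)] + ref + bases[rng.integers(4)]
            variants.append(
                make_random_variant(rng, ref=ref, alt=str(alt), context=ctx, sample_id="S1")
            )
        spec = build_spectrum(variants, exons, opps)
        rates = context_normalized_rates(spec)
        # brute force: recount and divide
        for row in rates.itertuples():
            n = 0
            for v in variants:
                label, _, cpg = classify_substitution(v.ref, v.alt, v.context)
                exonic = any(
                    c == v.chrom and s < v.position <= e for c, s, e in exons
                )
                region = "exonic" if exonic else "non_exonic"
                if label == row.type and region == row.region and (
                    row.cpg is None or cpg == row.cpg
                ):
                    n += 1
            assert n == row.count
            if row.opportunity:
                assert row.rate == pytest.approx(n / row.opportunity)
        doubled = build_spectrum(variants + variants, exons, opps)
        d_rates = context_normalized_rates(doubled)
        merged = rates.merge(d_rates, on=["sample", "type", "region", "cpg"])
        assert np.allclose(merged.rate_y, 2 * merged.rate_x)

    def test_zero_opportunity_with_nonzero_count_is_an_error(self):
        counts = pd.DataFrame(
            [{"sample": "S1", "type": "T>A", "region": "exonic", "cpg": False, "count": 2}]
        )
        opp = Opportunities(n_c=10, n_t=0, n_cpg_c=1)
        table = SpectrumTable(counts, {"exonic": opp, "non_exonic": opp})
        with pytest.raises(ValidationError, match="zero opportunity"):
            context_normalized_rates(table)

    def test_cpg_ct_enrichment_detected_in_exonic_regions(self, cohort_15):
        """CpG C>T rates exceed non-CpG rates in exons across the cohort."""
        exons = default_exons(DEFAULT_LAYOUT)
        opps = synthetic_opportunities(DEFAULT_LAYOUT, exons)
        cpg_rates, non_cpg_rates = [], []
        for variants, _, _, _, _ in cohort_15:
            spec = build_spectrum(variants, exons, opps)
            rates = context_normalized_rates(spec)
            ct = rates[(rates.type == "C>T") & (rates.region == "exonic")]
            if set(ct.cpg) == {True, False}:
                cpg_rates.append(float(ct[ct.cpg == True].rate.iloc[0]))  # noqa: E712
                non_cpg_rates.append(float(ct[ct.cpg == False].rate.iloc[0]))  # noqa: E712
        assert len(cpg_rates) >= 10
        from ovatime.stats import paired_t

        t, p_two = paired_t(cpg_rates, non_cpg_rates)
        assert t > 0
        assert p_two / 2 < 0.05  # one-sided


class TestTsTv:
    def test_single_transition_gives_undefined_ratio(self):
        rng = np.random.default_rng(4)
        v = make_random_variant(rng, chrom="chr1", ref="A", alt="G", context="AAA")
        df = tstv_by_chromosome([v], DEFAULT_LAYOUT)
        chr1 = df[df.chrom == "chr1"].iloc[0]
        assert np.isnan(chr1.tstv) and chr1.pct_ts == 100.0

    def test_uniform_substitutions_give_ratio_near_half(self):
        rng = np.random.default_rng(5)
        bases = "ACGT"
        variants = []
        for _ in range(3000):
            ref = bases[rng.integers(4)]
            alt = rng.permuted([b for b in bases if b != ref])[0]
            ctx = bases[rng.integers(4)] + ref + bases[rng.integers(4)]
            variants.append(make_random_variant(rng, ref=ref, alt=str(alt), context=ctx))
        df = tstv_by_chromosome(variants, DEFAULT_LAYOUT)
        ratio = df.ts.sum() / df.tv.sum()
        # 4 of 12 ordered types are transitions -> expected ratio 0.5
        assert ratio == pytest.approx(0.5, abs=0.06)

    def test_transition_enriched_generator_has_ts_above_tv_everywhere(self, cohort_15):
        variants = [v for sample in cohort_15 for v in sample[0]]
        df = tstv_by_chromosome(variants, DEFAULT_LAYOUT)
        assert (df.ts > df.tv).all()


class TestRegionalRates:
    def test_identical_rates_give_t_zero_p_one(self):
        rng = np.random.default_rng(6)
        exons = (("chr1", 0, 25_000_000),)
        from ovatime.core import GenomeLayout

        layout = GenomeLayout(("chr1",), (50_000_000,))
        variants = []
        for s in ("S1", "S2", "S3"):
            for pos in (10, 30_000_000):
                variants.append(
                    make_random_variant(rng, chrom="chr1", position=pos, sample_id=s)
                )
        result = regional_rate_comparison(variants, exons, layout)
        assert result.t_statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_three_sample_case_matches_scipy_paired_t(self):
        from scipy import stats as sps

        from ovatime.stats import paired_t

        a = [1.0, 2.0, 4.0]
        b = [0.5, 2.5, 1.0]
        t, p = paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_single_sample_skips_test_with_notice(self):
        rng = np.random.default_rng(7)
        v = make_random_variant(rng, chrom="chr1", position=5, sample_id="only")
        result = regional_rate_comparison([v], (("chr1", 0, 1000),), DEFAULT_LAYOUT)
        assert result.t_statistic is None and "skipped" in result.note

    def test_elevated_non_exonic_rate_is_significant_across_cohort(self, cohort_15):
        exons = default_exons(DEFAULT_LAYOUT)
        variants = [v for sample in cohort_15 for v in sample[0]]
        result = regional_rate_comparison(variants, exons, DEFAULT_LAYOUT)
        assert result.t_statistic > 0
        assert result.p_value < 0.01


class TestNsSRatio:
    def test_six_missense_two_silent_gives_three(self):
        rng = np.random.default_rng(8)
        variants = [make_random_variant(rng, category="Missense") for _ in range(6)]
        variants += [make_random_variant(rng, category="Silent") for _ in range(2)]
        df, mean = ns_s_ratio(variants)
        assert df.ratio.iloc[0] == pytest.approx(3.0) and mean == pytest.approx(3.0)

    def test_zero_silent_excluded_from_mean(self):
        rng = np.random.default_rng(9)
        a = [make_random_variant(rng, category="Missense", sample_id="A") for _ in range(4)]
        a += [make_random_variant(rng, category="Silent", sample_id="A")]
        b = [make_random_variant(rng, category="Missense", sample_id="B") for _ in range(3)]
        df, mean = ns_s_ratio(a + b)
        assert np.isnan(df[df["sample"] == "B"].ratio.iloc[0])
        assert mean == pytest.approx(4.0)

    def test_random_categories_match_brute_force_recount(self):
        rng = np.random.default_rng(10)
        cats = ["Missense", "Nonsense", "Splice site", "Silent", "Intron"]
        variants = [
            make_random_variant(
                rng, category=cats[int(rng.integers(5))], sample_id=f"S{int(rng.integers(3))}"
            )
            for _ in range(200)
        ]
        df, _ = ns_s_ratio(variants)
        for row in df.itertuples():
            ns = sum(
                1
                for v in variants
                if v.sample_id == row.sample
                and v.category in ("Missense", "Nonsense", "Splice site")
            )
            s = sum(
                1 for v in variants if v.sample_id == row.sample and v.category == "Silent"
            )
            assert row.nonsynonymous == ns and row.synonymous == s
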