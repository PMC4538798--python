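"""HRD/LOH scoring: thresholds, merge behaviour, burden, cohort classification."""

from __future__ import annotations

import numpy as np
import pytest

from ovatime import cohort_tables
from ovatime.core import GenomeLayout, Segment, ValidationError
from ovatime.loh import (
    classify_samples,
    hrd_like_score,
    hrd_score,
    loh_burden,
    loh_occurrence,
)

LAYOUT = GenomeLayout(("chr1", "chr2"), (100_000_000, 100_000_000))


def seg(chrom, start, end, log2=0.0, loh=False):
    return Segment(chrom, start, end, log2, loh=loh, sample_id="S")


def brute_force_hrd(segments, layout, min_length=15_000_000, merge_gap=1000):
    """Merge-then-count oracle written independently of the implementation."""
    count = 0
    for chrom in layout.names:
        flagged = sorted(
            [(s.start, s.end) for s in segments if s.chrom == chrom and s.loh]
        )
        merged = []
        for start, end in flagged:
            if merged and start - merged[-1][1] < merge_gap:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        count += sum(1 for s, e in merged if e - s > min_length)
    return count


class TestHrdScore:
    def test_no_loh_gives_zero(self):
        assert hrd_score([seg("chr1", 0, 10**7)], LAYOUT) == 0

    def test_strictly_greater_than_fifteen_mb(self):
        assert hrd_score([seg("chr1", 0, 15_000_000, loh=True)], LAYOUT) == 0
        assert hrd_score([seg("chr1", 0, 15_100_000, loh=True)], LAYOUT) == 1

    def test_split_segments_merge_before_thresholding(self):
        # one 16 Mb LOH region split in two abutting pieces still counts once
        parts = [
            seg("chr1", 0, 8_000_000, loh=True),
            seg("chr1", 8_000_000, 16_000_000, loh=True),
        ]
        whole = [seg("chr1", 0, 16_000_000, loh=True)]
        assert hrd_score(parts, LAYOUT) == hrd_score(whole, LAYOUT) == 1

    def test_random_segmentations_match_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            segments = []
            for chrom in LAYOUT.names:
                cursor = 0
                while cursor < 90_000_000:
                    length = int(rng.integers(1_000_000, 25_000_000))
                    end = min(cursor + length, 100_000_000)
                    segments.append(
                        seg(chrom, cursor, end, loh=bool(rng.random() < 0.4))
                    )
                    cursor = end + int(rng.integers(0, 3) * 500)
                    if cursor >= 100_000_000:
                        break
            segments = [s for s in segments if s.end <= 100_000_000]
            assert hrd_score(segments, LAYOUT) == brute_force_hrd(segments, LAYOUT)

    def test_order_permutation_invariant_and_bounded_by_segment_count(self):
        rng = np.random.default_rng(1)
        segments = [
            seg("chr1", s, s + 16_000_000, loh=True)
            for s in (0, 20_000_000, 40_000_000, 60_000_000)
        ]
        shuffled = list(segments)
        rng.shuffle(shuffled)
        assert hrd_score(segments, LAYOUT) == hrd_score(shuffled, LAYOUT) == 4
        assert hrd_score(segments, LAYOUT) <= len(segments)

    def test_segment_beyond_chromosome_end_rejected(self):
        with pytest.raises(ValidationError, match="beyond"):
            hrd_score([seg("chr1", 0, 200_000_000, loh=True)], LAYOUT)


class TestHrdLikeScore:
    def test_neutral_genome_scores_zero(self):
        assert hrd_like_score([seg("chr1", 0, 50_000_000, log2=0.0)], LAYOUT) == 0

    def test_twenty_mb_loss_scores_one(self):
        assert hrd_like_score([seg("chr1", 0, 20_000_000, log2=-1.0)], LAYOUT) == 1

    def test_cutoff_boundary_included(self):
        assert hrd_like_score([seg("chr1", 0, 20_000_000, log2=-0.3)], LAYOUT) == 1
        assert hrd_like_score([seg("chr1", 0, 20_000_000, log2=-0.29)], LAYOUT) == 0


class TestLohBurden:
    def test_fraction_of_layout(self):
        segs = [seg("chr1", 0, 43_000_000, loh=True), seg("chr2", 0, 10**7)]
        assert loh_burden(segs, LAYOUT) == pytest.approx(43e6 / 200e6)

    def test_zero_loh(self):
        assert loh_burden([seg("chr1", 0, 10**7)], LAYOUT) == 0.0

    def test_additive_over_chromosomes(self):
        a = [seg("chr1", 0, 20_000_000, loh=True)]
        b = [seg("chr2", 5_000_000, 30_000_000, loh=True)]
        assert loh_burden(a + b, LAYOUT) == pytest.approx(
            loh_burden(a, LAYOUT) + loh_burden(b, LAYOUT)
        )


class TestClassification:
    def test_published_cohort_has_ten_hrd_high(self):
        df = classify_samples(cohort_tables.hrd_table())
        assert (df.hrd_class == "HRD-high").sum() == 10

    def test_published_low_score_low_burden_samples_are_e_o_p(self):
        df = classify_samples(cohort_tables.hrd_table())
        flagged = df[(df.hrd_score < 10) & (df.loh_burden < 0.10)]
        assert sorted(flagged.sample_id) == ["E", "O", "P"]

    def test_boundary_score_fifteen_is_high(self):
        import pandas as pd

        df = classify_samples(
            pd.DataFrame([{"sample_id": "X", "hrd_score": 15, "loh_burden": 0.2}])
        )
        assert df.hrd_class.iloc[0] == "HRD-high"

    def test_empty_input_gives_empty_labels(self):
        assert classify_samples([]).empty


class TestLohOccurrence:
    def test_single_fully_loh_sample_fills_every_bin(self):
        segs = {"S1": [seg("chr1", 0, 100_000_000, loh=True),
                       seg("chr2", 0, 100_000_000, loh=True)]}
        df = loh_occurrence(segs, LAYOUT, bin_size=10_000_000)
        assert (df.samples_with_loh == 1).all()

    def test_constructed_fourteen_of_sixteen_recovered(self):
        cohort = {}
        for i in range(16):
            segments = []
            if i < 14:
                segments.append(seg("chr1", 54_000_000, 70_000_000, loh=True))
            cohort[f"P{i}"] = segments
        df = loh_occurrence(cohort, LAYOUT, bin_size=1_000_000)
        region = df[(df.chrom == "chr1") & (df.start >= 54_000_000) & (df.end <= 70_000_000)]
        assert (region.samples_with_loh == 14).all()
        outside = df[(df.chrom == "chr1") & (df.end <= 54_000_000)]
        assert (outside.samples_with_loh == 0).all()

    def test_random_cohorts_match_brute_force_bin_overlap(self):
        rng = np.random.default_rng(2)
        cohort = {}
        for i in range(6):
            segments = []
            for _ in range(rng.integers(1, 5)):
                start = int(rng.integers(0, 90_000_000))
                end = start + int(rng.integers(1_000_000, 10_000_000))
                segments.append(seg("chr1", start, min(end, 10**8), loh=True))
            # avoid overlaps within a sample by spacing via sort+clip
            segments = sorted(segments, key=lambda s: s.start)
            pruned = []
            cursor = 0
            for s in segments:
                if s.start >= cursor:
                    pruned.append(s)
                    cursor = s.end
            cohort[f"P{i}"] = pruned
        bin_size = 2_000_000
        df = loh_occurrence(cohort, LAYOUT, bin_size=bin_size)
        for row in df[df.chrom == "chr1"].itertuples():
            expect = sum(
                any(s.start < row.end and row.start < s.end for s in segs)
                for segs in cohort.values()
            )
            assert row.samples_with_loh == expect
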