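#!/usr/bin/env python
"""HRD/LOH scoring: synthetic cohort plus the published score column.

Scores every synthetic sample (HRD score, HRD-like score, LOH burden,
classification), builds the cohort LOH occurrence track, and reproduces
the published cohort classification (HRD-high count, low-score/low-burden
samples) from the printed score and burden columns.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from ovatime import cohort_tables
from ovatime.core import DEFAULT_LAYOUT, read_segments, write_table
from ovatime.loh import classify_samples, loh_occurrence, summarize_sample


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/hrd"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    summaries = []
    cohort_segments = {}
    for sample_dir in sorted(args.cohort_dir.iterdir()):
        seg_path = sample_dir / "segments.seg"
        if not seg_path.exists():
            continue
        segments = read_segments(seg_path)
        ploidy = json.loads((sample_dir / "profile.json").read_text())["ploidy"]
        summaries.append(summarize_sample(sample_dir.name, segments, DEFAULT_LAYOUT, ploidy))
        cohort_segments[sample_dir.name] = segments
    labelled = classify_samples(summaries)
    write_table(labelled, args.out_dir / "hrd_summary.tsv")
    print(labelled.to_string(index=False))

    occurrence = loh_occurrence(cohort_segments, DEFAULT_LAYOUT, bin_size=1_000_000)
    write_table(occurrence, args.out_dir / "loh_occurrence.tsv")
    peak = occurrence.loc[occurrence.samples_with_loh.idxmax()]
    print(f"LOH most common at {peak.chrom}:{peak.start}-{peak.end} "
          f"({peak.samples_with_loh} samples)")

    published = classify_samples(cohort_tables.hrd_table())
    write_table(published, args.out_dir / "published_classification.tsv")
    high = (published.hrd_class == "HRD-high").sum()
    low = published[(published.hrd_score < 10) & (published.loh_burden < 0.10)]
    print(f"published cohort: {high} of {len(published)} HRD-high; "
          f"low-score/low-burden samples: {', '.join(sorted(low.sample_id))}")


if __name__ == "__main__":
    main()
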