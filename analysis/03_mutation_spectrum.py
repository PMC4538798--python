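#!/usr/bin/env python
"""Mutation-spectrum statistics over the filtered cohort.

Reports the category count table, context-normalized substitution rates
with the exonic CpG-vs-non-CpG C>T contrast (paired t), Ts/Tv per
chromosome, the exonic vs non-exonic rate comparison, and the per-sample
non-synonymous/synonymous ratio.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from ovatime.core import DEFAULT_LAYOUT, read_variants, write_table
from ovatime.simulate import default_exons, synthetic_opportunities
from ovatime.spectrum import (
    build_spectrum,
    context_normalized_rates,
    ns_s_ratio,
    regional_rate_comparison,
    tabulate_by_annotation,
    tstv_by_chromosome,
)
from ovatime.stats import paired_t


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/spectrum"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    variants = []
    for sample_dir in sorted(args.cohort_dir.iterdir()):
        vcf = sample_dir / "pass.vcf"
        if vcf.exists():
            variants += read_variants(vcf, sample_id=sample_dir.name)
    exons = default_exons(DEFAULT_LAYOUT)
    opps = synthetic_opportunities(DEFAULT_LAYOUT, exons)

    table = tabulate_by_annotation(variants)
    table.counts.to_csv(args.out_dir / "category_counts.tsv", sep="\t")
    print(f"{table.grand_total()} mutations across {len(table.counts)} samples")

    rates = context_normalized_rates(build_spectrum(variants, exons, opps))
    write_table(rates, args.out_dir / "spectrum_rates.tsv")
    ct = rates[(rates.type == "C>T") & (rates.region == "exonic")]
    wide = ct.pivot_table(index="sample", columns="cpg", values="rate")
    if set(wide.columns) >= {True, False}:
        paired = wide.dropna()
        t, p = paired_t(paired[True], paired[False])
        print(f"exonic CpG vs non-CpG C>T rate: t={t:.2f}, one-sided p={p / 2:.2e}")

    write_table(tstv_by_chromosome(variants, DEFAULT_LAYOUT),
                args.out_dir / "tstv_by_chrom.tsv")

    regional = regional_rate_comparison(variants, exons, DEFAULT_LAYOUT)
    write_table(regional.per_sample, args.out_dir / "regional_rates.tsv")
    print(f"non-exonic vs exonic rate: t={regional.t_statistic:.2f}, "
          f"p={regional.p_value:.2e}")

    ns_df, mean_ratio = ns_s_ratio(variants)
    write_table(ns_df, args.out_dir / "ns_s_ratio.tsv")
    print(f"mean NS/S ratio over samples with defined ratio: {mean_ratio:.2f}")


if __name__ == "__main__":
    main()
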