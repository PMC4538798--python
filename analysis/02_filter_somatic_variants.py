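#!/usr/bin/env python
"""Apply the somatic filter battery to every cohort sample.

Writes per-sample pass.vcf plus a cohort-wide verdict summary counting how
often each rule fires.  On clean synthetic calls most variants pass; the
summary shows which rules reject the rest.
"""

from __future__ import annotations

import argparse
from collections import Counter
from pathlib import Path

import pandas as pd

from ovatime.core import read_variants, write_table, write_variants
from ovatime.filters import apply_snv_filters


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/filter_summary.tsv"))
    args = ap.parse_args()

    rows = []
    rule_counts: Counter[str] = Counter()
    for sample_dir in sorted(args.cohort_dir.iterdir()):
        vcf = sample_dir / "variants.vcf"
        if not vcf.exists():
            continue
        variants = read_variants(vcf, sample_id=sample_dir.name)
        verdicts = apply_snv_filters(variants)
        passing = [v.variant for v in verdicts if v.passed]
        for v in verdicts:
            rule_counts.update(v.failed_rules)
        write_variants(passing, sample_dir / "pass.vcf")
        rows.append({"sample": sample_dir.name, "total": len(variants),
                     "passing": len(passing),
                     "pass_fraction": len(passing) / len(variants)})
        print(f"{sample_dir.name}: {len(passing)}/{len(variants)} pass")
    write_table(pd.DataFrame(rows), args.out)
    print("rule failure counts:", dict(rule_counts))


if __name__ == "__main__":
    main()
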