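#!/usr/bin/env python
"""Temporal ordering of mutations relative to deletions: the F factor.

Two parts: (i) parameter recovery — noise-free inversion plus binomial
read noise at depth 100 over 50 regions; (ii) the gene-contrast scenario
at the study's scale (7 regions, depth 46): a cohort whose region
mutations all predate their deletions (F near 1, timing-neutral Wilcoxon)
against one where mutations arose in half the deletion clone after the
event (F near 0.5, significant Wilcoxon) — the qualitative pattern that
separates early-mutated from late-deleted genes.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ovatime.core import write_table
from ovatime.simulate import simulate_timing_pairs
from ovatime.timing import TimingPair, estimate_f, expected_maf


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/timing"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    # noise-free round trip
    pairs = [TimingPair("s", "g", m=expected_maf(0.6, 0.9, f), cna=0.54)
             for f in np.linspace(0.1, 1.0, 10)]
    est = estimate_f(pairs)
    max_err = max(abs(f - t) for f, t in zip(est.f_values, np.linspace(0.1, 1.0, 10)))
    print(f"noise-free inversion max |f_i - truth| = {max_err:.2e}")

    # noisy recovery
    recs = []
    for f_true in (0.4, 0.6, 0.8, 1.0):
        estimates = [
            estimate_f(simulate_timing_pairs(50, 100, 0.6, 1.0, f_true, rng)).F
            for _ in range(100)
        ]
        recs.append({"f_true": f_true, "mean_F": float(np.mean(estimates)),
                     "rmse": float(np.sqrt(np.mean((np.array(estimates) - f_true) ** 2)))})
        print(f"f={f_true}: mean F={recs[-1]['mean_F']:.3f}, RMSE={recs[-1]['rmse']:.3f}")
    write_table(pd.DataFrame(recs), args.out_dir / "recovery.tsv")

    # study-scale gene contrast
    rows = []
    for label, f_true in (("mutations_before_deletion", 1.0),
                          ("half_clone_mutated_after", 0.5)):
        est = estimate_f(simulate_timing_pairs(7, 46, 0.6, 1.0, f_true, rng,
                                               snvs_per_region=5))
        rows.append({"scenario": label, "F": est.F, "loo_min": est.loo_range[0],
                     "loo_max": est.loo_range[1], "p_wilcoxon": est.p_wilcoxon,
                     "n": est.n})
        print(f"{label}: F={est.F:.3f} [{est.loo_range[0]:.3f}-{est.loo_range[1]:.3f}], "
              f"one-sided Wilcoxon p={est.p_wilcoxon:.4f} (n={est.n})")
    write_table(pd.DataFrame(rows), args.out_dir / "scenario_contrast.tsv")


if __name__ == "__main__":
    main()
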