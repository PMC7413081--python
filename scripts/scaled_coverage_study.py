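#!/usr/bin/env python
"""Scaled-down well-calibrated coverage study (hours on one CPU).

20 replicates x 8 conditions of 8-taxon, 100-site alignments with shorter
chains.  Every coverage entry is checked against the exact binomial 99%
acceptance band for p = 0.95 at N = 20 and the verdict is printed with the
table.  This is the practical end-to-end calibration check; the full-size
study is scripts/full_coverage_study.py.
"""

import argparse
import pathlib

import numpy as np
from scipy import stats

from aamava import StudyConfig, run_well_calibrated_study
from aamava.summaries import write_coverage_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=pathlib.Path,
                    default=pathlib.Path("coverage_scaled.tsv"))
    ap.add_argument("--replicates", type=int, default=20)
    ap.add_argument("--n-taxa", type=int, default=8)
    ap.add_argument("--n-sites", type=int, default=100)
    ap.add_argument("--chain-length", type=int, default=100_000)
    args = ap.parse_args()

    cfg = StudyConfig(n_replicates=args.replicates, n_taxa=args.n_taxa,
                      n_sites=args.n_sites, chain_length=args.chain_length,
                      log_every=max(1, args.chain_length // 2000))
    table, _ = run_well_calibrated_study(cfg, args.seed, keep_records=False)
    write_coverage_table(table, args.out)

    n = args.replicates
    lo = 100.0 * stats.binom.ppf(0.005, n, 0.95) / n
    hi = 100.0
    print(table.to_string(float_format=lambda v: f"{v:5.1f}"))
    bad = []
    for cond in table.columns:
        for row, val in table[cond].dropna().items():
            if not lo <= val <= hi:
                bad.append((row, cond, val))
    print(f"\nbinomial 99% acceptance band for p=0.95, N={n}: "
          f"[{lo:.1f}, {hi:.1f}]")
    if bad:
        print("entries outside the band:")
        for row, cond, val in bad:
            print(f"  {row} / {cond}: {val:.1f}")
    else:
        print("all coverage entries inside the band")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
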