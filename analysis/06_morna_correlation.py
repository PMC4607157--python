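#!/usr/bin/env python
"""Correlate each moRNA with the miRNA produced from the same hairpin arm.

Pearson correlation of normalized expression profiles across samples,
two-sided p-values from the t transform, BH q-values with significance at
q <= 0.1, plus the summary statistics of the correlation distribution.
"""

import argparse
from pathlib import Path

import pandas as pd

from srnapipe.diffstats import correlation_summary, morna_mirna_correlation


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    res = args.results

    norm = pd.read_csv(res / "normalized_counts.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(res / "features.tsv", sep="\t", index_col=0)
    pairs = morna_mirna_correlation(norm, meta)
    pairs.to_csv(res / "morna_mirna_correlation.tsv", sep="\t", index=False)

    stats = correlation_summary(pairs)
    print(pairs.round(3).to_string(index=False))
    print(
        f"\n{stats['n_pairs']} moRNA-miRNA same-arm pairs; "
        f"median r {stats['median_r']:.2f}, mean r {stats['mean_r']:.2f}; "
        f"{stats['n_significant']} significant at q <= 0.1"
    )
    anticorrelated = int((pairs["r"] < 0).sum())
    print(f"anticorrelated pairs: {anticorrelated} "
          f"({anticorrelated / max(1, stats['n_pairs']):.0%})")


if __name__ == "__main__":
    main()
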