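#!/usr/bin/env python
"""Differential expression of features and isomiRs; detection summary.

Conditioned NB exact test on filter-passing features with BH correction at
FDR 0.05 and a +-15 cap on log2 fold changes (a one-sided zero reports the
cap exactly); Welch t-tests on log2-normalized isomiR counts flagged at
|log2FC| >= 1 and adjusted p < 0.05; and the per-class detection summary
table. Calls are compared against the planted truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from srnapipe.diffstats import de_table, isomir_de, summary_report
from srnapipe.quantify import fit_and_select, size_factors


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    res = args.results

    counts = pd.read_csv(res / "feature_counts.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(res / "features.tsv", sep="\t", index_col=0)
    iso = pd.read_csv(res / "isomir_counts.tsv", sep="\t", index_col=0)
    sheet = pd.read_csv(res / "data/reference/samples.tsv", sep="\t")
    groups = dict(zip(sheet["sample"], sheet["group"]))

    sf = size_factors(counts)
    fit = fit_and_select(counts, sf, groups)
    de = de_table(counts, sf, groups, fit)
    de.to_csv(res / "de_features.tsv", sep="\t")
    sig = de[de["significant"]].sort_values("padj")
    print(f"{len(sig)} significant features at FDR 0.05:")
    print(sig[["mean_a", "mean_b", "log2fc", "padj"]].round(3).to_string())

    truth = pd.read_csv(res / "data/reads/truth.tsv", sep="\t").set_index("feature_id")
    planted = set(truth.index[truth["is_de"]])
    called = set(sig.index)
    print(
        f"\nplanted DE features: {len(planted)}; called: {len(called)}; "
        f"true positives: {len(planted & called)}"
    )
    capped = de[de["log2fc"].abs() == 15.0]
    if len(capped):
        print("features at the +-15 cap (absent from one group):")
        print(capped[["mean_a", "mean_b", "log2fc"]].to_string())

    iso_de = isomir_de(iso, sf, groups, feature_totals=counts)
    iso_de.to_csv(res / "de_isomirs.tsv", sep="\t")
    n_flagged = int(iso_de["significant"].sum())
    n_corr = int(iso_de["in_correlation_set"].sum())
    print(
        f"\nisomiR level: {n_flagged} flagged (|log2FC|>=1, adj p<0.05); "
        f"{n_corr} isomiRs contribute >=10% of their mature and enter the "
        "correlation report"
    )

    summary = summary_report(counts, meta, groups)
    summary.to_csv(res / "summary.tsv", sep="\t")
    print("\ndetection summary (expressed = any read in group):")
    print(summary.to_string())


if __name__ == "__main__":
    main()
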