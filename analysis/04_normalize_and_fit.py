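#!/usr/bin/env python
"""Normalize counts, fit the dispersion-mean relationship, cluster samples.

Median-of-ratios size factors; parametric (a0 + a1/q) versus local-regression
dispersion fits compared by residual sum of squares; Euclidean/complete-
linkage clustering of samples on log2(normalized + 1) at three expression
filters (all features, above the median, above the third quartile).
"""

import argparse
from pathlib import Path

import pandas as pd

from srnapipe.diffstats import cluster_samples
from srnapipe.quantify import fit_dispersion, normalize, select_fit, size_factors


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    res = args.results

    counts = pd.read_csv(res / "feature_counts.tsv", sep="\t", index_col=0)
    sheet = pd.read_csv(res / "data/reference/samples.tsv", sep="\t")
    groups = dict(zip(sheet["sample"], sheet["group"]))

    sf = size_factors(counts)
    sf.to_frame().to_csv(res / "size_factors.tsv", sep="\t")
    norm = normalize(counts, sf)
    norm.to_csv(res / "normalized_counts.tsv", sep="\t")
    print("size factors:\n" + sf.round(3).to_string())

    par = fit_dispersion(counts, sf, "parametric", groups)
    loc = fit_dispersion(counts, sf, "local", groups)
    chosen = select_fit(par, loc)
    pd.DataFrame(
        [{"method": chosen.method, **chosen.params}]
    ).to_csv(res / "dispersion_fit.tsv", sep="\t", index=False)
    print(
        f"\ndispersion fits: parametric RSS {par.rss:.4g}, local RSS {loc.rss:.4g} "
        f"-> {chosen.method} selected"
    )

    for filt in ("all", "above_median", "above_q3"):
        _, dist, newick = cluster_samples(norm, filter=filt)
        (res / f"dendrogram_{filt}.nwk").write_text(newick + "\n")
        dist.to_csv(res / f"distances_{filt}.tsv", sep="\t")
        within = [
            dist.loc[a, b]
            for a in dist.index for b in dist.index
            if a < b and groups[a] == groups[b]
        ]
        between = [
            dist.loc[a, b]
            for a in dist.index for b in dist.index
            if a < b and groups[a] != groups[b]
        ]
        print(
            f"clustering ({filt}): mean within-group distance "
            f"{sum(within)/len(within):.1f}, between-group {sum(between)/len(between):.1f}"
        )


if __name__ == "__main__":
    main()
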