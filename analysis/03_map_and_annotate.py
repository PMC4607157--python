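#!/usr/bin/env python
"""Map unique tags, filter multi-mappers, and build the feature catalogue.

Tags are aligned ungapped (<= 2 mismatches) to the genome and to hairpins
extended by 30 bp per side; tags recurring at more than 5 genomic loci
outside hairpin regions are discarded. Kept tags become known-miRNA isomiRs,
star-arm (new) miRNAs, or moRNAs. Writes the catalogue, per-feature and
per-isomiR counts, and compares calls against the planted truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from srnapipe.align import ReferenceIndex, align_tags, multimap_filter, write_sam
from srnapipe.annotate import annotate
from srnapipe.io import read_tag_table
from srnapipe.quantify import feature_counts, isomir_counts
from srnapipe.reference import extend_hairpins, load_reference


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    res = args.results

    tags = read_tag_table(res / "tags.tsv")
    ref = res / "data/reference"
    genome, hairpins = load_reference(
        ref / "genome.fa", ref / "hairpins.fa", ref / "matures.gff3"
    )
    extended = extend_hairpins(hairpins, genome, flank=30)
    index = ReferenceIndex(genome, extended)

    alignments = align_tags(list(tags.index), index)
    verdicts = multimap_filter(alignments, index)
    write_sam(res / "alignments.sam", alignments, index)
    statuses = pd.Series([v.status for v in verdicts.values()]).value_counts()
    print("mapping verdicts:\n" + statuses.to_string())

    catalogue = annotate(index, verdicts, tags)
    meta = catalogue.meta_frame()
    meta.to_csv(res / "features.tsv", sep="\t")
    feature_counts(catalogue, tags).to_csv(res / "feature_counts.tsv", sep="\t")
    iso = isomir_counts(catalogue, tags)
    iso.to_csv(res / "isomir_counts.tsv", sep="\t")

    truth = pd.read_csv(res / "data/reads/truth.tsv", sep="\t")
    print("\ncalled feature classes:\n" + meta["class"].value_counts().to_string())
    for klass in ("moRNA", "new_miRNA"):
        planted = set(truth.loc[truth["class"] == klass, "feature_id"])
        called = set(meta.index[meta["class"] == klass])
        tp = len(planted & called)
        print(
            f"{klass}: planted {len(planted)}, called {len(called)}, "
            f"sensitivity {tp / len(planted):.2f}, precision {tp / len(called):.2f}"
        )
    cats = iso["category"].value_counts(normalize=True).round(3)
    print("\nisomiR category mix (unique tags):\n" + cats.to_string())


if __name__ == "__main__":
    main()
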