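"""File-format helpers: FASTA, FASTQ, miRBase-dialect GFF3, tag tables.

Sequence formats go through Biopython; the GFF3 dialect used for mature-miRNA
annotation (nine tab columns, ``ID=``/``Derives_from=`` attributes, 1-based
inclusive coordinates) is simple enough to read and write directly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def read_fasta(path: str | Path) -> dict[str, str]:
    """Return ``{record id: uppercase sequence}`` for a FASTA file."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(seqs, str(path), "fasta")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read id, sequence, quality string) from a Phred+33 FASTQ."""
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq.upper(), qual


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as handle:
        for name, seq, qual in reads:
            handle.write(f"@{name}\n{seq}\n+\n{qual}\n")


@dataclasses.dataclass
class Gff3Feature:
    """One row of a miRBase-dialect GFF3 file (1-based inclusive coords)."""

    seqid: str
    type: str  # miRNA_primary_transcript | miRNA
    start: int
    end: int
    strand: str
    attributes: dict[str, str]

    @property
    def feature_id(self) -> str:
        return self.attributes["ID"]


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    feats: list[Gff3Feature] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line (expected 9 columns): {line!r}")
            attrs = {}
            for field in cols[8].split(";"):
                if field and "=" in field:
                    key, value = field.split("=", 1)
                    attrs[key.strip()] = value.strip()
            feats.append(
                Gff3Feature(
                    seqid=cols[0],
                    type=cols[2],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    attributes=attrs,
                )
            )
    return feats


def write_gff3(path: str | Path, features: Iterable[Gff3Feature], source: str = "srnapipe") -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for feat in features:
            attrs = ";".join(f"{k}={v}" for k, v in feat.attributes.items())
            handle.write(
                f"{feat.seqid}\t{source}\t{feat.type}\t{feat.start}\t{feat.end}"
                f"\t.\t{feat.strand}\t.\t{attrs}\n"
            )


def read_tag_table(path: str | Path) -> pd.DataFrame:
    """Read a collapsed-tag TSV (column ``sequence`` + one count column per sample)."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("sequence")


def write_tag_table(path: str | Path, tags: pd.DataFrame) -> None:
    tags.to_csv(path, sep="\t", index_label="sequence")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for line in handle:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                continue
            sets[cols[0]] = {g for g in cols[2:] if g}
    return sets


def write_gmt(path: str | Path, sets: dict[str, Iterable[str]]) -> None:
    with open(path, "w") as handle:
        for name, genes in sets.items():
            genes = sorted(genes)
            handle.write("\t".join([name, "na"] + genes) + "\n")
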