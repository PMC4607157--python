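"""Extended-hairpin reference construction and coordinate maps.

A hairpin precursor annotated on the genome is extended by ``flank`` bases on
each side (default 30) so that small RNAs processed just outside the canonical
precursor — miRNA-offset RNAs — still map within a single reference sequence.
Internally all intervals are 0-based half-open; every emitted genomic
coordinate is 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
from Bio.Seq import reverse_complement

from . import io as _io

DEFAULT_FLANK = 30


@dataclasses.dataclass
class MatureAnnotation:
    """An annotated mature miRNA, located on its hairpin.

    ``interval`` is hairpin-local, 0-based half-open; ``arm`` is which side of
    the hairpin midpoint the mature sits on.
    """

    mature_id: str
    arm: str  # "5p" | "3p"
    interval: tuple[int, int]
    sequence: str

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be 5p or 3p, got {self.arm!r}")
        start, end = self.interval
        if not (0 <= start < end):
            raise ValueError(f"bad mature interval {self.interval}")


@dataclasses.dataclass
class HairpinRecord:
    """A precursor sequence with its genomic locus and annotated matures."""

    hairpin_id: str
    sequence: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    matures: list[MatureAnnotation] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"{self.hairpin_id}: locus span {self.end - self.start + 1} "
                f"!= sequence length {len(self.sequence)}"
            )
        for mat in self.matures:
            s, e = mat.interval
            if e > len(self.sequence):
                raise ValueError(f"{mat.mature_id} outside hairpin {self.hairpin_id}")
            if mat.sequence and self.sequence[s:e] != mat.sequence:
                raise ValueError(
                    f"{mat.mature_id}: annotated sequence disagrees with hairpin "
                    f"{self.hairpin_id} at {mat.interval}"
                )


@dataclasses.dataclass
class ExtendedHairpin:
    """A hairpin plus genomic flanks, with the local->genomic coordinate map."""

    hairpin_id: str
    sequence: str
    flank_left: int  # bases actually added on the extended 5' side
    flank_right: int
    hairpin: HairpinRecord

    @property
    def offset(self) -> int:
        """Shift mapping hairpin-local to extended-local coordinates."""
        return self.flank_left

    def mature_intervals_extended(self) -> dict[str, tuple[int, int]]:
        return {
            m.mature_id: (m.interval[0] + self.offset, m.interval[1] + self.offset)
            for m in self.hairpin.matures
        }

    def to_genomic(self, interval: tuple[int, int]) -> tuple[str, int, int, str]:
        """Map an extended-local 0-based half-open interval to a 1-based
        inclusive genomic span on the annotated strand."""
        start, end = interval
        if not (0 <= start < end <= len(self.sequence)):
            raise ValueError(
                f"interval {interval} outside extended hairpin {self.hairpin_id}"
            )
        hp = self.hairpin
        if hp.strand == "+":
            gstart = hp.start - self.flank_left + start
            gend = gstart + (end - start) - 1
        else:
            # extended-local runs 3'->5' along the + strand of the genome
            gend = hp.end + self.flank_left - start
            gstart = gend - (end - start) + 1
        return hp.contig, gstart, gend, hp.strand

    def from_genomic(self, gstart: int, gend: int) -> tuple[int, int]:
        """Inverse of :meth:`to_genomic` (1-based inclusive genomic input)."""
        hp = self.hairpin
        if hp.strand == "+":
            start = gstart - (hp.start - self.flank_left)
        else:
            start = (hp.end + self.flank_left) - gend
        end = start + (gend - gstart) + 1
        if not (0 <= start < end <= len(self.sequence)):
            raise ValueError(f"genomic span {gstart}-{gend} outside {self.hairpin_id}")
        return start, end

    def genomic_locus(self) -> tuple[str, int, int]:
        """Genomic span of the full extended sequence (1-based inclusive)."""
        hp = self.hairpin
        if hp.strand == "+":
            return hp.contig, hp.start - self.flank_left, hp.end + self.flank_right
        return hp.contig, hp.start - self.flank_right, hp.end + self.flank_left


def extend_hairpins(
    hairpins: list[HairpinRecord],
    genome: dict[str, str],
    flank: int = DEFAULT_FLANK,
) -> list[ExtendedHairpin]:
    """Add ``flank`` genomic bases per side to each hairpin, strand-aware.

    Flanks are truncated (and the truncation recorded) at contig ends. A
    hairpin whose annotated sequence disagrees with the genome at its locus is
    an error: the reference bundle is inconsistent.
    """
    extended = []
    for hp in hairpins:
        contig = genome[hp.contig]
        window = contig[hp.start - 1 : hp.end]
        expected = window if hp.strand == "+" else reverse_complement(window)
        if expected != hp.sequence:
            raise ValueError(
                f"hairpin {hp.hairpin_id} sequence disagrees with genome at "
                f"{hp.contig}:{hp.start}-{hp.end}({hp.strand})"
            )
        left_genomic = min(flank, hp.start - 1)  # + strand upstream
        right_genomic = min(flank, len(contig) - hp.end)
        big = contig[hp.start - 1 - left_genomic : hp.end + right_genomic]
        if hp.strand == "+":
            seq, fl, fr = big, left_genomic, right_genomic
        else:
            seq, fl, fr = reverse_complement(big), right_genomic, left_genomic
        extended.append(
            ExtendedHairpin(
                hairpin_id=hp.hairpin_id,
                sequence=seq,
                flank_left=fl,
                flank_right=fr,
                hairpin=hp,
            )
        )
    return extended


def load_reference(
    genome_fa: str | Path, hairpin_fa: str | Path, mature_gff: str | Path
) -> tuple[dict[str, str], list[HairpinRecord]]:
    """Load a reference bundle from FASTA + miRBase-dialect GFF3 files."""
    genome = _io.read_fasta(genome_fa)
    hairpin_seqs = _io.read_fasta(hairpin_fa)
    feats = _io.read_gff3(mature_gff)

    hairpins: dict[str, HairpinRecord] = {}
    for feat in feats:
        if feat.type != "miRNA_primary_transcript":
            continue
        hid = feat.feature_id
        if hid in hairpins:
            raise ValueError(f"duplicate hairpin ID {hid}")
        if hid not in hairpin_seqs:
            raise ValueError(f"hairpin {hid} annotated but absent from FASTA")
        hairpins[hid] = HairpinRecord(
            hairpin_id=hid,
            sequence=hairpin_seqs[hid],
            contig=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand,
        )
    for feat in feats:
        if feat.type != "miRNA":
            continue
        hid = feat.attributes["Derives_from"]
        hp = hairpins[hid]
        # genomic -> hairpin-local
        if hp.strand == "+":
            start = feat.start - hp.start
        else:
            start = hp.end - feat.end
        end = start + (feat.end - feat.start) + 1
        seq = hp.sequence[start:end]
        arm = feat.attributes.get("arm") or (
            "5p" if (start + end) / 2 < len(hp.sequence) / 2 else "3p"
        )
        mat = MatureAnnotation(
            mature_id=feat.feature_id, arm=arm, interval=(start, end), sequence=seq
        )
        if any(m.mature_id == mat.mature_id for m in hp.matures):
            raise ValueError(f"duplicate mature ID {mat.mature_id}")
        hp.matures.append(mat)
    return genome, list(hairpins.values())


def write_reference_index(path: str | Path, extended: list[ExtendedHairpin]) -> None:
    rows = []
    for ext in extended:
        contig, start, end = ext.genomic_locus()
        rows.append(
            {
                "hairpin_id": ext.hairpin_id,
                "contig": contig,
                "start": start,
                "end": end,
                "strand": ext.hairpin.strand,
                "flank_left": ext.flank_left,
                "flank_right": ext.flank_right,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
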