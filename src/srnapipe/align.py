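"""Ungapped full-length alignment of unique tags, and the multi-mapping filter.

The aligner is exhaustive at toy-genome scale: exact 5-mer seeds (pigeonhole
over three tag segments guarantees every hit with up to 2 mismatches is
seeded) are verified with vectorized full-length comparison. Tags are aligned
to both strands of the genome and to the forward orientation of the extended
hairpins. Tags whose exact sequence recurs at more than 5 genomic loci
outside hairpin regions are discarded as unlikely miRNA products.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from Bio.Seq import reverse_complement

from .reference import ExtendedHairpin

SEED_K = 5
MAX_MISMATCHES = 2
MAX_GENOMIC_LOCI = 5

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclasses.dataclass(frozen=True)
class TagAlignment:
    tag: str
    target: str  # extended-hairpin id or genome contig
    position: int  # target-local start, 0-based
    strand: str
    mismatches: int
    mismatch_positions: tuple[int, ...]  # tag-local


@dataclasses.dataclass
class MappingVerdict:
    tag: str
    hairpin_hits: list[TagAlignment]
    genomic_loci_outside_hairpins: int
    status: str  # kept | discarded_multimapper | unaligned


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_CODE[b] for b in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"tag contains non-ACGTN character: {exc}") from exc


class SeedIndex:
    """Exact 5-mer position index over one target sequence."""

    def __init__(self, name: str, sequence: str):
        self.name = name
        self.codes = _encode(sequence)
        n = len(self.codes)
        if n >= SEED_K:
            kmers = np.zeros(n - SEED_K + 1, dtype=np.int64)
            valid = np.ones(n - SEED_K + 1, dtype=bool)
            for i in range(SEED_K):
                window = self.codes[i : n - SEED_K + 1 + i]
                kmers = kmers * 4 + np.minimum(window, 3)
                valid &= window < 4
            order = np.argsort(kmers, kind="stable")
            self._sorted_kmers = kmers[order]
            self._positions = order
            self._valid = valid
        else:
            self._sorted_kmers = np.empty(0, dtype=np.int64)
            self._positions = np.empty(0, dtype=np.int64)
            self._valid = np.empty(0, dtype=bool)

    def seed_hits(self, kmer_code: int) -> np.ndarray:
        lo = np.searchsorted(self._sorted_kmers, kmer_code, side="left")
        hi = np.searchsorted(self._sorted_kmers, kmer_code, side="right")
        pos = self._positions[lo:hi]
        return pos[self._valid[pos]]

    def align(self, tag_codes: np.ndarray, max_mismatches: int) -> list[tuple[int, int, tuple[int, ...]]]:
        """All ungapped full-length hits: (position, n_mismatch, positions)."""
        L = len(tag_codes)
        n = len(self.codes)
        if n < L:
            return []
        if L < (max_mismatches + 1) * SEED_K:
            # too short for disjoint seeds: verify every offset directly
            candidates = set(range(0, n - L + 1))
            return self._verify(tag_codes, candidates, max_mismatches)
        # pigeonhole: with <=2 mismatches one of three disjoint seeds is exact
        offsets = sorted({0, L // 3, 2 * (L // 3), L - SEED_K})[: max_mismatches + 1]
        candidates = set()
        for off in offsets:
            seg = tag_codes[off : off + SEED_K]
            if np.any(seg > 3):
                continue
            code = 0
            for b in seg:
                code = code * 4 + int(b)
            for pos in self.seed_hits(code):
                start = int(pos) - off
                if 0 <= start <= n - L:
                    candidates.add(start)
        return self._verify(tag_codes, candidates, max_mismatches)

    def _verify(
        self, tag_codes: np.ndarray, candidates: set[int], max_mismatches: int
    ) -> list[tuple[int, int, tuple[int, ...]]]:
        L = len(tag_codes)
        if not candidates:
            return []
        starts = np.fromiter(sorted(candidates), dtype=np.int64)
        windows = self.codes[starts[:, None] + np.arange(L)]
        diff = (windows != tag_codes) | (windows > 3) | (tag_codes > 3)
        nmm = diff.sum(axis=1)
        hits = []
        for idx in np.nonzero(nmm <= max_mismatches)[0]:
            positions = tuple(int(p) for p in np.nonzero(diff[idx])[0])
            hits.append((int(starts[idx]), int(nmm[idx]), positions))
        return hits


class ReferenceIndex:
    """Seed indexes for the genome (both strands) and extended hairpins."""

    def __init__(self, genome: dict[str, str], extended: list[ExtendedHairpin]):
        self.genome_fwd = {c: SeedIndex(c, s) for c, s in genome.items()}
        self.genome_rev = {
            c: SeedIndex(c, reverse_complement(s)) for c, s in genome.items()
        }
        self.genome_lengths = {c: len(s) for c, s in genome.items()}
        self.hairpins = {e.hairpin_id: SeedIndex(e.hairpin_id, e.sequence) for e in extended}
        self.extended = {e.hairpin_id: e for e in extended}
        # genomic spans covered by extended hairpins, 0-based half-open
        self.hairpin_spans: dict[str, list[tuple[int, int]]] = {}
        for ext in extended:
            contig, start, end = ext.genomic_locus()
            self.hairpin_spans.setdefault(contig, []).append((start - 1, end))


def align_tags(
    tags: list[str],
    index: ReferenceIndex,
    max_mismatches: int = MAX_MISMATCHES,
) -> dict[str, list[TagAlignment]]:
    """All ungapped full-length hits of each tag, deterministically ordered.

    Genome hits are reported on both strands (minus-strand positions refer to
    the forward contig coordinate of the alignment start); extended-hairpin
    hits on the forward orientation only.
    """
    results: dict[str, list[TagAlignment]] = {}
    for tag in tags:
        codes = _encode(tag)
        hits: list[TagAlignment] = []
        for contig, idx in index.genome_fwd.items():
            for pos, nmm, mmpos in idx.align(codes, max_mismatches):
                hits.append(TagAlignment(tag, contig, pos, "+", nmm, mmpos))
        for contig, idx in index.genome_rev.items():
            n = index.genome_lengths[contig]
            for pos, nmm, mmpos in idx.align(codes, max_mismatches):
                fwd_pos = n - pos - len(tag)
                hits.append(TagAlignment(tag, contig, fwd_pos, "-", nmm, mmpos))
        for hid, idx in index.hairpins.items():
            for pos, nmm, mmpos in idx.align(codes, max_mismatches):
                hits.append(TagAlignment(tag, hid, pos, "+", nmm, mmpos))
        hits.sort(key=lambda h: (h.target, h.position, h.strand, h.mismatches))
        results[tag] = hits
    return results


def _outside_hairpin_loci(
    alignments: list[TagAlignment], index: ReferenceIndex, tag_len: int
) -> int:
    """Distinct exact genomic loci not overlapping any hairpin locus +- flank.

    Loci differing in position or strand are distinct. Only 0-mismatch genome
    hits are counted: the filter asks where the exact sequence recurs.
    """
    count = 0
    for aln in alignments:
        if aln.target not in index.genome_lengths or aln.mismatches != 0:
            continue
        spans = index.hairpin_spans.get(aln.target, [])
        lo, hi = aln.position, aln.position + tag_len
        if not any(lo < e and hi > s for s, e in spans):
            count += 1
    return count


def multimap_filter(
    alignments: dict[str, list[TagAlignment]],
    index: ReferenceIndex,
    max_loci: int = MAX_GENOMIC_LOCI,
) -> dict[str, MappingVerdict]:
    """Apply the comparative multi-mapping filter.

    A tag recurring at more than ``max_loci`` genomic loci outside hairpin
    regions (hairpin locus +- flank) is discarded; a tag with no hit anywhere
    is unaligned; everything else is kept.
    """
    verdicts: dict[str, MappingVerdict] = {}
    for tag, hits in alignments.items():
        hairpin_hits = [h for h in hits if h.target in index.hairpins]
        n_outside = _outside_hairpin_loci(hits, index, len(tag))
        if not hits:
            status = "unaligned"
        elif n_outside > max_loci:
            status = "discarded_multimapper"
        else:
            status = "kept"
        verdicts[tag] = MappingVerdict(tag, hairpin_hits, n_outside, status)
    return verdicts


def naive_align(
    tag: str, target: str, max_mismatches: int = MAX_MISMATCHES
) -> list[tuple[int, int]]:
    """Sliding-window oracle: (position, mismatches) at every offset.

    Reference implementation used to validate the seeded aligner on small
    targets; O(len(target) * len(tag)).
    """
    out = []
    L = len(tag)
    for pos in range(len(target) - L + 1):
        window = target[pos : pos + L]
        nmm = sum(1 for a, b in zip(window, tag) if a != b or a == "N" or b == "N")
        if nmm <= max_mismatches:
            out.append((pos, nmm))
    return out


def write_sam(
    path: str | Path,
    alignments: dict[str, list[TagAlignment]],
    index: ReferenceIndex,
) -> None:
    """Export hairpin/genome alignments as a text SAM with NM tags set."""
    import pysam

    names = list(index.genome_lengths) + list(index.hairpins)
    lengths = [index.genome_lengths[c] for c in index.genome_lengths] + [
        len(index.extended[h].sequence) for h in index.hairpins
    ]
    header = pysam.AlignmentHeader.from_references(names, lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for tag in sorted(alignments):
            for i, hit in enumerate(alignments[tag]):
                a = pysam.AlignedSegment(header)
                a.query_name = tag
                seq = tag if hit.strand == "+" else reverse_complement(tag)
                a.query_sequence = seq
                a.reference_id = names.index(hit.target)
                a.reference_start = hit.position
                a.cigarstring = f"{len(tag)}M"
                a.flag = (16 if hit.strand == "-" else 0) | (256 if i > 0 else 0)
                a.mapping_quality = 255
                a.set_tag("NM", hit.mismatches)
                sam.write(a)
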