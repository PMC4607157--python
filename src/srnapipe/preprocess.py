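"""Per-sample read cleaning and collapsing.

Stages, in order: 3' adapter clipping (adapter-only and unclipped reads are
discarded), length window 15-30 nt inclusive, quality filter (mean base
quality strictly above 30 and at most 2 bases under quality 20), then
collapsing identical sequences into unique tags and removal of ground noise —
unique sequences seen fewer than 10 times in a sample.
"""

from __future__ import annotations

import collections
import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from . import io as _io

MIN_LENGTH = 15
MAX_LENGTH = 30
MIN_MEAN_QUALITY = 30.0
LOW_QUALITY = 20
MAX_LOW_QUALITY_BASES = 2
NOISE_FLOOR = 10
MIN_ADAPTER_OVERLAP = 5


@dataclasses.dataclass
class ReadRecord:
    read_id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


def _phred(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]


def clip_adapter(read: ReadRecord, adapter: str) -> ReadRecord | str:
    """Truncate a read at the leftmost adapter occurrence.

    The adapter may enter the read anywhere with a minimum overlap of 5 nt at
    the read's 3' end and up to 1 mismatch per 10 aligned bases (N counts as a
    mismatch). Returns the clipped read, or the verdict string
    ``"adapter_only"`` (empty insert) / ``"unclipped"`` (no adapter found) —
    both verdicts mean the read is discarded.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.sequence
    n = len(seq)
    for start in range(0, n - MIN_ADAPTER_OVERLAP + 1):
        aligned = min(n - start, len(adapter))
        if aligned < MIN_ADAPTER_OVERLAP:
            break
        allowed = aligned // 10
        mismatches = 0
        ok = True
        for a, b in zip(seq[start : start + aligned], adapter[:aligned]):
            if a != b or a == "N":
                mismatches += 1
                if mismatches > allowed:
                    ok = False
                    break
        if ok:
            if start == 0:
                return "adapter_only"
            return ReadRecord(read.read_id, seq[:start], read.qualities[:start])
    return "unclipped"


def length_filter(read: ReadRecord) -> bool:
    """Keep iff the clipped length lies in the inclusive window [15, 30]."""
    return MIN_LENGTH <= len(read.sequence) <= MAX_LENGTH


def quality_filter(read: ReadRecord) -> bool:
    """Keep iff mean quality > 30 (strict) and <= 2 bases with quality < 20.

    N bases count as quality 0.
    """
    quals = [0 if b == "N" else q for b, q in zip(read.sequence, read.qualities)]
    if not quals:
        return False
    if sum(quals) / len(quals) <= MIN_MEAN_QUALITY:
        return False
    return sum(1 for q in quals if q < LOW_QUALITY) <= MAX_LOW_QUALITY_BASES


@dataclasses.dataclass
class AttritionReport:
    """Read counts discarded per reason, per sample."""

    sample: str
    total: int = 0
    adapter_only: int = 0
    unclipped: int = 0
    bad_length: int = 0
    low_quality: int = 0
    noise: int = 0  # reads lost to the ground-noise filter
    kept: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def clean_reads(
    reads: Iterable[ReadRecord], adapter: str, report: AttritionReport
) -> Iterator[ReadRecord]:
    """Apply clip -> length -> quality, tallying discards by reason."""
    for read in reads:
        report.total += 1
        clipped = clip_adapter(read, adapter)
        if clipped == "adapter_only":
            report.adapter_only += 1
            continue
        if clipped == "unclipped":
            report.unclipped += 1
            continue
        assert isinstance(clipped, ReadRecord)
        if not length_filter(clipped):
            report.bad_length += 1
            continue
        if not quality_filter(clipped):
            report.low_quality += 1
            continue
        yield clipped


def collapse_and_denoise(
    per_sample_sequences: dict[str, Iterable[str]],
    noise_floor: int = NOISE_FLOOR,
    noise_scope: str = "per_sample",
    reports: dict[str, AttritionReport] | None = None,
) -> pd.DataFrame:
    """Collapse identical sequences into unique tags and drop ground noise.

    With ``noise_scope="per_sample"`` (default) a unique sequence seen fewer
    than ``noise_floor`` times in a sample has its count zeroed for that
    sample; with ``"pooled"`` the threshold applies to the count summed over
    samples. A tag survives if it retains a non-zero count in at least one
    sample. Returns a tags x samples count DataFrame.
    """
    if noise_scope not in ("per_sample", "pooled"):
        raise ValueError(f"unknown noise_scope {noise_scope!r}")
    samples = list(per_sample_sequences)
    counters = {s: collections.Counter(per_sample_sequences[s]) for s in samples}
    all_tags = sorted(set().union(*[set(c) for c in counters.values()])) if samples else []
    if not all_tags:
        import warnings

        warnings.warn("collapse_and_denoise: no input reads", stacklevel=2)
        return pd.DataFrame(columns=samples, dtype=int)

    df = pd.DataFrame(
        {s: [counters[s].get(t, 0) for t in all_tags] for s in samples},
        index=pd.Index(all_tags, name="sequence"),
        dtype=int,
    )
    if noise_scope == "per_sample":
        removed = df.where(df >= noise_floor, 0)
    else:
        removed = df.where(df.sum(axis=1) >= noise_floor, 0)
    if reports is not None:
        lost = (df - removed).sum(axis=0)
        for s in samples:
            reports[s].noise += int(lost[s])
            reports[s].kept = int(removed[s].sum())
    return removed[removed.sum(axis=1) > 0]


def preprocess_sample(
    fastq_path: str | Path, adapter: str, sample: str
) -> tuple[list[str], AttritionReport]:
    """Clean one FASTQ and return surviving insert sequences + attrition."""
    report = AttritionReport(sample=sample)
    reads = (
        ReadRecord(rid, seq, _phred(qual))
        for rid, seq, qual in _io.iter_fastq(fastq_path)
    )
    survivors = [r.sequence for r in clean_reads(reads, adapter, report)]
    return survivors, report


def preprocess_samples(
    fastqs: dict[str, str | Path],
    adapter: str,
    noise_floor: int = NOISE_FLOOR,
    noise_scope: str = "per_sample",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full preprocessing stage for a set of sample FASTQs.

    Returns (tag count table, attrition report table).
    """
    sequences: dict[str, list[str]] = {}
    reports: dict[str, AttritionReport] = {}
    for sample, path in fastqs.items():
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"FASTQ not found: {path}")
        sequences[sample], reports[sample] = preprocess_sample(path, adapter, sample)
    tags = collapse_and_denoise(
        sequences, noise_floor=noise_floor, noise_scope=noise_scope, reports=reports
    )
    report_df = pd.DataFrame([r.as_dict() for r in reports.values()]).set_index("sample")
    return tags, report_df
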