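"""Synthetic small RNA-seq data with planted truth.

The generator emulates the statistical structure the downstream analysis
assumes: a two-group design (default 3 control vs 3 disease samples),
negative-binomially distributed counts per small RNA, isomiR mixtures in which
the annotated ("exact") sequence carries roughly one third of a miRNA's reads
and end variation is dominated by the 3' end, miRNA-offset RNA (moRNA) read
clusters beyond the mature boundaries with a strong 5'-arm bias, star-arm
clusters on hairpins with a single annotated mature ("new" miRNAs),
adapter-bearing reads, low-quality and adapter-only/unclipped read fractions,
low-count ground-noise sequences, decoy repeated loci for the multi-mapping
filter, and planted differential expression including one moRNA expressed only
in the control group.

Every random draw goes through numpy Generators seeded from ``SimConfig.seed``,
so a fixed configuration yields byte-identical FASTQ output.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from . import io as _io
from .reference import DEFAULT_FLANK, ExtendedHairpin, HairpinRecord, MatureAnnotation, extend_hairpins

BASES = np.array(list("ACGT"))

# Illumina TruSeq small-RNA 3' adapter and downstream sequence context.
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
_POST_ADAPTER = "AACTCCAGTCACATCACGATCTCGTATGCCGTCTTCTGCTTG"

ISOMIR_CATEGORIES = (
    "exact",
    "shorter_longer_3p",
    "shorter_longer_5p",
    "shorter_longer_both",
    "mismatch1",
    "mismatch2",
)

DEFAULT_ISOMIR_PROFILE = {
    # "exact" near one third of a miRNA's reads; end variation mostly 3'.
    "exact": 0.34,
    "shorter_longer_3p": 0.32,
    "shorter_longer_5p": 0.03,
    "shorter_longer_both": 0.05,
    "mismatch1": 0.18,
    "mismatch2": 0.08,
}


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions the pipeline targets: 3 vs 3
    samples, NB dispersion 0.2, a 5'-arm probability of 0.84 for planted
    moRNAs, and an isomiR mixture whose exact form carries about one third of
    the reads.
    """

    n_hairpins: int = 30
    n_samples_per_group: int = 3
    mean_depth: int = 50_000
    isomir_profile: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ISOMIR_PROFILE)
    )
    morna_fraction: float = 0.3
    morna_arm_bias: float = 0.84
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.2
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    seed: int = 0

    # reference geometry
    genome_length: int = 1_000_000
    contig: str = "chr_sim"
    flank: int = DEFAULT_FLANK
    single_arm_fraction: float = 0.3
    new_mirna_fraction: float = 0.8  # single-arm hairpins that express the star arm
    decoy_multiplicities: tuple = (1, 2, 4, 6, 8, 10)
    decoy_length: int = 22

    # library structure
    read_length: int = 50
    scale_factor_range: tuple = (0.5, 2.0)
    frac_adapter_only: float = 0.02
    frac_unclipped: float = 0.02
    frac_low_quality: float = 0.03
    frac_bad_length: float = 0.02  # inserts outside the 15-30 nt window
    frac_noise_tags: float = 0.03
    q_high: float = 38.0
    q_low: float = 15.0
    mu_range: tuple = (30.0, 3000.0)
    control_only_morna: bool = True

    def validate(self) -> None:
        prof = self.isomir_profile
        if set(prof) != set(ISOMIR_CATEGORIES):
            raise ValueError(f"isomir_profile must have keys {ISOMIR_CATEGORIES}")
        total = sum(prof.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"isomir_profile sums to {total}, expected 1")
        if any(not (0.0 <= v <= 1.0) for v in prof.values()):
            raise ValueError("isomir_profile proportions must lie in [0, 1]")
        for name in ("morna_fraction", "morna_arm_bias", "de_fraction",
                     "single_arm_fraction", "new_mirna_fraction",
                     "frac_adapter_only", "frac_unclipped",
                     "frac_low_quality", "frac_bad_length", "frac_noise_tags"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    @property
    def samples(self) -> list[str]:
        n = self.n_samples_per_group
        return [f"CTR{i + 1}" for i in range(n)] + [f"PMF{i + 1}" for i in range(n)]

    @property
    def groups(self) -> dict[str, str]:
        return {s: ("CTR" if s.startswith("CTR") else "PMF") for s in self.samples}


@dataclasses.dataclass
class TruthFeature:
    feature_id: str
    klass: str  # known_miRNA | new_miRNA | moRNA
    hairpin_id: str
    arm: str
    interval: tuple[int, int]  # extended-local, 0-based half-open
    sequence: str


@dataclasses.dataclass
class TruthSet:
    """Planted features, their DE status and expected/realized counts."""

    features: list[TruthFeature]
    de_status: dict[str, tuple[bool, float]]
    expected: pd.DataFrame  # features x samples expected NB means
    samples: list[str]
    groups: dict[str, str]
    counts: pd.DataFrame | None = None
    scale_factors: pd.Series | None = None

    def feature(self, feature_id: str) -> TruthFeature:
        return next(f for f in self.features if f.feature_id == feature_id)


@dataclasses.dataclass
class ReferenceBundle:
    genome: dict[str, str]
    hairpins: list[HairpinRecord]
    extended: list[ExtendedHairpin]
    decoys: list[tuple[str, list[int]]]  # (sequence, 0-based genome positions)
    truth: TruthSet
    config: SimConfig


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, pos: int) -> str:
    alt = [b for b in "ACGT" if b != seq[pos]]
    return seq[:pos] + alt[rng.integers(0, 3)] + seq[pos + 1 :]


def _star_interval(start: int, end: int, hairpin_len: int) -> tuple[int, int]:
    """Mirror a duplex interval across a perfect stem with a 2-nt 3' overhang.

    For a perfect inverted repeat, position x pairs with H-1-x; both duplex
    products overhang by 2 nt at their 3' ends, which shifts the mirrored
    interval by +2 in hairpin coordinates on either arm.
    """
    return hairpin_len - end + 2, hairpin_len - start + 2


def make_reference(config: SimConfig) -> ReferenceBundle:
    """Build the toy genome, hairpins, annotations and planted truth features.

    Each hairpin is an imperfect inverted repeat embedded at a unique genomic
    locus (half on the minus strand); decoy 22-mers are embedded at the
    configured multiplicities outside hairpin loci to exercise the
    multi-mapping filter; a configurable fraction of hairpins carries a single
    annotated mature so the opposite (star) arm can be discovered.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    glen = config.genome_length

    genome_arr = rng.integers(0, 4, size=glen)
    occupied: list[tuple[int, int]] = []  # 0-based half-open, with flank margin

    def place(length: int, margin: int) -> int:
        for _ in range(10_000):
            pos = int(rng.integers(margin, glen - length - margin))
            lo, hi = pos - margin, pos + length + margin
            if all(hi <= s or lo >= e for s, e in occupied):
                occupied.append((lo, hi))
                return pos
        raise RuntimeError("could not place sequence in genome; enlarge it")

    hairpins: list[HairpinRecord] = []
    features: list[TruthFeature] = []
    hairpin_meta = []  # per-hairpin plan used after extension

    for i in range(config.n_hairpins):
        arm_len = int(rng.integers(26, 31))
        loop_len = int(rng.integers(10, 16))
        arm5 = _random_seq(rng, arm_len)
        loop = _random_seq(rng, loop_len)
        arm3 = reverse_complement(arm5)
        # one substitution mid-arm keeps the stem imperfect but foldable
        arm3 = _mutate(rng, arm3, int(rng.integers(8, arm_len - 8)))
        hp_seq = arm5 + loop + arm3
        if len(hp_seq) > glen:
            raise ValueError("hairpin longer than genome contig")
        hlen = len(hp_seq)

        mlen = int(rng.integers(21, 24))
        s5 = int(rng.integers(2, 4))
        m5 = (s5, s5 + mlen)
        m3 = _star_interval(*m5, hlen)

        single_arm = rng.random() < config.single_arm_fraction
        annotated_arm = "5p" if (not single_arm or rng.random() < 0.5) else "3p"

        hid = f"mir-{i:04d}"
        matures = []
        if not single_arm or annotated_arm == "5p":
            matures.append(
                MatureAnnotation(f"miR-{i:04d}-5p", "5p", m5, hp_seq[m5[0] : m5[1]])
            )
        if not single_arm or annotated_arm == "3p":
            matures.append(
                MatureAnnotation(f"miR-{i:04d}-3p", "3p", m3, hp_seq[m3[0] : m3[1]])
            )

        strand = "+" if rng.random() < 0.5 else "-"
        pos = place(hlen, config.flank + 5)
        ins = hp_seq if strand == "+" else reverse_complement(hp_seq)
        genome_arr[pos : pos + hlen] = [("ACGT".index(b)) for b in ins]
        hairpins.append(
            HairpinRecord(
                hairpin_id=hid,
                sequence=hp_seq,
                contig=config.contig,
                start=pos + 1,
                end=pos + hlen,
                strand=strand,
                matures=matures,
            )
        )
        hairpin_meta.append(
            {
                "hid": hid,
                "single_arm": single_arm,
                "annotated_arm": annotated_arm,
                "m5": m5,
                "m3": m3,
                "hlen": hlen,
            }
        )

    # decoy repeats outside hairpin loci
    decoys: list[tuple[str, list[int]]] = []
    for mult in config.decoy_multiplicities:
        seq = _random_seq(rng, config.decoy_length)
        positions = []
        for _ in range(mult):
            pos = place(config.decoy_length, 2)
            genome_arr[pos : pos + config.decoy_length] = [
                "ACGT".index(b) for b in seq
            ]
            positions.append(pos)
        decoys.append((seq, positions))

    genome_seq = "".join(BASES[genome_arr])
    genome = {config.contig: genome_seq}
    extended = extend_hairpins(hairpins, genome, config.flank)
    ext_by_id = {e.hairpin_id: e for e in extended}

    # plant features in extended-local coordinates
    seen_ids: set[str] = set()
    morna_count = 0
    for meta, hp in zip(hairpin_meta, hairpins):
        ext = ext_by_id[meta["hid"]]
        off = ext.offset

        for mat in hp.matures:
            fid = mat.mature_id
            features.append(
                TruthFeature(
                    feature_id=fid,
                    klass="known_miRNA",
                    hairpin_id=hp.hairpin_id,
                    arm=mat.arm,
                    interval=(mat.interval[0] + off, mat.interval[1] + off),
                    sequence=mat.sequence,
                )
            )

        if meta["single_arm"] and rng.random() < config.new_mirna_fraction:
            mat = hp.matures[0]
            star = _star_interval(*mat.interval, meta["hlen"])
            interval = (star[0] + off, star[1] + off)
            seq = ext.sequence[interval[0] : interval[1]]
            arm = "3p" if mat.arm == "5p" else "5p"
            features.append(
                TruthFeature(
                    feature_id=f"{mat.mature_id}*",
                    klass="new_miRNA",
                    hairpin_id=hp.hairpin_id,
                    arm=arm,
                    interval=interval,
                    sequence=seq,
                )
            )

        if rng.random() < config.morna_fraction:
            arm = "5p" if rng.random() < config.morna_arm_bias else "3p"
            mlen2 = int(rng.integers(19, 23))
            gap = int(rng.integers(0, 2))
            if arm == "5p":
                end = meta["m5"][0] + off - gap
                interval = (end - mlen2, end)
            else:
                start = meta["m3"][1] + off + gap
                interval = (start, start + mlen2)
            seq = ext.sequence[interval[0] : interval[1]]
            features.append(
                TruthFeature(
                    feature_id=f"moR-{hp.hairpin_id.split('-', 1)[1]}-{arm}",
                    klass="moRNA",
                    hairpin_id=hp.hairpin_id,
                    arm=arm,
                    interval=interval,
                    sequence=seq,
                )
            )
            morna_count += 1

    for feat in features:
        if feat.feature_id in seen_ids:
            raise ValueError(f"duplicate feature ID {feat.feature_id}")
        seen_ids.add(feat.feature_id)
        lo, hi = feat.interval
        ext = ext_by_id[feat.hairpin_id]
        if not (0 <= lo < hi <= len(ext.sequence)):
            raise AssertionError(f"{feat.feature_id} outside its extended hairpin")

    truth = _plan_expression(config, features, rng)
    return ReferenceBundle(
        genome=genome,
        hairpins=hairpins,
        extended=extended,
        decoys=decoys,
        truth=truth,
        config=config,
    )


def _plan_expression(
    config: SimConfig, features: list[TruthFeature], rng: np.random.Generator
) -> TruthSet:
    samples = config.samples
    groups = config.groups
    n = len(features)
    lo, hi = config.mu_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    # rescale so the expected read total matches the insert budget
    budget = config.mean_depth * (
        1.0
        - config.frac_adapter_only
        - config.frac_unclipped
        - config.frac_low_quality
        - config.frac_bad_length
        - config.frac_noise_tags
    )
    mu *= budget / mu.sum()

    de_status: dict[str, tuple[bool, float]] = {}
    is_de = rng.random(n) < config.de_fraction
    signs = rng.choice([-1.0, 1.0], size=n)
    expected = pd.DataFrame(0.0, index=[f.feature_id for f in features], columns=samples)
    for i, feat in enumerate(features):
        fc = signs[i] * config.de_log2fc if is_de[i] else 0.0
        de_status[feat.feature_id] = (bool(is_de[i]), fc)
        for s in samples:
            shift = fc / 2 if groups[s] == "PMF" else -fc / 2
            expected.loc[feat.feature_id, s] = mu[i] * 2.0 ** shift

    if config.control_only_morna:
        morna_ids = [f.feature_id for f in features if f.klass == "moRNA"]
        if morna_ids:
            # mirror the motivating case: highly expressed in controls
            # (above the third quartile of feature means), absent in disease
            chosen = sorted(morna_ids)[0]
            de_status[chosen] = (True, -15.0)
            floor = float(np.percentile(mu, 75))
            for s in samples:
                if groups[s] == "PMF":
                    expected.loc[chosen, s] = 0.0
                else:
                    expected.loc[chosen, s] = max(expected.loc[chosen, s], floor)

    return TruthSet(
        features=features,
        de_status=de_status,
        expected=expected,
        samples=samples,
        groups=groups,
    )


def abstract_truth(config: SimConfig, n_features: int) -> TruthSet:
    """A count-only truth set (no sequences) for count-level simulations."""
    rng = np.random.default_rng(config.seed)
    features = [
        TruthFeature(f"f{i:05d}", "known_miRNA", "", "5p", (0, 1), "")
        for i in range(n_features)
    ]
    return _plan_expression(config, features, rng)


def simulate_counts(config: SimConfig, truth: TruthSet) -> pd.DataFrame:
    """Draw the per-sample NB count matrix and per-sample scale factors.

    Counts follow NB(mean = mu_i * s_j * 2^{±fc/2}, dispersion alpha) with the
    sample scale factors s_j drawn log-uniformly from ``scale_factor_range``
    and recorded in the truth set.
    """
    alpha = config.nb_dispersion
    if alpha <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.scale_factor_range
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(truth.samples)))
    scale = pd.Series(s, index=truth.samples)

    means = truth.expected.mul(scale, axis=1)
    mu = means.to_numpy()
    if alpha < 1e-8:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / alpha
        p = 1.0 / (1.0 + alpha * mu)
        counts = np.where(mu > 0, rng.negative_binomial(r, np.maximum(p, 1e-12)), 0)
    truth.counts = pd.DataFrame(
        counts.astype(np.int64), index=truth.expected.index, columns=truth.samples
    )
    truth.scale_factors = scale
    return truth.counts


def _quality_string(rng: np.random.Generator, length: int, center: float) -> str:
    q = np.clip(np.rint(rng.normal(center, 2.0, size=length)), 2, 40).astype(np.uint8)
    return (q + 33).tobytes().decode("ascii")


def _realize_read(
    rng: np.random.Generator,
    ext_seq: str,
    interval: tuple[int, int],
    category: str,
) -> str | None:
    """One insert sequence for a feature, per its isomiR category.

    Returns None if an end offset would leave the extended hairpin (the caller
    resamples).
    """
    start, end = interval
    d5 = d3 = 0
    if category == "shorter_longer_3p":
        d3 = int(rng.choice([-2, -1, 1, 2]))
    elif category == "shorter_longer_5p":
        d5 = int(rng.choice([-2, -1, 1, 2]))
    elif category == "shorter_longer_both":
        d5 = int(rng.choice([-2, -1, 1, 2]))
        d3 = int(rng.choice([-2, -1, 1, 2]))
    s, e = start + d5, end + d3
    if s < 0 or e > len(ext_seq) or e - s < 15:
        return None
    seq = ext_seq[s:e]
    if category in ("mismatch1", "mismatch2"):
        k = 1 if category == "mismatch1" else 2
        positions = rng.choice(len(seq), size=k, replace=False)
        for pos in positions:
            alt = [b for b in "ACGT" if b != seq[pos]]
            seq = seq[: pos] + alt[rng.integers(0, 3)] + seq[pos + 1 :]
    return seq


def emit_fastq(
    config: SimConfig, bundle: ReferenceBundle, outdir: str | Path
) -> dict[str, Path]:
    """Write one Phred+33 FASTQ per sample plus the truth table.

    Counts are realized with :func:`simulate_counts` when not already drawn;
    each feature's count becomes reads from its isomiR mixture with the 3'
    adapter appended, alongside configured fractions of adapter-only,
    unclipped and low-quality reads, decoy-locus reads, and unique ground-noise
    sequences with per-sample count < 10.
    """
    truth = bundle.truth
    if truth.counts is None:
        simulate_counts(config, truth)
    rng = np.random.default_rng(config.seed + 2)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext_by_id = {e.hairpin_id: e for e in bundle.extended}
    profile_p = np.array([config.isomir_profile[c] for c in ISOMIR_CATEGORIES])
    adapter_tail = config.adapter + _POST_ADAPTER
    rl = config.read_length

    paths: dict[str, Path] = {}
    n_resampled = 0
    for sample in truth.samples:
        reads: list[tuple[str, str, str]] = []
        serial = 0

        def add(insert: str, center: float) -> None:
            nonlocal serial
            full = (insert + adapter_tail)[:rl]
            reads.append(
                (f"{sample}_r{serial:07d}", full, _quality_string(rng, len(full), center))
            )
            serial += 1

        for feat in truth.features:
            count = int(truth.counts.loc[feat.feature_id, sample])
            if count == 0:
                continue
            ext_seq = ext_by_id[feat.hairpin_id].sequence
            if feat.klass == "known_miRNA":
                cats = rng.choice(len(ISOMIR_CATEGORIES), size=count, p=profile_p)
                categories = [ISOMIR_CATEGORIES[c] for c in cats]
            else:
                # cluster features: mostly one dominant sequence, light 3' jitter
                jitter = rng.random(count) < 0.1
                categories = [
                    "shorter_longer_3p" if j else "exact" for j in jitter
                ]
            for cat in categories:
                insert = _realize_read(rng, ext_seq, feat.interval, cat)
                while insert is None:
                    n_resampled += 1
                    insert = _realize_read(rng, ext_seq, feat.interval, "exact")
                add(insert, config.q_high)

        depth = config.mean_depth
        for seq, _pos in bundle.decoys:
            for _ in range(int(rng.integers(12, 30))):
                add(seq, config.q_high)
        for _ in range(rng.poisson(config.frac_adapter_only * depth)):
            add("", config.q_high)
        for _ in range(rng.poisson(config.frac_unclipped * depth)):
            full = _random_seq(rng, rl)
            reads.append((f"{sample}_r{serial:07d}", full, _quality_string(rng, rl, config.q_high)))
            serial += 1
        for _ in range(rng.poisson(config.frac_low_quality * depth)):
            insert = _random_seq(rng, int(rng.integers(18, 26)))
            add(insert, config.q_low)
        for _ in range(rng.poisson(config.frac_bad_length * depth)):
            length = int(rng.choice([8, 10, 12, 14, 31, 33, 36, 40]))
            add(_random_seq(rng, length), config.q_high)
        n_noise = max(1, int(config.frac_noise_tags * depth / 5))
        for _ in range(n_noise):
            insert = _random_seq(rng, int(rng.integers(15, 31)))
            for _ in range(int(rng.integers(1, 10))):
                add(insert, config.q_high)

        path = outdir / f"{sample}.fastq"
        _io.write_fastq(path, reads)
        paths[sample] = path

    write_truth(truth, outdir / "truth.tsv")
    if n_resampled:
        print(f"emit_fastq: resampled {n_resampled} reads whose offsets left the extended hairpin")
    return paths


def write_truth(truth: TruthSet, path: str | Path) -> None:
    rows = []
    for feat in truth.features:
        is_de, fc = truth.de_status[feat.feature_id]
        rows.append(
            {
                "feature_id": feat.feature_id,
                "class": feat.klass,
                "hairpin_id": feat.hairpin_id,
                "arm": feat.arm,
                "start": feat.interval[0],
                "end": feat.interval[1],
                "sequence": feat.sequence,
                "is_de": is_de,
                "true_log2fc": fc,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_reference(bundle: ReferenceBundle, outdir: str | Path) -> None:
    """Write genome/hairpin FASTA, the mature GFF3 and the sample sheet."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_fasta(outdir / "genome.fa", bundle.genome)
    _io.write_fasta(
        outdir / "hairpins.fa", {h.hairpin_id: h.sequence for h in bundle.hairpins}
    )
    feats = []
    for hp in bundle.hairpins:
        feats.append(
            _io.Gff3Feature(
                seqid=hp.contig,
                type="miRNA_primary_transcript",
                start=hp.start,
                end=hp.end,
                strand=hp.strand,
                attributes={"ID": hp.hairpin_id, "Name": hp.hairpin_id},
            )
        )
        for mat in hp.matures:
            s, e = mat.interval
            if hp.strand == "+":
                gstart, gend = hp.start + s, hp.start + e - 1
            else:
                gend, gstart = hp.end - s, hp.end - e + 1
            feats.append(
                _io.Gff3Feature(
                    seqid=hp.contig,
                    type="miRNA",
                    start=gstart,
                    end=gend,
                    strand=hp.strand,
                    attributes={
                        "ID": mat.mature_id,
                        "Name": mat.mature_id,
                        "Derives_from": hp.hairpin_id,
                        "arm": mat.arm,
                    },
                )
            )
    _io.write_gff3(outdir / "matures.gff3", feats)
    sheet = pd.DataFrame(
        {"sample": bundle.truth.samples,
         "group": [bundle.truth.groups[s] for s in bundle.truth.samples]}
    )
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)


def make_gene_sets(
    n_genes: int = 400, n_sets: int = 25, seed: int = 0
) -> tuple[list[str], dict[str, set[str]]]:
    """A synthetic gene universe and GMT-style gene-set collection for the
    enrichment stage (stand-in for a pathway annotation resource)."""
    rng = np.random.default_rng(seed)
    universe = [f"G{i:04d}" for i in range(n_genes)]
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(15, 50))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"SET{i:03d}"] = set(members)
    return universe, sets
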