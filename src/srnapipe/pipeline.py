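"""End-to-end orchestration of the small RNA pipeline stages.

Stages: simulate (optional) -> preprocess -> align -> annotate -> quantify ->
differential statistics. Each stage writes its artifacts as TSV/FASTA/GFF3
under the run directory so stages can also be run individually; a manifest
records the package version, seed and a hash of the configuration. Identical
configuration and seed give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io as _io
from . import align as _align
from .annotate import MIN_CLUSTER_COUNT, STAR_TOLERANCE, annotate as _annotate_tags
from . import diffstats as _diff
from . import preprocess as _pre
from . import quantify as _quant
from . import reference as _ref
from . import simdata as _sim


@dataclasses.dataclass
class PipelineConfig:
    """All pipeline parameters, with the analysis defaults.

    Defaults: 30-nt hairpin flanks, 15-30 nt length window, mean quality > 30
    with at most 2 bases under 20, ground-noise floor 10, multi-mapping bound
    5, BH FDR 0.05, log2 fold-change cap 15, correlation q 0.1, enrichment
    q 0.05.
    """

    outdir: str = "srnapipe_run"
    seed: int = 0
    simulate: bool = True
    # input paths (used when simulate is False)
    fastq_dir: str | None = None
    genome_fasta: str | None = None
    hairpin_fasta: str | None = None
    mature_gff3: str | None = None
    sample_sheet: str | None = None
    gene_sets_gmt: str | None = None
    target_lists_tsv: str | None = None

    adapter: str = _sim.TRUSEQ_SMALL_RNA_ADAPTER
    flank: int = _ref.DEFAULT_FLANK
    noise_floor: int = _pre.NOISE_FLOOR
    noise_scope: str = "per_sample"
    max_mismatches: int = _align.MAX_MISMATCHES
    max_genomic_loci: int = _align.MAX_GENOMIC_LOCI
    min_cluster_count: int = MIN_CLUSTER_COUNT
    star_tolerance: int = STAR_TOLERANCE
    fdr: float = _diff.DE_ALPHA
    log2fc_cap: float = _diff.LOG2FC_CAP
    correlation_q: float = _diff.CORRELATION_Q
    enrichment_q: float = _diff.ENRICHMENT_Q
    dispersion_sharing: str = "maximum"
    sim: dict = dataclasses.field(default_factory=dict)  # SimConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def sim_config(self) -> _sim.SimConfig:
        known = {f.name for f in dataclasses.fields(_sim.SimConfig)}
        unknown = set(self.sim) - known
        if unknown:
            raise ValueError(f"unknown sim keys: {sorted(unknown)}")
        overrides = dict(self.sim)
        overrides.setdefault("seed", self.seed)
        overrides.setdefault("adapter", self.adapter)
        overrides.setdefault("flank", self.flank)
        if "isomir_profile" in overrides:
            overrides["isomir_profile"] = dict(overrides["isomir_profile"])
        return _sim.SimConfig(**overrides)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Raises :class:`StageError` naming the failing stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        if config.simulate:
            sim_cfg = config.sim_config()
            bundle = _sim.make_reference(sim_cfg)
            _sim.simulate_counts(sim_cfg, bundle.truth)
            fastqs = _sim.emit_fastq(sim_cfg, bundle, out / "reads")
            _sim.write_reference(bundle, out / "reference")
            genome, hairpins = bundle.genome, bundle.hairpins
            groups = bundle.truth.groups
            adapter = sim_cfg.adapter
        else:
            for name in ("fastq_dir", "genome_fasta", "hairpin_fasta",
                         "mature_gff3", "sample_sheet"):
                path = getattr(config, name)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"{name} missing or not found: {path}")
            genome, hairpins = _ref.load_reference(
                config.genome_fasta, config.hairpin_fasta, config.mature_gff3
            )
            sheet = pd.read_csv(config.sample_sheet, sep="\t")
            groups = dict(zip(sheet["sample"], sheet["group"]))
            fastqs = {}
            for sample in groups:
                path = Path(config.fastq_dir) / f"{sample}.fastq"
                if not path.exists():
                    raise FileNotFoundError(f"FASTQ not found: {path}")
                fastqs[sample] = path
            adapter = config.adapter

        stage = "preprocess"
        tags, attrition = _pre.preprocess_samples(
            fastqs, adapter, noise_floor=config.noise_floor,
            noise_scope=config.noise_scope,
        )
        _io.write_tag_table(out / "tags.tsv", tags)
        attrition.to_csv(out / "attrition.tsv", sep="\t")

        stage = "reference"
        extended = _ref.extend_hairpins(hairpins, genome, config.flank)
        _io.write_fasta(
            out / "extended_hairpins.fa", {e.hairpin_id: e.sequence for e in extended}
        )
        _ref.write_reference_index(out / "extended_index.tsv", extended)

        stage = "align"
        index = _align.ReferenceIndex(genome, extended)
        alignments = _align.align_tags(
            list(tags.index), index, max_mismatches=config.max_mismatches
        )
        verdicts = _align.multimap_filter(
            alignments, index, max_loci=config.max_genomic_loci
        )
        _align.write_sam(out / "alignments.sam", alignments, index)
        pd.DataFrame(
            [
                {"tag": v.tag, "status": v.status,
                 "outside_loci": v.genomic_loci_outside_hairpins,
                 "hairpin_hits": len(v.hairpin_hits)}
                for v in verdicts.values()
            ]
        ).to_csv(out / "mapping_filter.tsv", sep="\t", index=False)

        stage = "annotate"
        catalogue = _annotate_tags(
            index, verdicts, tags,
            min_cluster_count=config.min_cluster_count,
            star_tolerance=config.star_tolerance,
        )
        meta = catalogue.meta_frame()
        meta.to_csv(out / "features.tsv", sep="\t")
        _write_feature_gff(out / "features.gff3", catalogue, index)

        stage = "quantify"
        counts = _quant.feature_counts(catalogue, tags)
        iso = _quant.isomir_counts(catalogue, tags)
        counts.to_csv(out / "feature_counts.tsv", sep="\t")
        if len(iso):
            iso.to_csv(out / "isomir_counts.tsv", sep="\t")
        sf = _quant.size_factors(counts)
        sf.to_frame().to_csv(out / "size_factors.tsv", sep="\t")
        norm = _quant.normalize(counts, sf)
        norm.to_csv(out / "normalized_counts.tsv", sep="\t")
        fit = _quant.fit_and_select(counts, sf, groups)
        pd.DataFrame([{"method": fit.method, **fit.params}]).to_csv(
            out / "dispersion_fit.tsv", sep="\t", index=False
        )

        stage = "differential"
        de = _diff.de_table(
            counts, sf, groups, fit, alpha=config.fdr,
            sharing=config.dispersion_sharing, cap=config.log2fc_cap,
        )
        de.to_csv(out / "de_features.tsv", sep="\t")
        if len(iso):
            samples = list(sf.index)
            iso_de = _diff.isomir_de(iso, sf, groups, feature_totals=counts)
            iso_de.to_csv(out / "de_isomirs.tsv", sep="\t")

        stage = "cluster"
        for filt in ("all", "above_median", "above_q3"):
            try:
                _, dist, newick = _diff.cluster_samples(norm, filter=filt)
            except ValueError:
                continue
            (out / f"dendrogram_{filt}.nwk").write_text(newick + "\n")
            dist.to_csv(out / f"distances_{filt}.tsv", sep="\t")

        stage = "correlate"
        pairs = _diff.morna_mirna_correlation(
            norm, meta, q_threshold=config.correlation_q
        )
        pairs.to_csv(out / "morna_mirna_correlation.tsv", sep="\t", index=False)

        stage = "enrich"
        if config.gene_sets_gmt and config.target_lists_tsv:
            sets = _io.read_gmt(config.gene_sets_gmt)
            targets = pd.read_csv(config.target_lists_tsv, sep="\t")
            universe = set().union(*sets.values())
            query = set(targets["gene"]) & universe
            enr = _diff.hypergeometric_enrichment(
                query, sets, universe, q_threshold=config.enrichment_q
            )
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)

        stage = "report"
        summary = _diff.summary_report(counts, meta, groups)
        summary.to_csv(out / "summary.tsv", sep="\t")
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
        raise StageError(stage, exc) from exc
    return out


def _write_feature_gff(path: Path, catalogue, index) -> None:
    feats = []
    type_by_class = {
        "known_miRNA": "miRNA",
        "new_miRNA": "miRNA",
        "moRNA": "moR",
    }
    for feat in catalogue.features:
        ext = index.extended[feat.hairpin_id]
        contig, gstart, gend, strand = ext.to_genomic(feat.interval)
        feats.append(
            _io.Gff3Feature(
                seqid=contig,
                type=type_by_class[feat.klass],
                start=gstart,
                end=gend,
                strand=strand,
                attributes={
                    "ID": feat.feature_id,
                    "Derives_from": feat.hairpin_id,
                    "class": feat.klass,
                    "arm": feat.arm,
                },
            )
        )
    _io.write_gff3(path, feats)
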