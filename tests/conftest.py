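"""Shared fixtures: a small synthetic study run once per session."""

from __future__ import annotations

import dataclasses

import pytest

import srnapipe as sp
from srnapipe import align as al
from srnapipe.annotate import annotate
from srnapipe.simdata import SimConfig, make_reference, simulate_counts, emit_fastq
from srnapipe.preprocess import preprocess_samples
from srnapipe import quantify as qt


SMALL_KW = dict(n_hairpins=8, genome_length=60_000, mean_depth=8_000, seed=3)


@dataclasses.dataclass
class StudyRun:
    """All intermediate artifacts of one synthetic study, for reuse."""

    config: SimConfig
    bundle: object
    tags: object
    attrition: object
    index: object
    alignments: dict
    verdicts: dict
    catalogue: object
    counts: object
    sf: object


def _run_study(config: SimConfig, tmpdir) -> StudyRun:
    bundle = make_reference(config)
    simulate_counts(config, bundle.truth)
    fastqs = emit_fastq(config, bundle, tmpdir)
    tags, attrition = preprocess_samples(fastqs, config.adapter)
    index = al.ReferenceIndex(bundle.genome, bundle.extended)
    alignments = al.align_tags(list(tags.index), index)
    verdicts = al.multimap_filter(alignments, index)
    catalogue = annotate(index, verdicts, tags)
    counts = qt.feature_counts(catalogue, tags)
    sf = qt.size_factors(counts)
    return StudyRun(
        config=config,
        bundle=bundle,
        tags=tags,
        attrition=attrition,
        index=index,
        alignments=alignments,
        verdicts=verdicts,
        catalogue=catalogue,
        counts=counts,
        sf=sf,
    )


@pytest.fixture(scope="session")
def small_study(tmp_path_factory) -> StudyRun:
    """An 8-hairpin study on a 60 kb contig, processed end to end."""
    cfg = SimConfig(**SMALL_KW)
    return _run_study(cfg, tmp_path_factory.mktemp("small_study"))


@pytest.fixture(scope="session")
def default_study(tmp_path_factory) -> StudyRun:
    """The default study conditions (30 hairpins, 1 Mb contig, 3v3)."""
    cfg = SimConfig(seed=1)
    return _run_study(cfg, tmp_path_factory.mktemp("default_study"))
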