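"""Shared fixtures: tiny hand-built annotations and one synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from txrefine.annotation_io import AnnotationSet, GenomicInterval, TranscriptModel
from txrefine.consolidate import RefineConfig, refine_annotation
from txrefine.synthetic_data import GeneratorConfig, generate_cohort

COHORT_SEED = 20126


def make_tx(
    tid: str,
    exons,
    strand: str = "+",
    contig: str = "c",
    gene: str | None = None,
    cds=(),
    **attrs,
) -> TranscriptModel:
    """Build a transcript from plain (start, end) tuples."""
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene or f"gene_{tid}",
        exons=tuple(GenomicInterval(contig, s, e, strand) for s, e in exons),
        cds=tuple(GenomicInterval(contig, s, e, strand) for s, e in cds),
        attributes=dict(attrs),
    )


def make_set(*transcripts) -> AnnotationSet:
    return AnnotationSet(transcripts)


@pytest.fixture(scope="session")
def cohort():
    """One deterministic synthetic cohort shared by the whole suite."""
    return generate_cohort(GeneratorConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def refined(cohort):
    """The full pipeline result on the shared cohort."""
    return refine_annotation(
        cohort.samples, cohort.reference, RefineConfig(), genome=cohort.genome
    )


@pytest.fixture
def rng():
    return np.random.default_rng(915)
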