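"""Multi-sample consolidation pipeline.

The pipeline mirrors a conservative reference-guided annotation
refinement workflow: per-sample assemblies are merged into one isoform
set, transcripts must be confirmed in at least two samples and exceed a
coverage floor, survivors are categorized against the reference
annotation by class code, transcripts fusing two same-strand reference
genes are discarded from the isoform sets, and new-gene candidates
overlapping the reference directly or indirectly (through single-sample
transcripts) are removed.  The result is a refined annotation with full
per-transcript provenance and per-gene boundary extensions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from . import intervals as ivl
from .annotation_io import AnnotationSet, TranscriptModel
from .transcript_algebra import (
    DEFAULT_RUN_ON_WINDOW,
    DEFAULT_SINGLE_EXON_OVERLAP,
    ClassCode,
    GeneCluster,
    classify_transcript,
    cluster_genes,
    junction_chain,
    single_exon_match,
    spans_multiple_genes,
)

log = logging.getLogger(__name__)


@dataclass
class SampleAnnotation:
    """One sample's assembled transcripts plus its design labels."""

    sample_id: str
    sex: str
    strain: str
    annotation: AnnotationSet


@dataclass
class SupportRecord:
    """A merged isoform with the samples and coverage backing it."""

    transcript: TranscriptModel
    supporting_samples: frozenset[str]
    max_coverage: float


@dataclass
class RefineConfig:
    min_samples: int = 2
    min_coverage: float = 2.0  # strict: kept iff coverage > min_coverage
    run_on_window: int = DEFAULT_RUN_ON_WINDOW
    single_exon_overlap_fraction: float = DEFAULT_SINGLE_EXON_OVERLAP
    cluster_min_overlap: float = 0.1


@dataclass
class CategorizedSets:
    """Class-code routed transcript sets after reference comparison."""

    extended_isoforms: list[SupportRecord] = field(default_factory=list)
    new_isoforms: list[SupportRecord] = field(default_factory=list)
    intronic_new: list[SupportRecord] = field(default_factory=list)
    intergenic_new: list[SupportRecord] = field(default_factory=list)
    run_on: list[SupportRecord] = field(default_factory=list)
    new_genes: list[GeneCluster] = field(default_factory=list)
    codes: dict[str, ClassCode] = field(default_factory=dict)
    dropped_overlap: int = 0  # 'o' transcripts, excluded downstream
    removed_fusions: list[str] = field(default_factory=list)
    removed_new_gene_transcripts: list[str] = field(default_factory=list)

    @property
    def new_gene_records(self) -> list[SupportRecord]:
        return self.intronic_new + self.intergenic_new


@dataclass
class RefinedAnnotation:
    annotation: AnnotationSet
    provenance: pd.DataFrame
    boundary_extensions: pd.DataFrame
    categorized: CategorizedSets
    specificity: dict
    stage_counts: dict


# ---------------------------------------------------------------------------
# merge and filter
# ---------------------------------------------------------------------------


def merge_samples(samples: list[SampleAnnotation]) -> list[SupportRecord]:
    """Pool per-sample transcripts into unique isoforms.

    Two transcripts are the same isoform iff their junction chains are
    identical (multi-exon) or they satisfy the single-exon reciprocal
    overlap criterion.  The representative keeps the widest termini over
    its members, the union of supporting samples and the maximum
    coverage/FPKM.
    """
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample_id among {ids}")

    members: dict[object, list[tuple[str, TranscriptModel]]] = {}
    singles: list[tuple[str, TranscriptModel]] = []
    for sample in samples:
        for t in sample.annotation:
            if t.is_multi_exon:
                chain = junction_chain(t)
                key = (chain.contig, chain.strand, chain.junctions)
                members.setdefault(key, []).append((sample.sample_id, t))
            else:
                singles.append((sample.sample_id, t))

    # single-exon transcripts: single-linkage under the '=' criterion
    frac = DEFAULT_SINGLE_EXON_OVERLAP
    parent = list(range(len(singles)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(singles)):
        for j in range(i + 1, len(singles)):
            a, b = singles[i][1], singles[j][1]
            if (
                a.contig == b.contig
                and a.strand == b.strand
                and single_exon_match(a, b, frac)
            ):
                parent[find(j)] = find(i)
    single_groups: dict[int, list[tuple[str, TranscriptModel]]] = {}
    for i, item in enumerate(singles):
        single_groups.setdefault(find(i), []).append(item)

    records = []
    for group in list(members.values()) + list(single_groups.values()):
        group = sorted(group, key=lambda st: st[1].transcript_id)
        rep = min((t for _, t in group), key=lambda t: t.transcript_id)
        start = min(t.start for _, t in group)
        end = max(t.end for _, t in group)
        exons = list(rep.exons)
        exons[0] = replace(exons[0], start=start)
        exons[-1] = replace(exons[-1], end=end)
        if len(exons) == 1:
            exons = [replace(rep.exons[0], start=start, end=end)]
        cov = max((t.coverage or 0.0) for _, t in group)
        fpkm = max((t.fpkm or 0.0) for _, t in group)
        support = frozenset(sid for sid, _ in group)
        merged = TranscriptModel(
            transcript_id=rep.transcript_id,
            gene_id=rep.gene_id,
            exons=tuple(exons),
            cds=rep.cds,
            attributes={
                **rep.attributes,
                "cov": cov,
                "fpkm": fpkm,
                "sample_ids": ",".join(sorted(support)),
            },
        )
        records.append(SupportRecord(merged, support, cov))
    records.sort(key=lambda r: (r.transcript.contig, r.transcript.start,
                                r.transcript.transcript_id))
    return records


def filter_supported(
    records: list[SupportRecord],
    min_samples: int = 2,
    min_coverage: float = 2.0,
) -> list[SupportRecord]:
    """Keep records confirmed in >= min_samples with coverage strictly
    greater than min_coverage; input order is preserved."""
    if min_samples < 0 or min_coverage < 0:
        raise ValueError("thresholds must be >= 0")
    return [
        r
        for r in records
        if len(r.supporting_samples) >= min_samples
        and r.max_coverage > min_coverage
    ]


# ---------------------------------------------------------------------------
# categorization and cleanup
# ---------------------------------------------------------------------------


def categorize_vs_reference(
    filtered: list[SupportRecord],
    reference: AnnotationSet,
    run_on_window: int = DEFAULT_RUN_ON_WINDOW,
    single_exon_overlap_fraction: float = DEFAULT_SINGLE_EXON_OVERLAP,
    cluster_min_overlap: float = 0.1,
) -> CategorizedSets:
    """Route each record to its class-code category set.

    Intronic ('i') and intergenic ('u') transcripts are additionally
    clustered into candidate new genes; 'o' transcripts are dropped
    with a logged count.
    """
    sets = CategorizedSets()
    routes = {
        "=": sets.extended_isoforms,
        "j": sets.new_isoforms,
        "i": sets.intronic_new,
        "u": sets.intergenic_new,
        "p": sets.run_on,
    }
    for record in filtered:
        code = classify_transcript(
            record.transcript,
            reference,
            run_on_window=run_on_window,
            single_exon_overlap_fraction=single_exon_overlap_fraction,
        )
        sets.codes[record.transcript.transcript_id] = code
        if code.code == "o":
            sets.dropped_overlap += 1
            continue
        routes[code.code].append(record)
    if sets.dropped_overlap:
        log.info("dropped %d 'o' transcripts (generic exonic overlap)",
                 sets.dropped_overlap)
    sets.new_genes = cluster_genes(
        [r.transcript for r in sets.new_gene_records],
        min_overlap=cluster_min_overlap,
    )
    return sets


def remove_fusions(
    sets: CategorizedSets, reference: AnnotationSet
) -> CategorizedSets:
    """Discard extended/new isoforms spanning >= 2 same-strand reference
    genes; other category sets are untouched."""
    for name in ("extended_isoforms", "new_isoforms"):
        kept = []
        for record in getattr(sets, name):
            fused, genes = spans_multiple_genes(record.transcript, reference)
            if fused:
                sets.removed_fusions.append(record.transcript.transcript_id)
                log.info(
                    "removed fusion %s spanning genes %s",
                    record.transcript.transcript_id, sorted(genes),
                )
            else:
                kept.append(record)
        setattr(sets, name, kept)
    return sets


def _exon_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    return (
        a.contig == b.contig
        and ivl.intersect_length(a.exon_bounds, b.exon_bounds) > 0
    )


def _overlaps_reference_exons(
    t: TranscriptModel, reference: AnnotationSet
) -> bool:
    return any(
        _exon_overlap(t, ref)
        for ref in reference.overlapping(t.contig, t.start, t.end)
    )


def filter_new_genes(
    sets: CategorizedSets,
    reference: AnnotationSet,
    single_sample_transcripts: list[TranscriptModel],
    cluster_min_overlap: float = 0.1,
) -> CategorizedSets:
    """Remove new-gene candidates touching the reference directly or
    indirectly through chains of single-sample transcripts.

    A single-sample transcript is "tainted" when it overlaps reference
    exons, or overlaps another tainted single-sample transcript
    (transitive closure, unbounded depth).  A candidate is removed when
    it overlaps reference exons or any tainted transcript; removal acts
    at the cluster level (one tainted member removes the whole cluster).
    """
    tainted = [
        _overlaps_reference_exons(t, reference)
        for t in single_sample_transcripts
    ]
    changed, depth = True, 0
    while changed:
        changed = False
        depth += 1
        for i, t in enumerate(single_sample_transcripts):
            if tainted[i]:
                continue
            if any(
                tainted[j] and _exon_overlap(t, single_sample_transcripts[j])
                for j in range(len(single_sample_transcripts))
                if j != i
            ):
                tainted[i] = True
                changed = True
    log.info("single-sample taint closure converged at depth %d", depth)
    tainted_txs = [
        t for t, flag in zip(single_sample_transcripts, tainted) if flag
    ]

    def is_removed(t: TranscriptModel) -> bool:
        if _overlaps_reference_exons(t, reference):
            return True
        return any(_exon_overlap(t, x) for x in tainted_txs)

    removed_ids = {
        r.transcript.transcript_id
        for r in sets.new_gene_records
        if is_removed(r.transcript)
    }
    # cluster-level removal: any tainted member taints the cluster
    removed_clusters = [
        c for c in sets.new_genes if c.member_transcripts & removed_ids
    ]
    removed_all = set().union(
        *[c.member_transcripts for c in removed_clusters], removed_ids
    )
    sets.removed_new_gene_transcripts.extend(sorted(removed_all))
    sets.intronic_new = [
        r for r in sets.intronic_new
        if r.transcript.transcript_id not in removed_all
    ]
    sets.intergenic_new = [
        r for r in sets.intergenic_new
        if r.transcript.transcript_id not in removed_all
    ]
    sets.new_genes = cluster_genes(
        [r.transcript for r in sets.new_gene_records],
        min_overlap=cluster_min_overlap,
    )
    return sets


# ---------------------------------------------------------------------------
# sample specificity
# ---------------------------------------------------------------------------


def sample_specificity(
    records: list[SupportRecord], samples: list[SampleAnnotation]
) -> dict:
    """Fractions of retained transcripts specific to a sex or strain.

    With the 2-sex x 2-strain design the discordant-pair class (exactly
    two supporting samples differing in both sex and strain) estimates
    the chance baseline for apparent specificity.
    """
    info = {s.sample_id: (s.sex, s.strain) for s in samples}
    n = len(records)
    counts = {
        "male_specific": 0,
        "female_specific": 0,
        "strain_specific": 0,
        "discordant_pair": 0,
    }
    for r in records:
        sexes = {info[s][0] for s in r.supporting_samples if s in info}
        strains = {info[s][1] for s in r.supporting_samples if s in info}
        if sexes == {"male"}:
            counts["male_specific"] += 1
        elif sexes == {"female"}:
            counts["female_specific"] += 1
        if len(strains) == 1:
            counts["strain_specific"] += 1
        if len(r.supporting_samples) == 2 and len(sexes) == 2 and len(strains) == 2:
            counts["discordant_pair"] += 1
    out = {k: (v / n if n else 0.0) for k, v in counts.items()}
    out["n_retained"] = n
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def boundary_extensions(
    sets: CategorizedSets, reference: AnnotationSet
) -> pd.DataFrame:
    """Per reference gene, maximal 5'/3' extension (bp) over surviving
    '='/'j' transcripts, measured against the gene span envelope and
    oriented by the gene strand."""
    rows: dict[str, dict] = {}
    for record in sets.extended_isoforms + sets.new_isoforms:
        code = sets.codes[record.transcript.transcript_id]
        ref_tx = reference.get(code.matched_reference_transcript)
        gene_id = ref_tx.gene_id
        gene_span = reference.gene_span(gene_id)
        t = record.transcript
        left = max(0, gene_span.start - t.start)
        right = max(0, t.end - gene_span.end)
        if gene_span.strand == "-":
            ext5, ext3 = right, left
        else:
            ext5, ext3 = left, right
        row = rows.setdefault(
            gene_id, {"gene_id": gene_id, "ext5": 0, "ext3": 0}
        )
        row["ext5"] = max(row["ext5"], ext5)
        row["ext3"] = max(row["ext3"], ext3)
    df = pd.DataFrame(
        sorted(rows.values(), key=lambda r: r["gene_id"]),
        columns=["gene_id", "ext5", "ext3"],
    )
    return df


def refine_annotation(
    samples: list[SampleAnnotation],
    reference: AnnotationSet,
    config: RefineConfig | None = None,
    genome=None,
) -> RefinedAnnotation:
    """Run the full consolidation pipeline.

    merge -> support/coverage filter -> class-code categorization ->
    fusion removal -> new-gene overlap filtering; then per-gene boundary
    extensions are measured and, when a genome is supplied, complete
    ORFs are attached to novel transcripts.
    """
    config = config or RefineConfig()
    merged = merge_samples(samples)
    log.info("merged %d per-sample transcripts into %d isoforms",
             sum(len(s.annotation) for s in samples), len(merged))
    filtered = filter_supported(
        merged, min_samples=config.min_samples, min_coverage=config.min_coverage
    )
    log.info("support/coverage filter kept %d of %d isoforms",
             len(filtered), len(merged))
    sets = categorize_vs_reference(
        filtered,
        reference,
        run_on_window=config.run_on_window,
        single_exon_overlap_fraction=config.single_exon_overlap_fraction,
        cluster_min_overlap=config.cluster_min_overlap,
    )
    sets = remove_fusions(sets, reference)
    single_sample = [
        r.transcript for r in merged if len(r.supporting_samples) == 1
    ]
    sets = filter_new_genes(
        sets, reference, single_sample,
        cluster_min_overlap=config.cluster_min_overlap,
    )
    extensions = boundary_extensions(sets, reference)
    specificity = sample_specificity(filtered, samples)

    # assemble the final annotation: reference + surviving novelties
    final = AnnotationSet()
    for t in reference:
        final.add(t)
    new_gene_ids = {}
    for idx, cluster in enumerate(sets.new_genes, start=1):
        for tid in cluster.member_transcripts:
            new_gene_ids[tid] = f"NEWG{idx:05d}"
    provenance_rows = []

    def add_novel(record: SupportRecord, category: str) -> None:
        t = record.transcript
        code = sets.codes[t.transcript_id]
        if code.matched_reference_transcript is not None and code.code in ("=", "j"):
            gene_id = reference.get(code.matched_reference_transcript).gene_id
        else:
            gene_id = new_gene_ids.get(t.transcript_id, t.gene_id)
        t = replace(t, gene_id=gene_id)
        if genome is not None and category in ("new_isoform", "new_gene") and not t.cds:
            from .splicing import annotate_orf

            with_orf = annotate_orf(t, genome)
            if with_orf is not None:
                t = with_orf
        elif category == "extended" and not t.cds:
            ref_tx = reference.get(code.matched_reference_transcript)
            exon_bounds = [e.bounds for e in t.exons]
            if ref_tx.cds and all(
                any(ivl.contains(e, c.bounds) for e in exon_bounds)
                for c in ref_tx.cds
            ):
                t = replace(t, cds=ref_tx.cds)
        final.add(t)
        provenance_rows.append(
            {
                "transcript_id": t.transcript_id,
                "category": category,
                "class_code": code.code,
                "matched_reference_transcript": code.matched_reference_transcript,
                "gene_id": gene_id,
                "supporting_samples": ",".join(sorted(record.supporting_samples)),
                "max_coverage": record.max_coverage,
            }
        )

    for record in sets.extended_isoforms:
        add_novel(record, "extended")
    for record in sets.new_isoforms:
        add_novel(record, "new_isoform")
    for record in sets.new_gene_records:
        add_novel(record, "new_gene")
    for record in sets.run_on:
        code = sets.codes[record.transcript.transcript_id]
        provenance_rows.append(
            {
                "transcript_id": record.transcript.transcript_id,
                "category": "run_on",
                "class_code": code.code,
                "matched_reference_transcript": code.matched_reference_transcript,
                "gene_id": record.transcript.gene_id,
                "supporting_samples": ",".join(sorted(record.supporting_samples)),
                "max_coverage": record.max_coverage,
            }
        )

    provenance = pd.DataFrame(
        provenance_rows,
        columns=[
            "transcript_id", "category", "class_code",
            "matched_reference_transcript", "gene_id",
            "supporting_samples", "max_coverage",
        ],
    )
    stage_counts = {
        "input_transcripts": sum(len(s.annotation) for s in samples),
        "merged": len(merged),
        "filtered": len(filtered),
        "extended_isoforms": len(sets.extended_isoforms),
        "new_isoforms": len(sets.new_isoforms),
        "new_gene_transcripts": len(sets.new_gene_records),
        "new_genes": len(sets.new_genes),
        "run_on": len(sets.run_on),
        "dropped_overlap": sets.dropped_overlap,
        "removed_fusions": len(sets.removed_fusions),
        "removed_new_gene_transcripts": len(sets.removed_new_gene_transcripts),
        "discarded_fraction_merged": (
            1 - len(filtered) / len(merged) if merged else 0.0
        ),
    }
    return RefinedAnnotation(
        annotation=final,
        provenance=provenance,
        boundary_extensions=extensions,
        categorized=sets,
        specificity=specificity,
        stage_counts=stage_counts,
    )
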