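"""Transcript comparison core: junction chains, class codes, clustering.

A query transcript is placed in exactly one category relative to a
reference annotation, mirroring the cuffcompare-style codes used in
reference-guided annotation refinement:

``=``
    exact intron-chain match (or, for two single-exon transcripts,
    reciprocal exonic overlap above a configurable fraction);
``j``
    shares at least one splice junction with an overlapping reference
    transcript but matches no full chain (a novel isoform);
``o``
    generic exonic overlap with no shared junction;
``i``
    fully contained in an intron of a reference transcript;
``p``
    a run-on fragment: no reference-exon overlap, starting within a
    configurable window downstream of a reference 3' end on the same
    strand (polymerase read-through past the terminator);
``u``
    intergenic (none of the above).

Strand handling: '.' is a wildcard for '=', 'j' and 'o'; the run-on call
'p' requires an explicit strand; 'i' ignores strand (containment in an
intron is a positional statement).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import intervals as ivl
from .annotation_io import (
    AnnotationSet,
    GenomicInterval,
    TranscriptModel,
    derive_introns,
    strands_compatible,
)

CLASS_CODES = ("=", "j", "o", "i", "p", "u")
DEFAULT_RUN_ON_WINDOW = 2000
DEFAULT_SINGLE_EXON_OVERLAP = 0.5


@dataclass(frozen=True)
class JunctionChain:
    """Ordered intron-boundary pairs; the identity key of an isoform."""

    contig: str
    strand: str
    junctions: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.junctions)


@dataclass(frozen=True)
class ClassCode:
    code: str
    matched_reference_transcript: str | None = None

    def __post_init__(self) -> None:
        if self.code not in CLASS_CODES:
            raise ValueError(f"unknown class code {self.code!r}")
        if self.code in ("=", "j") and self.matched_reference_transcript is None:
            raise ValueError(f"code {self.code!r} requires a matched transcript")
        if self.code == "u" and self.matched_reference_transcript is not None:
            raise ValueError("code 'u' cannot carry a matched transcript")


@dataclass(frozen=True)
class GeneCluster:
    """Single-linkage cluster of transcripts treated as one gene locus."""

    member_transcripts: frozenset[str]
    span: GenomicInterval


def junction_chain(transcript: TranscriptModel) -> JunctionChain:
    """One (donor-side, acceptor-side) coordinate pair per intron."""
    return JunctionChain(
        contig=transcript.contig,
        strand=transcript.strand,
        junctions=tuple(i.bounds for i in derive_introns(transcript)),
    )


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    if a.contig != b.contig:
        return 0
    return ivl.intersect_length(a.exon_bounds, b.exon_bounds)


def single_exon_match(
    a: TranscriptModel, b: TranscriptModel, fraction: float
) -> bool:
    """Reciprocal-overlap '=' criterion for two single-exon transcripts."""
    ov = _exonic_overlap(a, b)
    return (
        ov >= fraction * a.exonic_length
        and ov >= fraction * b.exonic_length
        and ov > 0
    )


def classify_transcript(
    query: TranscriptModel,
    reference: AnnotationSet,
    run_on_window: int = DEFAULT_RUN_ON_WINDOW,
    single_exon_overlap_fraction: float = DEFAULT_SINGLE_EXON_OVERLAP,
) -> ClassCode:
    """Assign the query exactly one class code against the reference.

    The six rules are tested in fixed priority order ('=' , 'j', 'o',
    'i', 'p', 'u'); where several reference transcripts qualify the one
    with the most shared junctions, then the largest exonic overlap,
    then the smallest transcript_id wins.
    """
    qchain = junction_chain(query)
    qjunctions = set(qchain.junctions)
    # pad by one extra base: tree overlap is half-open, and a reference
    # ending exactly run_on_window upstream must still be fetched
    pad = max(run_on_window, 0) + 1
    nearby = reference.overlapping(
        query.contig, query.start - pad, query.end + pad
    )

    def rank(ref: TranscriptModel) -> tuple[int, int, str]:
        shared = len(qjunctions & set(junction_chain(ref).junctions))
        return (-shared, -_exonic_overlap(query, ref), ref.transcript_id)

    # rule 1: "="
    equal: list[TranscriptModel] = []
    for ref in nearby:
        if not strands_compatible(query.strand, ref.strand):
            continue
        if query.is_multi_exon and ref.is_multi_exon:
            if junction_chain(ref).junctions == qchain.junctions:
                equal.append(ref)
        elif not query.is_multi_exon and not ref.is_multi_exon:
            if single_exon_match(query, ref, single_exon_overlap_fraction):
                equal.append(ref)
    if equal:
        best = min(equal, key=rank)
        return ClassCode("=", best.transcript_id)

    # rule 2: "j" — shared junction with a span-overlapping reference
    sharers = [
        ref
        for ref in nearby
        if strands_compatible(query.strand, ref.strand)
        and ivl.overlaps(query.span.bounds, ref.span.bounds)
        and qjunctions & set(junction_chain(ref).junctions)
    ]
    if sharers:
        best = min(sharers, key=rank)
        return ClassCode("j", best.transcript_id)

    # rule 3: "o" — exonic overlap without a shared junction
    overlappers = [
        ref
        for ref in nearby
        if strands_compatible(query.strand, ref.strand)
        and _exonic_overlap(query, ref) > 0
    ]
    if overlappers:
        best = min(overlappers, key=rank)
        return ClassCode("o", best.transcript_id)

    # rule 4: "i" — wholly inside one reference intron (strand ignored)
    for ref in sorted(nearby, key=lambda r: r.transcript_id):
        for intron in derive_introns(ref):
            if intron.contig == query.contig and ivl.contains(
                intron.bounds, query.span.bounds
            ):
                return ClassCode("i", ref.transcript_id)

    # rule 5: "p" — run-on fragment downstream of a 3' end, same strand
    if query.strand in ("+", "-") and not any(
        _exonic_overlap(query, ref) > 0 for ref in nearby
    ):
        candidates = []
        for ref in nearby:
            if ref.strand != query.strand:
                continue
            if query.strand == "+":
                dist = query.start - ref.end
            else:
                dist = ref.start - query.end
            if 0 <= dist <= run_on_window:
                candidates.append((dist, ref.transcript_id))
        if candidates:
            _, tid = min(candidates)
            return ClassCode("p", tid)

    return ClassCode("u")


def spans_multiple_genes(
    query: TranscriptModel, reference: AnnotationSet
) -> tuple[bool, set[str]]:
    """Fusion check: exon overlap with >= 2 reference genes, same orientation.

    Only reference transcripts whose strand equals the query strand
    count (a transcript bridging a + and a - gene is not a fusion in
    that gene's orientation).
    """
    genes: set[str] = set()
    for ref in reference.overlapping(query.contig, query.start, query.end):
        if ref.strand != query.strand:
            continue
        if _exonic_overlap(query, ref) > 0:
            genes.add(ref.gene_id)
    return len(genes) >= 2, genes


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_genes(
    transcripts: list[TranscriptModel], min_overlap: float = 0.1
) -> list[GeneCluster]:
    """Single-linkage clustering of transcripts into gene loci.

    Two transcripts are linked iff they sit on the same contig, have
    compatible strands, and share exonic bases amounting to at least
    ``min_overlap`` times the exonic length of the shorter one.
    """
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must be in (0, 1]")
    txs = sorted(transcripts, key=lambda t: t.transcript_id)
    uf = _UnionFind(len(txs))
    by_contig: dict[str, list[int]] = {}
    for idx, t in enumerate(txs):
        by_contig.setdefault(t.contig, []).append(idx)
    for idxs in by_contig.values():
        for pos, i in enumerate(idxs):
            for j in idxs[pos + 1 :]:
                a, b = txs[i], txs[j]
                if not strands_compatible(a.strand, b.strand):
                    continue
                shorter = min(a.exonic_length, b.exonic_length)
                if _exonic_overlap(a, b) >= min_overlap * shorter > 0:
                    uf.union(i, j)
    groups: dict[int, list[TranscriptModel]] = {}
    for idx, t in enumerate(txs):
        groups.setdefault(uf.find(idx), []).append(t)
    clusters = []
    for members in groups.values():
        strands = {t.strand for t in members} - {"."}
        span = GenomicInterval(
            members[0].contig,
            min(t.start for t in members),
            max(t.end for t in members),
            strands.pop() if len(strands) == 1 else ".",
        )
        clusters.append(
            GeneCluster(
                member_transcripts=frozenset(t.transcript_id for t in members),
                span=span,
            )
        )
    clusters.sort(key=lambda c: (c.span.contig, c.span.start, min(c.member_transcripts)))
    return clusters
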