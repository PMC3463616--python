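"""Alternative-splicing event extraction, ORF finding and frame impact.

Events are extracted pairwise from two overlapping isoforms: within the
shared genomic span, the introns present in only one of the two
transcripts are grouped into local clusters (overlapping or touching
differing introns belong to the same event) and each cluster is
classified into one of the canonical modes:

* ``intron_retention`` — an intron of one isoform lies strictly inside
  an exon of the other;
* ``exon_skipping`` — an internal exon, with both flanking introns, is
  absent from the other isoform while the fused outer junctions agree;
* ``alt_donor`` / ``alt_acceptor`` — two introns share one boundary and
  differ at the other (donor = 5' intron end in transcript orientation);
* ``complex`` — any other local difference, including terminal
  variation where no common flanking splice site exists.

The event ``region`` is the alternatively spliced sequence itself (the
retained intron, the skipped exon, or the stretch between the two
alternative sites), which is what the reading-frame impact of the event
is measured on.
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
from .genome import Genome, reverse_complement

AS_MODES = (
    "alt_donor",
    "alt_acceptor",
    "exon_skipping",
    "intron_retention",
    "complex",
)
START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class ASEvent:
    """A localized splicing difference between two isoforms."""

    mode: str
    region: tuple[GenomicInterval, ...]
    isoform_pair: tuple[str, str]

    @property
    def length(self) -> int:
        return sum(r.length for r in self.region)

    @property
    def region_bounds(self) -> list[ivl.Interval]:
        return [r.bounds for r in self.region]


@dataclass(frozen=True)
class ORF:
    """A complete open reading frame in transcript coordinates."""

    tx_start: int
    tx_end: int
    frame: int
    complete: bool = True
    genomic_cds: tuple[GenomicInterval, ...] = ()

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start


@dataclass(frozen=True)
class ImpactCall:
    """Reading-frame verdict of an AS event on the coding sequence."""

    verdict: str  # frame_preserving | frameshift | premature_stop
    event: ASEvent
    utr_only: bool = False


# ---------------------------------------------------------------------------
# event extraction
# ---------------------------------------------------------------------------


def _cluster_diff_introns(
    diff: list[tuple[ivl.Interval, str]]
) -> list[list[tuple[ivl.Interval, str]]]:
    """Group differing introns that overlap or touch into event clusters."""
    diff = sorted(diff)
    clusters: list[list[tuple[ivl.Interval, str]]] = []
    cur: list[tuple[ivl.Interval, str]] = []
    cur_end = None
    for iv, owner in diff:
        if cur and iv[0] <= cur_end:
            cur.append((iv, owner))
            cur_end = max(cur_end, iv[1])
        else:
            if cur:
                clusters.append(cur)
            cur = [(iv, owner)]
            cur_end = iv[1]
    if cur:
        clusters.append(cur)
    return clusters


def _classify_cluster(
    cluster: list[tuple[ivl.Interval, str]],
    a: TranscriptModel,
    b: TranscriptModel,
    strand: str,
    boundary_crossed: bool,
) -> tuple[str, tuple[ivl.Interval, ...]]:
    ia = sorted(iv for iv, owner in cluster if owner == "a")
    ib = sorted(iv for iv, owner in cluster if owner == "b")
    span = (min(iv[0] for iv, _ in cluster), max(iv[1] for iv, _ in cluster))
    if boundary_crossed:
        return "complex", (span,)

    def retained_in(intron: ivl.Interval, other: TranscriptModel) -> bool:
        return any(
            ivl.strictly_contains(e, intron) for e in other.exon_bounds
        )

    if len(ia) == 1 and not ib and retained_in(ia[0], b):
        return "intron_retention", (ia[0],)
    if len(ib) == 1 and not ia and retained_in(ib[0], a):
        return "intron_retention", (ib[0],)

    if len(ia) == 1 and len(ib) == 1:
        (sa, ea), (sb, eb) = ia[0], ib[0]
        if ea == eb and sa != sb:
            region = ((min(sa, sb), max(sa, sb)),)
            # + strand: shared acceptor, differing donor
            return ("alt_donor" if strand != "-" else "alt_acceptor"), region
        if sa == sb and ea != eb:
            region = ((min(ea, eb), max(ea, eb)),)
            return ("alt_acceptor" if strand != "-" else "alt_donor"), region
        return "complex", (span,)

    for two, one, two_tx in ((ia, ib, a), (ib, ia, b)):
        if len(two) == 2 and len(one) == 1:
            (s1, e1), (s2, e2) = two
            (fs, fe) = one[0]
            exon = (e1, s2)
            if (
                fs == s1
                and fe == e2
                and e1 < s2
                and exon in two_tx.exon_bounds
            ):
                return "exon_skipping", (exon,)
    return "complex", (span,)


def find_as_events(a: TranscriptModel, b: TranscriptModel) -> list[ASEvent]:
    """Extract localized splicing differences between two isoforms.

    Returns an empty list when the transcripts do not overlap
    exonically.  Results are symmetric in the two arguments up to the
    order of ``isoform_pair``.
    """
    if a.contig != b.contig or not strands_compatible(a.strand, b.strand):
        return []
    if ivl.intersect_length(a.exon_bounds, b.exon_bounds) == 0:
        return []
    shared = (max(a.start, b.start), min(a.end, b.end))
    strand = a.strand if a.strand != "." else b.strand

    introns_a = [i.bounds for i in derive_introns(a)]
    introns_b = [i.bounds for i in derive_introns(b)]
    set_a, set_b = set(introns_a), set(introns_b)

    diff: list[tuple[ivl.Interval, str]] = []
    crossing: set[ivl.Interval] = set()
    for iv in sorted(set_a ^ set_b):
        owner = "a" if iv in set_a else "b"
        if ivl.overlaps(shared, iv):
            diff.append((iv, owner))
            if not ivl.contains(shared, iv):
                crossing.add(iv)

    events = []
    for cluster in _cluster_diff_introns(diff):
        crossed = any(iv in crossing for iv, _ in cluster)
        mode, region = _classify_cluster(cluster, a, b, strand, crossed)
        if crossed:
            # terminal variation: the shared-span boundary delimits the event
            region = tuple(
                iv for iv in (ivl.intersect(list(region), [shared])) if iv
            )
            if not region:
                continue
        events.append(
            ASEvent(
                mode=mode,
                region=tuple(
                    GenomicInterval(a.contig, s, e, strand) for s, e in region
                ),
                isoform_pair=(a.transcript_id, b.transcript_id),
            )
        )
    return events


def count_alternatively_spliced(annotation: AnnotationSet):
    """Per-gene isoform counts and deduplicated AS events.

    Events from all isoform pairs of a gene are merged when they share
    mode and region; a gene is alternatively spliced iff at least one
    event remains.  Returns a pandas DataFrame with one row per gene.
    """
    import pandas as pd

    rows = []
    for gene_id, tids in sorted(annotation.gene_index.items()):
        txs = [annotation.get(t) for t in sorted(tids)]
        seen: dict[tuple, ASEvent] = {}
        raw = 0
        for i in range(len(txs)):
            for j in range(i + 1, len(txs)):
                for ev in find_as_events(txs[i], txs[j]):
                    raw += 1
                    key = (ev.mode, tuple(r.bounds for r in ev.region))
                    seen.setdefault(key, ev)
        rows.append(
            {
                "gene_id": gene_id,
                "n_isoforms": len(txs),
                "n_events": len(seen),
                "n_events_raw": raw,
                "alternatively_spliced": bool(seen),
                "events": tuple(seen.values()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ORFs
# ---------------------------------------------------------------------------


def find_orf(tx_sequence: str) -> ORF | None:
    """Longest complete (start..stop) reading frame of the sequence.

    All three forward frames of the already-oriented transcript sequence
    are scanned; ties go to the 5'-most ORF; codons containing N never
    act as start or stop.  Returns None when no complete ORF exists.
    """
    seq = tx_sequence.upper()
    best: ORF | None = None
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == START_CODON:
                    start = pos
            elif codon in STOP_CODONS:
                cand = ORF(tx_start=start, tx_end=pos + 3, frame=frame)
                if (
                    best is None
                    or cand.length > best.length
                    or (cand.length == best.length and cand.tx_start < best.tx_start)
                ):
                    best = cand
                start = None
    return best


def map_orf_to_genome(
    transcript: TranscriptModel, orf: ORF
) -> list[GenomicInterval]:
    """Project transcript-coordinate ORF bounds through the exon chain.

    On the '-' strand transcript coordinate 0 is the genomically
    rightmost exonic base; the returned genomic intervals are sorted by
    start and total exactly ``orf.length`` bases.
    """
    if orf.tx_end > transcript.exonic_length or orf.tx_start < 0:
        raise ValueError(
            f"ORF bounds [{orf.tx_start}, {orf.tx_end}) exceed exonic length "
            f"{transcript.exonic_length}"
        )
    exons = list(transcript.exon_bounds)
    if transcript.strand == "-":
        exons = exons[::-1]
    out: list[ivl.Interval] = []
    offset = 0
    for s, e in exons:
        elen = e - s
        lo = max(orf.tx_start - offset, 0)
        hi = min(orf.tx_end - offset, elen)
        if lo < hi:
            if transcript.strand == "-":
                out.append((e - hi, e - lo))
            else:
                out.append((s + lo, s + hi))
        offset += elen
    return [
        GenomicInterval(transcript.contig, s, e, transcript.strand)
        for s, e in sorted(out)
    ]


def annotate_orf(
    transcript: TranscriptModel, genome: Genome
) -> TranscriptModel | None:
    """Attach the longest complete ORF of the transcript as its CDS.

    Returns a copy with ``cds`` set, or None when no complete ORF is
    found (mirroring a pipeline that retains complete ORFs only).
    """
    from .genome import transcript_sequence

    orf = find_orf(transcript_sequence(genome, transcript))
    if orf is None or transcript.strand == ".":
        return None
    cds = map_orf_to_genome(transcript, orf)
    return TranscriptModel(
        transcript_id=transcript.transcript_id,
        gene_id=transcript.gene_id,
        exons=transcript.exons,
        cds=tuple(cds),
        attributes=dict(transcript.attributes),
    )


# ---------------------------------------------------------------------------
# frame impact
# ---------------------------------------------------------------------------


def _cds_codon_positions(
    transcript: TranscriptModel, genome: Genome
) -> tuple[str, list[list[int]]]:
    """Spliced CDS sequence plus per-codon genomic base positions."""
    from .genome import cds_sequence

    positions: list[int] = []
    for s, e in transcript.cds_bounds:
        positions.extend(range(s, e))
    if transcript.strand == "-":
        positions = positions[::-1]
    seq = cds_sequence(genome, transcript)
    codons = [positions[i : i + 3] for i in range(0, len(positions) - 2, 3)]
    return seq, codons


def assess_impact(
    event: ASEvent,
    inclusion_tx: TranscriptModel,
    exclusion_tx: TranscriptModel,
    genome: Genome,
) -> ImpactCall:
    """Classify an AS event's effect on the reading frame.

    The net change in CDS-overlapping exonic length over the event
    region decides frameshift (not divisible by 3); otherwise the
    inclusion isoform's CDS is translated and a stop codon overlapping
    the event region before the annotated stop yields premature_stop;
    else the event is frame preserving.  Events entirely outside both
    CDSs are frame preserving with ``utr_only`` set.
    """
    region = event.region_bounds
    incl_len = ivl.intersect_length(
        ivl.intersect(inclusion_tx.cds_bounds, inclusion_tx.exon_bounds), region
    )
    excl_len = ivl.intersect_length(
        ivl.intersect(exclusion_tx.cds_bounds, exclusion_tx.exon_bounds), region
    )
    if incl_len == 0 and excl_len == 0:
        return ImpactCall("frame_preserving", event, utr_only=True)
    if (incl_len - excl_len) % 3 != 0:
        return ImpactCall("frameshift", event)

    seq, codons = _cds_codon_positions(inclusion_tx, genome)
    for idx, codon_positions in enumerate(codons):
        codon = seq[idx * 3 : idx * 3 + 3]
        if idx == len(codons) - 1:
            break  # annotated stop
        if codon in STOP_CODONS and any(
            any(s <= p < e for s, e in region) for p in codon_positions
        ):
            return ImpactCall("premature_stop", event)
    return ImpactCall("frame_preserving", event)


# ---------------------------------------------------------------------------
# splice sites
# ---------------------------------------------------------------------------


def splice_site_dinucleotides(
    annotation: AnnotationSet, genome: Genome
):
    """Donor/acceptor dinucleotide counts over all derived introns.

    The first two intronic bases form the donor dinucleotide and the
    last two the acceptor, read on the transcript strand (reverse
    complement on '-').  Introns shorter than 4 bases are skipped.
    Returns a pandas DataFrame indexed by dinucleotide with 'donor' and
    'acceptor' count columns.
    """
    import logging

    import pandas as pd

    log = logging.getLogger(__name__)
    donors: dict[str, int] = {}
    acceptors: dict[str, int] = {}
    for t in annotation:
        for intron in derive_introns(t):
            if intron.length < 4:
                log.warning(
                    "intron %s:[%d,%d) shorter than 4 bases, skipped",
                    intron.contig, intron.start, intron.end,
                )
                continue
            left = genome.fetch(intron.contig, intron.start, intron.start + 2)
            right = genome.fetch(intron.contig, intron.end - 2, intron.end)
            if t.strand == "-":
                donor = reverse_complement(right)
                acceptor = reverse_complement(left)
            else:
                donor, acceptor = left, right
            donors[donor] = donors.get(donor, 0) + 1
            acceptors[acceptor] = acceptors.get(acceptor, 0) + 1
    idx = sorted(set(donors) | set(acceptors))
    return pd.DataFrame(
        {
            "donor": [donors.get(k, 0) for k in idx],
            "acceptor": [acceptors.get(k, 0) for k in idx],
        },
        index=idx,
    )
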