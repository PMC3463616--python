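"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (per-base sets, exhaustive scans,
direct translation) and shares no code path with the package internals
it checks.
"""

from __future__ import annotations

import numpy as np

from txrefine.annotation_io import AnnotationSet, GenomicInterval, TranscriptModel

STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# random small transcripts
# ---------------------------------------------------------------------------


def random_transcript(
    rng: np.random.Generator,
    tid: str,
    contig: str = "c",
    max_exons: int = 3,
    grid_max: int = 300,
    step: int = 10,
    strands: tuple[str, ...] = ("+", "-", "."),
) -> TranscriptModel:
    k = int(rng.integers(1, max_exons, endpoint=True))
    points = sorted(
        rng.choice(np.arange(0, grid_max, step), size=2 * k, replace=False)
    )
    exons = [
        GenomicInterval(contig, int(points[2 * i]), int(points[2 * i + 1]),
                        str(rng.choice(strands)))
        for i in range(k)
    ]
    strand = exons[0].strand
    exons = [GenomicInterval(contig, e.start, e.end, strand) for e in exons]
    return TranscriptModel(
        transcript_id=tid, gene_id=f"gene_{tid}", exons=tuple(exons)
    )


def transcript_from_bounds(
    tid: str, bounds, strand: str = "+", contig: str = "c", gene: str | None = None,
    cds=(),
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene or f"gene_{tid}",
        exons=tuple(GenomicInterval(contig, s, e, strand) for s, e in bounds),
        cds=tuple(GenomicInterval(contig, s, e, strand) for s, e in cds),
    )


# ---------------------------------------------------------------------------
# class-code oracle
# ---------------------------------------------------------------------------


def _bases(t: TranscriptModel) -> set[int]:
    return {p for e in t.exons for p in range(e.start, e.end)}


def _introns(t: TranscriptModel) -> list[tuple[int, int]]:
    out = []
    for a, b in zip(t.exons, t.exons[1:]):
        out.append((a.end, b.start))
    return out


def _compat(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


def oracle_class_code(
    query: TranscriptModel,
    reference: AnnotationSet,
    run_on_window: int,
    single_exon_overlap_fraction: float,
) -> str:
    """Rule-by-rule per-base re-derivation of the class code."""
    refs = [r for r in reference if r.contig == query.contig]
    qb = _bases(query)
    qi = _introns(query)

    # rule 1: "="
    for r in refs:
        if not _compat(query.strand, r.strand):
            continue
        if len(query.exons) > 1 and len(r.exons) > 1:
            if _introns(r) == qi:
                return "="
        elif len(query.exons) == 1 and len(r.exons) == 1:
            ov = len(qb & _bases(r))
            if ov > 0 and ov >= single_exon_overlap_fraction * len(qb) \
                    and ov >= single_exon_overlap_fraction * len(_bases(r)):
                return "="
    # rule 2: "j"
    for r in refs:
        if not _compat(query.strand, r.strand):
            continue
        span_overlap = (
            query.start < r.end and r.start < query.end
        )
        if span_overlap and set(qi) & set(_introns(r)):
            return "j"
    # rule 3: "o"
    for r in refs:
        if _compat(query.strand, r.strand) and qb & _bases(r):
            return "o"
    # rule 4: "i"
    for r in refs:
        for s, e in _introns(r):
            if s <= query.start and query.end <= e:
                return "i"
    # rule 5: "p"
    if query.strand in ("+", "-"):
        any_exon_overlap = any(qb & _bases(r) for r in refs)
        if not any_exon_overlap:
            for r in refs:
                if r.strand != query.strand:
                    continue
                dist = (
                    query.start - r.end
                    if query.strand == "+"
                    else r.start - query.end
                )
                if 0 <= dist <= run_on_window:
                    return "p"
    return "u"


# ---------------------------------------------------------------------------
# AS-event oracle (per-base occupancy runs)
# ---------------------------------------------------------------------------


def oracle_as_events(
    a: TranscriptModel, b: TranscriptModel
) -> list[tuple[str, tuple[tuple[int, int], ...] | None]]:
    """Per-base re-derivation of event modes.

    Returns (mode, region) pairs; the region is None for complex events
    (their extent is a delimitation convention, not a mode property).
    """
    if a.contig != b.contig or not _compat(a.strand, b.strand):
        return []
    ab, bb = _bases(a), _bases(b)
    if not ab & bb:
        return []
    lo, hi = max(a.start, b.start), min(a.end, b.end)
    strand = a.strand if a.strand != "." else b.strand

    runs: list[tuple[int, int]] = []
    cur = None
    for p in range(lo, hi):
        if (p in ab) != (p in bb):
            if cur is None:
                cur = p
        else:
            if cur is not None:
                runs.append((cur, p))
                cur = None
    if cur is not None:
        runs.append((cur, hi))

    # differing introns (present in exactly one transcript) connect runs;
    # introns reaching past the shared span mark terminal variation
    ia, ib = set(_introns(a)), set(_introns(b))
    diff_introns = [
        iv for iv in sorted(ia ^ ib) if iv[0] < hi and lo < iv[1]
    ]
    crossing = {iv for iv in diff_introns if iv[0] < lo or iv[1] > hi}

    def touches(x, y) -> bool:
        return x[0] <= y[1] and y[0] <= x[1]

    parent = list(range(len(runs)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    terminal_groups: set[int] = set()
    for iv in diff_introns:
        hit = [i for i, r in enumerate(runs) if touches(iv, r)]
        for i in hit[1:]:
            parent[find(i)] = find(hit[0])
        if iv in crossing and hit:
            terminal_groups.add(hit[0])
    groups: dict[int, list[tuple[int, int]]] = {}
    terminal_roots = {find(i) for i in terminal_groups}
    for i, r in enumerate(runs):
        groups.setdefault(find(i), []).append(r)

    def classify(run: tuple[int, int]):
        p, q = run
        in_a = all(pp in ab for pp in range(p, q))
        in_b = all(pp in bb for pp in range(p, q))
        if in_a == in_b:
            return ("complex", None)
        x, y = (a, b) if in_a else (b, a)  # x exonic over run, y intronic
        iy = next(
            (iv for iv in _introns(y) if iv[0] <= p and q <= iv[1]), None
        )
        if iy is None:
            return ("complex", None)
        if iy == run and any(
            e.start < p and q < e.end for e in x.exons
        ):
            return ("intron_retention", (run,))
        x_introns = _introns(x)
        if any((e.start, e.end) == run for e in x.exons):
            left = next((iv for iv in x_introns if iv[1] == p), None)
            right = next((iv for iv in x_introns if iv[0] == q), None)
            if left and right and iy == (left[0], right[1]):
                return ("exon_skipping", (run,))
        for ix in x_introns:
            if ix[0] == q and ix[1] == iy[1]:
                # boundary shared on the right
                mode = "alt_donor" if strand != "-" else "alt_acceptor"
                return (mode, (run,))
            if ix[1] == p and ix[0] == iy[0]:
                mode = "alt_acceptor" if strand != "-" else "alt_donor"
                return (mode, (run,))
        return ("complex", None)

    events = []
    for root, group in groups.items():
        if root in terminal_roots:
            events.append(("complex", None))
        elif len(group) == 1:
            events.append(classify(group[0]))
        else:
            events.append(("complex", None))
    return sorted(events, key=lambda e: (e[0], e[1] or ()))


# ---------------------------------------------------------------------------
# frame-impact oracle (direct translation)
# ---------------------------------------------------------------------------


def oracle_impact(
    region: list[tuple[int, int]],
    inclusion_exons: list[tuple[int, int]],
    inclusion_cds: list[tuple[int, int]],
    exclusion_exons: list[tuple[int, int]],
    exclusion_cds: list[tuple[int, int]],
    sequence: str,
    strand: str,
) -> str:
    """Naive per-base frame-impact verdict on a single-contig layout."""
    region_bases = {p for s, e in region for p in range(s, e)}

    def cds_bases(cds, exons):
        exonic = {p for s, e in exons for p in range(s, e)}
        return [p for s, e in cds for p in range(s, e) if p in exonic]

    incl = cds_bases(inclusion_cds, inclusion_exons)
    excl = cds_bases(exclusion_cds, exclusion_exons)
    d_incl = sum(1 for p in incl if p in region_bases)
    d_excl = sum(1 for p in excl if p in region_bases)
    if d_incl == 0 and d_excl == 0:
        return "frame_preserving"  # UTR-only
    if (d_incl - d_excl) % 3 != 0:
        return "frameshift"
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    ordered = sorted(incl) if strand != "-" else sorted(incl, reverse=True)
    seq = "".join(
        sequence[p] if strand != "-" else comp[sequence[p]] for p in ordered
    )
    n_codons = len(ordered) // 3
    for c in range(n_codons - 1):  # skip the annotated stop
        codon = seq[c * 3 : c * 3 + 3]
        if codon in STOPS and any(
            p in region_bases for p in ordered[c * 3 : c * 3 + 3]
        ):
            return "premature_stop"
    return "frame_preserving"


def random_retention_case(rng: np.random.Generator):
    """A random two-exon gene with CDS plus its intron-retaining isoform.

    Returns (event, inclusion_tx, exclusion_tx, genome, intron_bounds)
    for frame-impact comparisons against `oracle_impact`.
    """
    from txrefine.genome import Genome
    from txrefine.splicing import ASEvent

    bases = np.array(["A", "C", "G", "T"])
    l1 = 3 * int(rng.integers(8, 30))
    l2 = 3 * int(rng.integers(8, 30))
    ilen = int(rng.integers(10, 120))
    n = 10 + l1 + ilen + l2 + 10
    seq = "".join(bases[rng.integers(0, 4, size=n)])
    e1 = (10, 10 + l1)
    e2 = (10 + l1 + ilen, 10 + l1 + ilen + l2)
    intron = (e1[1], e2[0])
    exclusion = transcript_from_bounds("ex", [e1, e2], cds=[e1, e2])
    inclusion = transcript_from_bounds(
        "in", [(e1[0], e2[1])], cds=[(e1[0], e2[1])]
    )
    event = ASEvent(
        mode="intron_retention",
        region=(GenomicInterval("c", *intron, "+"),),
        isoform_pair=("in", "ex"),
    )
    return event, inclusion, exclusion, Genome({"c": seq}), intron


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------


def naive_mean(scores: np.ndarray, start: int, end: int) -> float:
    """Pure-python per-base mean ignoring NaN positions."""
    total, n = 0.0, 0
    for p in range(start, end):
        v = float(scores[p])
        if v == v:  # not NaN
            total += v
            n += 1
    return total / n if n else float("nan")
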