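"""Gene-annotation containers and GTF input/output.

The package works internally in 0-based half-open coordinates; the GTF
reader and writer convert to and from the 1-based inclusive coordinates
of the GTF dialect (tab-separated, attributes as ``key "value";`` pairs).
Introns and UTRs are not stored on the transcript: they are derived from
the exon and CDS structure (`derive_introns`, `derive_utrs`) and emitted
by `write_gtf` on request, mirroring a refined annotation deliverable
that carries exon, intron, CDS, five_prime_UTR and three_prime_UTR
features.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

from . import intervals as ivl

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class GtfParseError(ValueError):
    """Malformed GTF content; the message names the offending line."""


class AnnotationValidationError(ValueError):
    """A transcript or annotation set violates its structural invariants."""


class MissingCdsError(ValueError):
    """Raised when UTRs are requested for a transcript with no ORF annotated."""


class StrandUnknownError(ValueError):
    """Raised when an orientation-dependent result is requested on strand '.'."""


def strands_compatible(a: str, b: str) -> bool:
    """'.' acts as a wildcard; '+' and '-' only match themselves."""
    return a == "." or b == "." or a == b


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded half-open interval on a contig (0-based internally)."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise AnnotationValidationError("interval contig must be non-empty")
        if not self.start < self.end:
            raise AnnotationValidationError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise AnnotationValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def bounds(self) -> ivl.Interval:
        return (self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.contig == other.contig and ivl.overlaps(self.bounds, other.bounds)


@dataclass
class TranscriptModel:
    """A stranded multi-exon transcript with optional CDS.

    ``exons`` are sorted, pairwise disjoint intervals on one contig and
    strand; every ``cds`` interval lies inside an exon.  Expression
    (``fpkm``), read depth (``cov``) and the supporting sample labels
    (``sample_ids``) live in ``attributes``.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        self.cds = tuple(sorted(self.cds, key=lambda c: c.start))
        if not self.exons:
            raise AnnotationValidationError(
                f"transcript {self.transcript_id}: at least one exon required"
            )
        contigs = {e.contig for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(contigs) > 1 or len(strands) > 1:
            raise AnnotationValidationError(
                f"transcript {self.transcript_id}: exons span several contigs/strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise AnnotationValidationError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        exon_bounds = [e.bounds for e in self.exons]
        for c in self.cds:
            if c.contig != self.contig or not any(
                ivl.contains(e, c.bounds) for e in exon_bounds
            ):
                raise AnnotationValidationError(
                    f"transcript {self.transcript_id}: CDS [{c.start},{c.end}) "
                    "not contained in any exon"
                )
        for key in ("fpkm", "cov"):
            if key in self.attributes and float(self.attributes[key]) < 0:
                raise AnnotationValidationError(
                    f"transcript {self.transcript_id}: {key} must be >= 0"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start, self.end, self.strand)

    @property
    def exon_bounds(self) -> list[ivl.Interval]:
        return [e.bounds for e in self.exons]

    @property
    def cds_bounds(self) -> list[ivl.Interval]:
        return [c.bounds for c in self.cds]

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    @property
    def fpkm(self) -> float | None:
        v = self.attributes.get("fpkm")
        return None if v is None else float(v)

    @property
    def coverage(self) -> float | None:
        v = self.attributes.get("cov")
        return None if v is None else float(v)

    @property
    def sample_ids(self) -> frozenset[str]:
        v = self.attributes.get("sample_ids", ())
        if isinstance(v, str):
            v = v.split(",") if v else ()
        return frozenset(v)

    def with_attributes(self, **kwargs) -> "TranscriptModel":
        attrs = dict(self.attributes)
        attrs.update(kwargs)
        return replace(self, attributes=attrs)


def derive_introns(transcript: TranscriptModel) -> list[GenomicInterval]:
    """Gaps between consecutive exons; exons + introns partition the span."""
    return [
        GenomicInterval(transcript.contig, s, e, transcript.strand)
        for s, e in ivl.gaps(transcript.exon_bounds)
    ]


def derive_utrs(
    transcript: TranscriptModel,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Exonic-minus-CDS intervals, split into 5' and 3' sides.

    The UTRs are the interval difference between the exonic and the CDS
    region; parts upstream of the CDS in transcript orientation are the
    5' UTR, parts downstream the 3' UTR.
    """
    if not transcript.cds:
        raise MissingCdsError(
            f"transcript {transcript.transcript_id}: no ORF annotated"
        )
    if transcript.strand == ".":
        raise StrandUnknownError(
            f"transcript {transcript.transcript_id}: orientation unknown, "
            "UTR sides undefined"
        )
    cds_start = transcript.cds[0].start
    cds_end = transcript.cds[-1].end
    utr = ivl.subtract(transcript.exon_bounds, transcript.cds_bounds)
    left = [iv for iv in utr if iv[1] <= cds_start]
    right = [iv for iv in utr if iv[0] >= cds_end]
    mk = lambda ivs: [
        GenomicInterval(transcript.contig, s, e, transcript.strand) for s, e in ivs
    ]
    if transcript.strand == "+":
        return mk(left), mk(right)
    return mk(right), mk(left)


class AnnotationSet:
    """A collection of transcripts with gene and interval indexes."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self.transcripts: dict[str, TranscriptModel] = {}
        self.gene_index: dict[str, list[str]] = {}
        self._span_trees: dict[str, IntervalTree] | None = None
        for t in transcripts:
            self.add(t)

    def add(self, transcript: TranscriptModel) -> None:
        if transcript.transcript_id in self.transcripts:
            raise AnnotationValidationError(
                f"duplicate transcript_id {transcript.transcript_id!r}"
            )
        self.transcripts[transcript.transcript_id] = transcript
        self.gene_index.setdefault(transcript.gene_id, []).append(
            transcript.transcript_id
        )
        self._span_trees = None

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def get(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def gene_transcripts(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[t] for t in self.gene_index.get(gene_id, [])]

    def gene_span(self, gene_id: str) -> GenomicInterval:
        """Min-start/max-end envelope over the gene's transcripts."""
        txs = self.gene_transcripts(gene_id)
        if not txs:
            raise KeyError(gene_id)
        return GenomicInterval(
            txs[0].contig,
            min(t.start for t in txs),
            max(t.end for t in txs),
            txs[0].strand,
        )

    def _trees(self) -> dict[str, IntervalTree]:
        if self._span_trees is None:
            trees: dict[str, IntervalTree] = {}
            for t in self.transcripts.values():
                trees.setdefault(t.contig, IntervalTree()).addi(
                    t.start, t.end, t.transcript_id
                )
            self._span_trees = trees
        return self._span_trees

    def overlapping(
        self, contig: str, start: int, end: int
    ) -> list[TranscriptModel]:
        """Transcripts whose span intersects [start, end) on ``contig``."""
        tree = self._trees().get(contig)
        if tree is None:
            return []
        hits = sorted(tree.overlap(start, end), key=lambda h: (h.begin, h.data))
        return [self.transcripts[h.data] for h in hits]


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')
_KNOWN_FEATURES = {"exon", "CDS"}
_DERIVED_FEATURES = {"intron", "five_prime_UTR", "three_prime_UTR"}
_NUMERIC_ATTRS = {"fpkm": "fpkm", "FPKM": "fpkm", "cov": "cov", "coverage": "cov"}


def _parse_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(raw))
    if not attrs or "gene_id" not in attrs or "transcript_id" not in attrs:
        raise GtfParseError(
            f"line {lineno}: attribute field must carry gene_id and "
            f"transcript_id: {raw.strip()!r}"
        )
    return attrs


def read_gtf(path: str | Path) -> AnnotationSet:
    """Read a GTF file into an `AnnotationSet`.

    Exon records are grouped into transcripts by ``transcript_id``; CDS
    records are attached; derived features (intron/UTR) and unknown
    feature types are ignored (unknown ones with a logged warning).
    1-based inclusive GTF coordinates become 0-based half-open.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict] = {}
    warned: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            contig, _source, feature, start, end, _score, strand, _frame, raw = fields
            if feature not in _KNOWN_FEATURES:
                if feature not in _DERIVED_FEATURES and feature not in warned:
                    log.warning(
                        "%s line %d: ignoring unknown feature type %r",
                        path.name, lineno, feature,
                    )
                    warned.add(feature)
                continue
            try:
                iv = GenomicInterval(contig, int(start) - 1, int(end), strand)
            except (ValueError, AnnotationValidationError) as exc:
                raise GtfParseError(f"line {lineno}: {exc}") from exc
            attrs = _parse_attributes(raw, lineno)
            tid = attrs["transcript_id"]
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            else:
                cds.setdefault(tid, []).append(iv)
            if tid not in meta:
                extra = {}
                for key, value in attrs.items():
                    if key in ("gene_id", "transcript_id"):
                        continue
                    if key in _NUMERIC_ATTRS:
                        extra[_NUMERIC_ATTRS[key]] = float(value)
                    elif key == "sample_ids":
                        extra[key] = value
                    else:
                        extra[key] = value
                meta[tid] = {"gene_id": attrs["gene_id"], "attributes": extra}
    out = AnnotationSet()
    for tid, ex in exons.items():
        info = meta[tid]
        try:
            out.add(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=info["gene_id"],
                    exons=tuple(ex),
                    cds=tuple(cds.get(tid, ())),
                    attributes=info["attributes"],
                )
            )
        except AnnotationValidationError as exc:
            raise AnnotationValidationError(f"{path.name}: {exc}") from exc
    return out


def _format_attributes(transcript: TranscriptModel) -> str:
    parts = [
        f'gene_id "{transcript.gene_id}"',
        f'transcript_id "{transcript.transcript_id}"',
    ]
    attrs = transcript.attributes
    for key in ("fpkm", "cov"):
        if key in attrs:
            parts.append(f'{key} "{float(attrs[key]):g}"')
    if "sample_ids" in attrs:
        v = attrs["sample_ids"]
        if not isinstance(v, str):
            v = ",".join(sorted(v))
        parts.append(f'sample_ids "{v}"')
    for key in sorted(attrs):
        if key in ("fpkm", "cov", "sample_ids"):
            continue
        parts.append(f'{key} "{attrs[key]}"')
    return "; ".join(parts) + ";"


def _cds_frames(transcript: TranscriptModel) -> dict[ivl.Interval, int]:
    """GTF frame column per CDS segment, in transcript orientation."""
    segs = list(transcript.cds)
    if transcript.strand == "-":
        segs = segs[::-1]
    frames = {}
    done = 0
    for seg in segs:
        frames[seg.bounds] = (3 - done % 3) % 3
        done += seg.length
    return frames


def write_gtf(
    annotation: AnnotationSet,
    path: str | Path,
    emit_derived: bool = False,
    source: str = "txrefine",
) -> None:
    """Write an `AnnotationSet` as GTF (1-based inclusive coordinates).

    With ``emit_derived`` the intron, five_prime_UTR and three_prime_UTR
    features are computed from the exon/CDS structure and written
    alongside exon and CDS lines.  Attribute order is deterministic so
    equal annotations produce byte-identical files.
    """
    with open(path, "w") as fh:
        for tid in sorted(annotation.transcripts):
            t = annotation.transcripts[tid]
            attrs = _format_attributes(t)

            def emit(feature: str, iv: GenomicInterval, frame: str = ".") -> None:
                fh.write(
                    f"{iv.contig}\t{source}\t{feature}\t{iv.start + 1}\t{iv.end}\t"
                    f".\t{iv.strand}\t{frame}\t{attrs}\n"
                )

            for e in t.exons:
                emit("exon", e)
            frames = _cds_frames(t)
            for c in t.cds:
                emit("CDS", c, str(frames[c.bounds]))
            if emit_derived:
                for i in derive_introns(t):
                    emit("intron", i)
                if t.cds and t.strand in ("+", "-"):
                    five, three = derive_utrs(t)
                    for u in five:
                        emit("five_prime_UTR", u)
                    for u in three:
                        emit("three_prime_UTR", u)
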