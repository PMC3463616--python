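"""Gene-architecture statistics and conservation-score comparisons.

Covers the descriptive layer of an annotation-refinement study: the
position (first/internal/terminal) and host region (5'UTR/CDS/3'UTR) of
every intron, exon position classes, UTR length summaries, and
per-interval mean conservation scores (PhastCons-style, one score per
base in [0, 1]) contrasted between exons, introns and short introns
(the conventional neutral proxy).  Group contrasts use the two-sided
Mann-Whitney rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import (
    AnnotationSet,
    GenomicInterval,
    TranscriptModel,
    derive_introns,
    derive_utrs,
)

log = logging.getLogger(__name__)

POSITION_CLASSES = ("first", "internal", "terminal")
REGION_CLASSES = ("five_prime_utr", "cds", "three_prime_utr", "mixed", "unknown")

# neutral-proxy convention for short (presumably unconstrained) introns
DEFAULT_SHORT_INTRON_MAX_LENGTH = 65


@dataclass(frozen=True)
class IntronRecord:
    gene_id: str
    transcript_id: str
    position_class: str
    region_class: str
    length: int
    interval: GenomicInterval


@dataclass(frozen=True)
class ExonRecord:
    gene_id: str
    transcript_id: str
    position_class: str
    length: int
    interval: GenomicInterval


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    statistic: float
    pvalue: float


def _oriented(items: list, strand: str) -> list:
    return items[::-1] if strand == "-" else items


def classify_intron_positions(
    transcript: TranscriptModel,
) -> list[IntronRecord]:
    """Label each intron first/internal/terminal in transcript orientation.

    A single-intron transcript yields one 'first' intron (the intron at
    first position); with two introns there is a first and a terminal
    one and no internal introns.
    """
    introns = _oriented(derive_introns(transcript), transcript.strand)
    records = []
    for idx, intron in enumerate(introns):
        if idx == 0:
            pos = "first"
        elif idx == len(introns) - 1:
            pos = "terminal"
        else:
            pos = "internal"
        records.append(
            IntronRecord(
                gene_id=transcript.gene_id,
                transcript_id=transcript.transcript_id,
                position_class=pos,
                region_class="unknown",
                length=intron.length,
                interval=intron,
            )
        )
    return records


def classify_exon_positions(transcript: TranscriptModel) -> list[ExonRecord]:
    """Label exons first/internal/terminal; single-exon transcripts are
    excluded from position comparisons and yield no records."""
    if not transcript.is_multi_exon:
        return []
    exons = _oriented(list(transcript.exons), transcript.strand)
    records = []
    for idx, exon in enumerate(exons):
        if idx == 0:
            pos = "first"
        elif idx == len(exons) - 1:
            pos = "terminal"
        else:
            pos = "internal"
        records.append(
            ExonRecord(
                gene_id=transcript.gene_id,
                transcript_id=transcript.transcript_id,
                position_class=pos,
                length=exon.length,
                interval=exon,
            )
        )
    return records


def classify_intron_regions(
    transcript: TranscriptModel,
) -> list[IntronRecord]:
    """Label each intron by the gene region hosting it.

    An intron is five_prime_utr when both flanking exonic bases lie 5'
    of the CDS start (in transcript orientation), three_prime_utr when
    both lie 3' of the CDS end, cds when both fall inside the CDS
    bounds, and mixed otherwise.  Without a CDS all introns are
    unknown.
    """
    introns = derive_introns(transcript)
    if not transcript.cds or transcript.strand == ".":
        region = ["unknown"] * len(introns)
    else:
        cds_start = transcript.cds[0].start
        cds_end = transcript.cds[-1].end

        def side(pos: int) -> str:
            # pos is a genomic base position of a flanking exonic base
            if pos < cds_start:
                return "five_prime_utr" if transcript.strand == "+" else "three_prime_utr"
            if pos >= cds_end:
                return "three_prime_utr" if transcript.strand == "+" else "five_prime_utr"
            return "cds"

        region = []
        for intron in introns:
            left = side(intron.start - 1)
            right = side(intron.end)
            region.append(left if left == right else "mixed")
    positions = classify_intron_positions(transcript)
    return [
        IntronRecord(
            gene_id=r.gene_id,
            transcript_id=r.transcript_id,
            position_class=r.position_class,
            region_class=reg,
            length=r.length,
            interval=r.interval,
        )
        for r, reg in zip(
            positions, _oriented(region, transcript.strand)
        )
    ]


def length_comparisons(
    groups: dict[str, list[int]],
    contrasts: list[tuple[str, str]],
) -> list[ComparisonResult]:
    """Two-sided rank-sum contrasts between named length groups.

    Contrasts with an empty group are skipped with a warning.
    """
    results = []
    for a, b in contrasts:
        xa, xb = groups.get(a, []), groups.get(b, [])
        if not xa or not xb:
            log.warning("contrast %s vs %s skipped: empty group", a, b)
            continue
        stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        results.append(
            ComparisonResult(
                group_a=a, group_b=b, n_a=len(xa), n_b=len(xb),
                mean_a=float(np.mean(xa)), mean_b=float(np.mean(xb)),
                median_a=float(np.median(xa)), median_b=float(np.median(xb)),
                statistic=float(stat), pvalue=float(p),
            )
        )
    return results


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------


class ConservationTrack:
    """Per-base conservation scores; missing positions are NaN."""

    def __init__(self, scores: dict[str, np.ndarray]) -> None:
        self.scores = {}
        for contig, arr in scores.items():
            arr = np.asarray(arr, dtype=float)
            present = arr[~np.isnan(arr)]
            if present.size and (present.min() < 0 or present.max() > 1):
                raise ValueError(
                    f"{contig}: conservation scores must lie in [0, 1]"
                )
            self.scores[contig] = arr

    @classmethod
    def from_bedgraph(
        cls, path, contig_lengths: dict[str, int] | None = None
    ) -> "ConservationTrack":
        """Read a bedGraph-like track (contig, start, end, score; 0-based
        half-open).  Positions not covered by any record stay missing."""
        records: dict[str, list[tuple[int, int, float]]] = {}
        maxima: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                contig, start, end, value = line.split()[:4]
                s, e, v = int(start), int(end), float(value)
                records.setdefault(contig, []).append((s, e, v))
                maxima[contig] = max(maxima.get(contig, 0), e)
        lengths = contig_lengths or maxima
        arrays = {}
        for contig, recs in records.items():
            arr = np.full(lengths[contig], np.nan)
            for s, e, v in recs:
                arr[s:e] = v
            arrays[contig] = arr
        return cls(arrays)

    def __contains__(self, contig: str) -> bool:
        return contig in self.scores


def mean_conservation(
    intervals: list[GenomicInterval], track: ConservationTrack
) -> list[float]:
    """Arithmetic mean score per interval, ignoring missing positions.

    Intervals with zero scored bases come back as NaN (flagged for
    downstream exclusion).  A contig absent from the track is an error.
    """
    out = []
    for iv in intervals:
        if iv.contig not in track:
            raise KeyError(f"contig {iv.contig!r} absent from conservation track")
        window = track.scores[iv.contig][iv.start : iv.end]
        present = window[~np.isnan(window)]
        out.append(float(present.mean()) if present.size else float("nan"))
    return out


def conservation_comparison(
    exon_intervals: list[GenomicInterval],
    intron_intervals: list[GenomicInterval],
    track: ConservationTrack,
    short_intron_max_length: int = DEFAULT_SHORT_INTRON_MAX_LENGTH,
) -> tuple[dict[str, list[float]], list[ComparisonResult]]:
    """Mean-score distributions for exons, introns and short introns,
    with rank-sum contrasts exons-vs-introns and exons-vs-short-introns.
    """
    short = [
        iv for iv in intron_intervals if iv.length <= short_intron_max_length
    ]
    dists = {
        "exons": [m for m in mean_conservation(exon_intervals, track)
                  if not np.isnan(m)],
        "introns": [m for m in mean_conservation(intron_intervals, track)
                    if not np.isnan(m)],
        "short_introns": [m for m in mean_conservation(short, track)
                          if not np.isnan(m)],
    }
    contrasts = [("exons", "introns")]
    if dists["short_introns"]:
        contrasts.append(("exons", "short_introns"))
    else:
        log.warning("no introns at or below %d bp; short-intron contrast skipped",
                    short_intron_max_length)
    results = length_comparisons(dists, contrasts)
    return dists, results


# ---------------------------------------------------------------------------
# UTR summaries
# ---------------------------------------------------------------------------


def longest_isoforms(annotation: AnnotationSet) -> list[TranscriptModel]:
    """One transcript per gene: the one with the largest exonic length
    (smallest transcript_id on ties)."""
    out = []
    for gene_id, tids in sorted(annotation.gene_index.items()):
        txs = [annotation.get(t) for t in tids]
        out.append(
            max(txs, key=lambda t: (t.exonic_length, t.transcript_id))
        )
    return out


def utr_length_stats(annotation: AnnotationSet) -> dict:
    """Per-gene (longest isoform) UTR presence and length summary.

    Genes without a CDS (or without orientation) are counted as having
    no UTR annotation.  Includes the 5'-vs-3' UTR length rank-sum
    contrast when both sides are populated.
    """
    five_lengths: list[int] = []
    three_lengths: list[int] = []
    genes_with_utr = 0
    genes_without_cds = 0
    per_gene = []
    for t in longest_isoforms(annotation):
        if not t.cds or t.strand == ".":
            genes_without_cds += 1
            continue
        five, three = derive_utrs(t)
        l5 = sum(u.length for u in five)
        l3 = sum(u.length for u in three)
        if l5 > 0:
            five_lengths.append(l5)
        if l3 > 0:
            three_lengths.append(l3)
        if l5 > 0 or l3 > 0:
            genes_with_utr += 1
        per_gene.append(
            {"gene_id": t.gene_id, "transcript_id": t.transcript_id,
             "utr5_length": l5, "utr3_length": l3}
        )
    stats_out = {
        "n_genes": len(annotation.gene_index),
        "n_genes_no_cds": genes_without_cds,
        "n_genes_with_utr": genes_with_utr,
        "n_five_prime_utrs": len(five_lengths),
        "n_three_prime_utrs": len(three_lengths),
        "mean_five_prime_utr_length": (
            float(np.mean(five_lengths)) if five_lengths else float("nan")
        ),
        "mean_three_prime_utr_length": (
            float(np.mean(three_lengths)) if three_lengths else float("nan")
        ),
        "per_gene": pd.DataFrame(
            per_gene,
            columns=["gene_id", "transcript_id", "utr5_length", "utr3_length"],
        ),
    }
    if five_lengths and three_lengths:
        (contrast,) = length_comparisons(
            {"five_prime": five_lengths, "three_prime": three_lengths},
            [("five_prime", "three_prime")],
        )
        stats_out["five_vs_three_contrast"] = contrast
    return stats_out
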