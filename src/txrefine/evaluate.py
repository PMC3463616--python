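"""Annotation sensitivity metrics and cross-annotation concordance.

Sensitivity follows the classical gene-prediction convention: at the
base level it is the fraction of validation exonic bases covered by
predicted exonic bases, at the junction level the fraction of distinct
validation splice junctions recovered exactly, and at the isoform level
the fraction of validation multi-exon transcripts whose complete
junction chain is matched by some predicted transcript.  Specificity is
deliberately not reported: against incomplete validation sets (ortholog
re-annotations, EST alignments) a predicted feature absent from the
validation set is not interpretable as a false positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import intervals as ivl
from .annotation_io import AnnotationSet, strands_compatible
from .transcript_algebra import junction_chain

log = logging.getLogger(__name__)


class UndefinedSensitivityError(ValueError):
    """Validation set has no elements at the requested level."""


@dataclass(frozen=True)
class LevelResult:
    matched: int
    total: int

    @property
    def fraction(self) -> float:
        return self.matched / self.total


@dataclass(frozen=True)
class SensitivityReport:
    base_level: LevelResult
    junction_level: LevelResult
    isoform_level: LevelResult

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("base_level", "junction_level", "isoform_level"):
            r = getattr(self, name)
            rows.append(
                {"level": name, "sensitivity": r.fraction,
                 "matched": r.matched, "total": r.total}
            )
        return pd.DataFrame(rows)


def _merged_exons_by_strand(
    annotation: AnnotationSet,
) -> dict[tuple[str, str], list[ivl.Interval]]:
    """Merged exonic intervals per (contig, strand) group."""
    raw: dict[tuple[str, str], list[ivl.Interval]] = {}
    for t in annotation:
        raw.setdefault((t.contig, t.strand), []).extend(t.exon_bounds)
    return {k: ivl.merge(v) for k, v in raw.items()}


def _base_counts(
    predicted: AnnotationSet, validation: AnnotationSet
) -> LevelResult:
    pred = _merged_exons_by_strand(predicted)
    val = _merged_exons_by_strand(validation)
    matched = total = 0
    for (contig, strand), exons in val.items():
        compat = ivl.merge(
            [
                iv
                for (pc, ps), ivs in pred.items()
                if pc == contig and strands_compatible(strand, ps)
                for iv in ivs
            ]
        )
        total += ivl.total_length(exons)
        matched += ivl.intersect_length(exons, compat)
    if total == 0:
        raise UndefinedSensitivityError("validation set has no exonic bases")
    return LevelResult(matched, total)


def _junction_sets(
    annotation: AnnotationSet,
) -> dict[tuple[str, int, int], set[str]]:
    """Distinct junctions -> set of strands carrying them."""
    out: dict[tuple[str, int, int], set[str]] = {}
    for t in annotation:
        for d, a in junction_chain(t).junctions:
            out.setdefault((t.contig, d, a), set()).add(t.strand)
    return out


def _junction_counts(
    predicted: AnnotationSet, validation: AnnotationSet
) -> LevelResult:
    pred = _junction_sets(predicted)
    val = _junction_sets(validation)
    if not val:
        raise UndefinedSensitivityError("validation set has no junctions")
    matched = 0
    for key, strands in val.items():
        pstrands = pred.get(key, set())
        for s in strands:
            if any(strands_compatible(s, p) for p in pstrands):
                matched += 1
                break
    return LevelResult(matched, len(val))


def _chain_sets(
    annotation: AnnotationSet,
) -> dict[tuple[str, tuple], set[str]]:
    out: dict[tuple[str, tuple], set[str]] = {}
    for t in annotation:
        if not t.is_multi_exon:
            continue
        chain = junction_chain(t)
        out.setdefault((chain.contig, chain.junctions), set()).add(t.strand)
    return out


def _isoform_counts(
    predicted: AnnotationSet, validation: AnnotationSet
) -> LevelResult:
    pred = _chain_sets(predicted)
    val = _chain_sets(validation)
    if not val:
        raise UndefinedSensitivityError("validation set has no multi-exon isoforms")
    matched = 0
    for key, strands in val.items():
        pstrands = pred.get(key, set())
        for s in strands:
            if any(strands_compatible(s, p) for p in pstrands):
                matched += 1
                break
    return LevelResult(matched, len(val))


def base_sensitivity(
    predicted: AnnotationSet, validation: AnnotationSet
) -> float:
    """Fraction of validation exonic bases covered by predicted exons."""
    return _base_counts(predicted, validation).fraction


def junction_sensitivity(
    predicted: AnnotationSet, validation: AnnotationSet
) -> float:
    """Fraction of distinct validation junctions recovered exactly."""
    return _junction_counts(predicted, validation).fraction


def isoform_sensitivity(
    predicted: AnnotationSet, validation: AnnotationSet
) -> float:
    """Fraction of validation multi-exon chains matched completely."""
    return _isoform_counts(predicted, validation).fraction


def sensitivity_report(
    predicted: AnnotationSet, validation: AnnotationSet
) -> SensitivityReport:
    return SensitivityReport(
        base_level=_base_counts(predicted, validation),
        junction_level=_junction_counts(predicted, validation),
        isoform_level=_isoform_counts(predicted, validation),
    )


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceReport:
    """Venn-cell membership counts at junction and isoform level."""

    junction_cells: dict[frozenset, int]
    isoform_cells: dict[frozenset, int]
    junction_sizes: dict[str, int]
    isoform_sizes: dict[str, int]

    @staticmethod
    def _private(cells: dict[frozenset, int], sizes: dict[str, int]) -> dict:
        return {
            name: (cells.get(frozenset([name]), 0) / size if size else 0.0)
            for name, size in sizes.items()
        }

    @property
    def private_junction_fraction(self) -> dict[str, float]:
        return self._private(self.junction_cells, self.junction_sizes)

    @property
    def private_isoform_fraction(self) -> dict[str, float]:
        return self._private(self.isoform_cells, self.isoform_sizes)

    def to_frame(self, level: str = "junction") -> pd.DataFrame:
        cells = self.junction_cells if level == "junction" else self.isoform_cells
        rows = [
            {"members": "+".join(sorted(k)), "count": v}
            for k, v in sorted(cells.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["members", "count"])


def concordance(annotations: dict[str, AnnotationSet]) -> ConcordanceReport:
    """Membership-combination counts for junctions and isoform chains.

    Each distinct element (junction or full chain, keyed without
    strand-wildcard resolution) lands in exactly one Venn cell.
    """
    if len(annotations) < 2:
        raise ValueError("concordance needs at least two annotations")

    def cells(extract) -> tuple[dict[frozenset, int], dict[str, int]]:
        membership: dict[object, set[str]] = {}
        sizes: dict[str, int] = {}
        for name, ann in annotations.items():
            elements = extract(ann)
            sizes[name] = len(elements)
            for el in elements:
                membership.setdefault(el, set()).add(name)
        out: dict[frozenset, int] = {}
        for members in membership.values():
            key = frozenset(members)
            out[key] = out.get(key, 0) + 1
        return out, sizes

    junction_cells, junction_sizes = cells(
        lambda ann: set(_junction_sets(ann).keys())
    )
    isoform_cells, isoform_sizes = cells(
        lambda ann: set(_chain_sets(ann).keys())
    )
    return ConcordanceReport(
        junction_cells=junction_cells,
        isoform_cells=isoform_cells,
        junction_sizes=junction_sizes,
        isoform_sizes=isoform_sizes,
    )


# ---------------------------------------------------------------------------
# isoform recovery by expression
# ---------------------------------------------------------------------------

DEFAULT_FPKM_EDGES = (0.0, 1.0, 10.0, 100.0, float("inf"))


def isoforms_by_expression(
    annotation_sets: list[tuple[str, AnnotationSet]],
    edges: tuple[float, ...] = DEFAULT_FPKM_EDGES,
) -> pd.DataFrame:
    """Mean reconstructed isoforms per gene, by gene expression bin.

    Genes are binned by their highest isoform FPKM; transcripts missing
    an FPKM value are excluded with a logged count.  Rows are bins,
    one column of means per named annotation (e.g. pooled-sample
    configurations).
    """
    labels = [
        f"({edges[i]:g}, {edges[i + 1]:g}]" for i in range(len(edges) - 1)
    ]
    table: dict[str, list[float]] = {}
    for name, ann in annotation_sets:
        missing = 0
        per_gene: dict[str, tuple[int, float]] = {}
        for gene_id, tids in ann.gene_index.items():
            fpkms = []
            n = 0
            for tid in tids:
                t = ann.get(tid)
                if t.fpkm is None:
                    missing += 1
                    continue
                fpkms.append(t.fpkm)
                n += 1
            if fpkms:
                per_gene[gene_id] = (n, max(fpkms))
        if missing:
            log.info("%s: excluded %d transcripts without fpkm", name, missing)
        sums = [0.0] * len(labels)
        counts = [0] * len(labels)
        for n, fpkm in per_gene.values():
            for i in range(len(labels)):
                if edges[i] < fpkm <= edges[i + 1]:
                    sums[i] += n
                    counts[i] += 1
                    break
        table[name] = [
            (sums[i] / counts[i] if counts[i] else 0.0)
            for i in range(len(labels))
        ]
        table[f"{name}_n_genes"] = counts
    return pd.DataFrame(table, index=labels)
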