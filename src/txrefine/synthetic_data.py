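"""Deterministic synthetic cohort generator with planted ground truth.

Builds a study-design-shaped test bed entirely in memory: a random
genome, a multi-gene reference annotation with canonical splice signals
and complete ORFs written into the sequence, and per-sample "observed"
annotations (two sexes x two strains, no replicates) containing exact
reference matches, boundary-extended isoforms, novel junction isoforms
of every alternative-splicing mode, intronic and intergenic new genes,
run-on fragments, fusion transcripts and single-sample noise.  Every
planted feature is recorded in a truth table together with the outcome
the consolidation pipeline is expected to produce under the default
thresholds, so recovery can be scored exactly.

Plant categories draw from independent random streams derived from the
master seed, so changing the count of one category does not perturb the
others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import intervals as ivl
from .annotation_io import (
    AnnotationSet,
    GenomicInterval,
    TranscriptModel,
    read_gtf,
    write_gtf,
)
from .consolidate import SampleAnnotation
from .genome import Genome, reverse_complement
from .splicing import STOP_CODONS, find_orf

log = logging.getLogger(__name__)

PLANT_CATEGORIES = (
    "extended",
    "new_isoform_alt_donor",
    "new_isoform_alt_acceptor",
    "new_isoform_exon_skipping",
    "new_isoform_intron_retention",
    "intronic_new_gene",
    "intergenic_new_gene",
    "run_on_fragment",
    "fusion_transcript",
    "single_sample_noise",
)

_STREAMS = (
    "genome",
    "layout",
    "reference",
    "expression",
    "extended",
    "new_isoform_alt_donor",
    "new_isoform_alt_acceptor",
    "new_isoform_exon_skipping",
    "new_isoform_intron_retention",
    "intronic_new_gene",
    "intergenic_new_gene",
    "run_on_fragment",
    "fusion_transcript",
    "single_sample_noise",
    "boundary",
)


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_genes: int = 64
    exon_count_range: tuple[int, int] = (4, 5)
    exon_length_range: tuple[int, int] = (120, 300)
    intron_length_range: tuple[int, int] = (80, 400)
    intergenic_gap_range: tuple[int, int] = (4800, 6400)
    gc_content: float = 0.45
    # the 2-sex x 2-strain adult-fly design, one lane per sample
    samples: tuple[tuple[str, str, str], ...] = (
        ("ps94_male", "male", "ps94"),
        ("ps94_female", "female", "ps94"),
        ("ps88_male", "male", "ps88"),
        ("ps88_female", "female", "ps88"),
    )
    plant_counts: dict = field(
        default_factory=lambda: {c: 6 for c in PLANT_CATEGORIES}
    )
    coverage_range: tuple[float, float] = (3.0, 50.0)
    fpkm_range: tuple[float, float] = (0.5, 200.0)
    run_on_window: int = 2000
    min_samples: int = 2
    min_coverage: float = 2.0
    # extra plants sitting exactly on the support/coverage thresholds
    boundary_plants: bool = True
    contig_name: str = "chrSim"

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.plant_counts.values()):
            raise ValueError("plant counts must be >= 0")
        for r in (
            self.exon_count_range,
            self.exon_length_range,
            self.intron_length_range,
            self.intergenic_gap_range,
        ):
            if r[0] > r[1]:
                raise ValueError(f"empty range {r}")
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must be in [0, 1]")


@dataclass
class TruthRow:
    feature_id: str
    planted_category: str
    target_gene: str
    planted_samples: tuple[str, ...]
    planted_coverage: float
    expected_survival: bool  # passes the support + coverage thresholds
    expected_in_final: bool  # additionally survives fusion/overlap cleanup
    expected_code: str
    as_mode: str = ""
    frame_impact: str = ""
    planted_ext5: int = 0
    planted_ext3: int = 0


@dataclass
class TruthTable:
    rows: list[TruthRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    **vars(r),
                    "planted_samples": ",".join(r.planted_samples),
                }
                for r in self.rows
            ]
        )

    def by_category(self, category: str) -> list[TruthRow]:
        return [r for r in self.rows if r.planted_category == category]


@dataclass
class Cohort:
    config: GeneratorConfig
    genome: Genome
    reference: AnnotationSet
    samples: list[SampleAnnotation]
    truth: TruthTable


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _streams(seed: int) -> dict[str, np.random.Generator]:
    return {
        name: np.random.default_rng((int(seed), idx))
        for idx, name in enumerate(_STREAMS)
    }


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class _MutableContig:
    def __init__(self, seq: str) -> None:
        self.seq = bytearray(seq, "ascii")

    def write(self, pos: int, bases: str) -> None:
        self.seq[pos : pos + len(bases)] = bases.encode("ascii")

    def write_tx(self, pos: int, base: str, strand: str) -> None:
        """Write one base given in transcript orientation."""
        self.write(pos, _COMPLEMENT[base] if strand == "-" else base)

    def __str__(self) -> str:
        return self.seq.decode("ascii")


def _tx_positions(exons: list[ivl.Interval], strand: str) -> list[int]:
    """Genomic base positions in transcript (5'->3') order."""
    pos = [p for s, e in exons for p in range(s, e)]
    return pos[::-1] if strand == "-" else pos


def _project(
    exons: list[ivl.Interval], strand: str, tx_start: int, tx_end: int
) -> list[ivl.Interval]:
    """Project a transcript-coordinate interval to genomic intervals."""
    pos = sorted(_tx_positions(exons, strand)[tx_start:tx_end])
    out: list[ivl.Interval] = []
    for p in pos:
        if out and p == out[-1][1]:
            out[-1] = (out[-1][0], p + 1)
        else:
            out.append((p, p + 1))
    return out


@dataclass
class _RefGene:
    gene_id: str
    transcript_id: str
    strand: str
    exons: list[ivl.Interval]
    introns: list[ivl.Interval]
    cds_tx: tuple[int, int]  # transcript coords of the planted ORF
    cds: list[ivl.Interval]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


# ---------------------------------------------------------------------------
# genome + reference
# ---------------------------------------------------------------------------


def _genome_length_budget(config: GeneratorConfig) -> int:
    max_gene = (
        config.exon_count_range[1] * config.exon_length_range[1]
        + (config.exon_count_range[1] - 1) * config.intron_length_range[1]
    )
    return (config.n_genes + 1) * (
        max_gene + config.intergenic_gap_range[1]
    ) + 10_000


def generate_genome(config: GeneratorConfig) -> Genome:
    """Random nucleotide contig at the configured GC fraction, sized to
    host all genes and intergenic gaps."""
    rng = _streams(config.seed)["genome"]
    n = _genome_length_budget(config)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(
        np.array(["A", "C", "G", "T"])[
            rng.choice(4, size=n, p=probs)
        ]
    )
    return Genome({config.contig_name: seq})


def _layout_genes(config: GeneratorConfig) -> tuple[list[_RefGene], list[ivl.Interval]]:
    rng = _streams(config.seed)["layout"]
    genes: list[_RefGene] = []
    gaps: list[ivl.Interval] = []
    cursor = 0
    for i in range(config.n_genes):
        gap = int(rng.integers(*config.intergenic_gap_range, endpoint=True))
        gaps.append((cursor, cursor + gap))
        cursor += gap
        k = int(rng.integers(*config.exon_count_range, endpoint=True))
        strand = "+" if rng.random() < 0.5 else "-"
        exons: list[ivl.Interval] = []
        introns: list[ivl.Interval] = []
        for j in range(k):
            elen = int(rng.integers(*config.exon_length_range, endpoint=True))
            exons.append((cursor, cursor + elen))
            cursor += elen
            if j < k - 1:
                ilen = int(rng.integers(*config.intron_length_range, endpoint=True))
                introns.append((cursor, cursor + ilen))
                cursor += ilen
        exonic = ivl.total_length(exons)
        utr5 = int(rng.integers(20, 60, endpoint=True))
        utr3 = int(rng.integers(20, 60, endpoint=True))
        utr3 += (exonic - utr5 - utr3) % 3  # CDS length divisible by 3
        cds_tx = (utr5, exonic - utr3)
        cds = _project(exons, strand, *cds_tx)
        genes.append(
            _RefGene(
                gene_id=f"g{i:04d}",
                transcript_id=f"g{i:04d}.t1",
                strand=strand,
                exons=exons,
                introns=introns,
                cds_tx=cds_tx,
                cds=cds,
            )
        )
    gap = int(rng.integers(*config.intergenic_gap_range, endpoint=True))
    gaps.append((cursor, cursor + gap))
    return genes, gaps


def _write_gene_signals(contig: _MutableContig, gene: _RefGene) -> None:
    """Plant canonical GT..AG introns and ATG..stop ORF signals."""
    for s, e in gene.introns:
        if gene.strand == "+":
            contig.write(s, "GT")
            contig.write(e - 2, "AG")
        else:
            contig.write(s, "CT")
            contig.write(e - 2, "AC")
    pos = _tx_positions(gene.exons, gene.strand)
    cds_s, cds_e = gene.cds_tx
    for offset, base in enumerate("ATG"):
        contig.write_tx(pos[cds_s + offset], base, gene.strand)
    for offset, base in enumerate("TAA"):
        contig.write_tx(pos[cds_e - 3 + offset], base, gene.strand)
    # stop-codon barrier at the start of the 3' UTR truncates any
    # run-through reading frame in all three frames
    for offset, base in enumerate("TAATAATAA"):
        contig.write_tx(pos[cds_e + offset], base, gene.strand)


def _scrub_orf(contig: _MutableContig, gene: _RefGene, contig_name: str) -> None:
    """Make the planted ORF the unique longest complete ORF.

    Removes in-frame stop codons inside the planted CDS, start codons in
    the 5' UTR, and (iteratively) any competing ORF that still outruns
    the planted one.
    """
    pos = _tx_positions(gene.exons, gene.strand)
    cds_s, cds_e = gene.cds_tx

    def tx_seq() -> str:
        seq = "".join(
            contig.seq[s:e].decode("ascii") for s, e in gene.exons
        )
        return reverse_complement(seq) if gene.strand == "-" else seq

    for _ in range(40):
        seq = tx_seq()
        changed = False
        # internal in-frame stops -> CTC
        for c in range(cds_s, cds_e - 3, 3):
            if seq[c : c + 3] in STOP_CODONS:
                for offset, base in enumerate("CTC"):
                    contig.write_tx(pos[c + offset], base, gene.strand)
                changed = True
        # upstream start codons in the 5' UTR
        for c in range(0, cds_s):
            if seq[c : c + 3] == "ATG":
                contig.write_tx(pos[c + 1], "C", gene.strand)
                changed = True
        if changed:
            continue
        orf = find_orf(seq)
        if orf is not None and (orf.tx_start, orf.tx_end) == (cds_s, cds_e):
            return
        if orf is not None and orf.tx_start != cds_s:
            # break the competing start codon
            contig.write_tx(pos[orf.tx_start + 1], "C", gene.strand)
            _write_gene_signals(contig, gene)
            continue
        raise RuntimeError(
            f"could not isolate planted ORF for {gene.gene_id}"
        )
    raise RuntimeError(f"ORF scrub did not converge for {gene.gene_id}")


def generate_reference(
    config: GeneratorConfig, genome: Genome
) -> tuple[AnnotationSet, list[_RefGene], list[ivl.Interval]]:
    """Lay out non-overlapping multi-exon genes with complete ORFs and
    write their splice/ORF signals into the genome (in place)."""
    genes, gaps = _layout_genes(config)
    contig = _MutableContig(genome.sequences[config.contig_name])
    for gene in genes:
        _write_gene_signals(contig, gene)
        _scrub_orf(contig, gene, config.contig_name)
    genome.sequences[config.contig_name] = str(contig)
    annotation = AnnotationSet()
    for gene in genes:
        annotation.add(
            TranscriptModel(
                transcript_id=gene.transcript_id,
                gene_id=gene.gene_id,
                exons=tuple(
                    GenomicInterval(config.contig_name, s, e, gene.strand)
                    for s, e in gene.exons
                ),
                cds=tuple(
                    GenomicInterval(config.contig_name, s, e, gene.strand)
                    for s, e in gene.cds
                ),
            )
        )
    return annotation, genes, gaps


# ---------------------------------------------------------------------------
# plants
# ---------------------------------------------------------------------------


def _draw_coverage(rng: np.random.Generator, config: GeneratorConfig) -> float:
    """Coverage avoiding the +-0.5 band around the filter threshold."""
    lo, hi = config.coverage_range
    for _ in range(100):
        v = float(rng.uniform(lo, hi))
        if abs(v - config.min_coverage) > 0.5:
            return round(v, 2)
    raise RuntimeError("coverage range collapses onto the threshold band")


def _draw_samples(
    rng: np.random.Generator, config: GeneratorConfig, n: int | None = None
) -> tuple[str, ...]:
    ids = [s[0] for s in config.samples]
    if n is None:
        n = int(rng.integers(2, len(ids), endpoint=True))
    picked = rng.choice(len(ids), size=n, replace=False)
    return tuple(sorted(ids[i] for i in picked))


def _frame_impact(
    genome: Genome,
    gene: _RefGene,
    contig: str,
    region: list[ivl.Interval],
    inclusion_exons: list[ivl.Interval],
    delta: int,
) -> str:
    """Mod-3 rule at plant time; translation decides premature stops."""
    if delta % 3 != 0:
        return "frameshift"
    # hypothetical inclusion CDS: reference CDS plus the event region
    cds = ivl.intersect(
        ivl.merge(gene.cds + region), inclusion_exons
    )
    seq = "".join(genome.fetch(contig, s, e) for s, e in cds)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    for c in range(0, len(seq) - 5, 3):
        codon = seq[c : c + 3]
        if codon in STOP_CODONS:
            return "premature_stop"
    return "frame_preserving"


class _PlantContext:
    """Bookkeeping for gene/gap allocation during planting."""

    def __init__(self, config: GeneratorConfig, genes: list[_RefGene],
                 gaps: list[ivl.Interval]) -> None:
        self.config = config
        self.genes = genes
        self.free_genes = list(range(len(genes)))
        self.free_gaps = set(range(len(gaps)))
        self.gaps = gaps

    def take_gene(self, predicate=None) -> _RefGene:
        for idx in self.free_genes:
            if predicate is None or predicate(self.genes[idx]):
                self.free_genes.remove(idx)
                return self.genes[idx]
        raise RuntimeError("no reference gene satisfies the plant constraints")

    def take_adjacent_pair(self) -> tuple[_RefGene, _RefGene]:
        for idx in self.free_genes:
            if (
                idx + 1 in self.free_genes
                and self.genes[idx].strand == self.genes[idx + 1].strand
            ):
                self.free_genes.remove(idx)
                self.free_genes.remove(idx + 1)
                return self.genes[idx], self.genes[idx + 1]
        raise RuntimeError("no adjacent same-strand gene pair available")

    def take_gap(self, min_length: int = 0) -> ivl.Interval:
        for idx in sorted(self.free_gaps):
            if ivl.length(self.gaps[idx]) >= min_length:
                self.free_gaps.remove(idx)
                return self.gaps[idx]
        raise RuntimeError("no free intergenic gap long enough")

    def run_on_gap_index(self, gene: _RefGene) -> int:
        idx = self.genes.index(gene)
        return idx + 1 if gene.strand == "+" else idx

    def reserve_run_on_gap(self, gene: _RefGene) -> ivl.Interval:
        gap_idx = self.run_on_gap_index(gene)
        if gap_idx not in self.free_gaps:
            raise RuntimeError("run-on gap already reserved")
        self.free_gaps.remove(gap_idx)
        return self.gaps[gap_idx]


@dataclass
class _Plant:
    feature_id: str
    category: str
    transcript: TranscriptModel
    samples: tuple[str, ...]
    coverage: float
    truth: TruthRow


def _observed(
    contig: str,
    feature_id: str,
    strand: str,
    exons: list[ivl.Interval],
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=feature_id,
        gene_id=f"obs_{feature_id}",
        exons=tuple(GenomicInterval(contig, s, e, strand) for s, e in exons),
    )


def plant_variants(
    config: GeneratorConfig,
    reference: AnnotationSet,
    genome: Genome,
    genes: list[_RefGene],
    gaps: list[ivl.Interval],
) -> tuple[list[SampleAnnotation], TruthTable]:
    """Construct the per-sample observed annotations and the truth table."""
    streams = _streams(config.seed)
    contig = config.contig_name
    ctx = _PlantContext(config, genes, gaps)
    plants: list[_Plant] = []
    counts = {**{c: 0 for c in PLANT_CATEGORIES}, **config.plant_counts}

    def survival(samples: tuple[str, ...], cov: float) -> bool:
        return len(samples) >= config.min_samples and cov > config.min_coverage

    def add(feature_id, category, transcript, samples, cov, *, target="",
            code="", as_mode="", frame_impact="", in_final=None,
            ext5=0, ext3=0) -> None:
        surv = survival(samples, cov)
        plants.append(
            _Plant(
                feature_id=feature_id,
                category=category,
                transcript=transcript,
                samples=samples,
                coverage=cov,
                truth=TruthRow(
                    feature_id=feature_id,
                    planted_category=category,
                    target_gene=target,
                    planted_samples=samples,
                    planted_coverage=cov,
                    expected_survival=surv,
                    expected_in_final=surv if in_final is None else in_final,
                    expected_code=code,
                    as_mode=as_mode,
                    frame_impact=frame_impact,
                    planted_ext5=ext5,
                    planted_ext3=ext3,
                ),
            )
        )

    # ---- fusion transcripts first: they consume adjacent gene pairs ----
    rng = streams["fusion_transcript"]
    for i in range(counts["fusion_transcript"]):
        ga, gb = ctx.take_adjacent_pair()
        exons = list(ga.exons) + [gb.exons[0]]
        fid = f"fus{i:03d}"
        add(
            fid, "fusion_transcript",
            _observed(contig, fid, ga.strand, exons),
            _draw_samples(rng, config), _draw_coverage(rng, config),
            target=ga.gene_id, code="j", in_final=False,
        )

    # ---- boundary-threshold plants (explicit threshold probes) ----
    if config.boundary_plants:
        rng = streams["boundary"]
        sample_ids = [s[0] for s in config.samples]
        probes = [
            ("bnd_cov_at", 2, config.min_coverage),        # strict >: fails
            ("bnd_cov_above", 2, config.min_coverage + 0.01),
            ("bnd_samples_one", 1, 10.0),                  # < min_samples
            ("bnd_samples_two", 2, 10.0),
        ]
        for fid, n_samples, cov in probes:
            gene = ctx.take_gene(lambda g: len(g.introns) >= 3)
            intron = gene.introns[1]
            exons = ivl.merge([e for e in gene.exons] + [intron])
            samples = tuple(sorted(sample_ids[:n_samples]))
            add(
                fid, "new_isoform_intron_retention",
                _observed(contig, fid, gene.strand, exons),
                samples, cov,
                target=gene.gene_id, code="j", as_mode="intron_retention",
                frame_impact=_frame_impact(
                    genome, gene, contig, [intron], exons, ivl.length(intron)
                ),
            )

    # ---- extended isoforms ----
    rng = streams["extended"]
    for i in range(counts["extended"]):
        gene = ctx.take_gene()
        ext5 = int(rng.integers(100, 400, endpoint=True))
        ext3 = int(rng.integers(100, 400, endpoint=True))
        left, right = (ext5, ext3) if gene.strand == "+" else (ext3, ext5)
        exons = list(gene.exons)
        exons[0] = (exons[0][0] - left, exons[0][1])
        exons[-1] = (exons[-1][0], exons[-1][1] + right)
        fid = f"ext{i:03d}"
        add(
            fid, "extended",
            _observed(contig, fid, gene.strand, exons),
            _draw_samples(rng, config), _draw_coverage(rng, config),
            target=gene.gene_id, code="=", ext5=ext5, ext3=ext3,
        )

    # ---- novel junction isoforms, one construction per AS mode ----
    def plant_isoform(mode: str, build) -> None:
        rng = streams[f"new_isoform_{mode}"]
        for i in range(counts[f"new_isoform_{mode}"]):
            gene = ctx.take_gene(lambda g: len(g.introns) >= 3)
            exons, region, delta = build(rng, gene)
            # frame impact is measured on the isoform that contains the
            # region exonically (novel for retention/alt sites, the
            # reference for exon skipping)
            incl_exons = exons if delta > 0 else list(gene.exons)
            fid = f"{mode[:6]}{i:03d}"
            add(
                fid, f"new_isoform_{mode}",
                _observed(contig, fid, gene.strand, exons),
                _draw_samples(rng, config), _draw_coverage(rng, config),
                target=gene.gene_id, code="j", as_mode=mode,
                frame_impact=_frame_impact(
                    genome, gene, contig, region, incl_exons, delta
                ),
            )

    def build_intron_retention(rng, gene):
        j = int(rng.integers(1, len(gene.introns) - 1))
        intron = gene.introns[j]
        exons = ivl.merge(list(gene.exons) + [intron])
        return exons, [intron], ivl.length(intron)

    def build_exon_skipping(rng, gene):
        j = int(rng.integers(1, len(gene.exons) - 1))
        exon = gene.exons[j]
        exons = [e for e in gene.exons if e != exon]
        return exons, [exon], -ivl.length(exon)

    def _shift_boundary(rng, gene, donor: bool):
        j = int(rng.integers(1, len(gene.introns) - 1))
        s, e = gene.introns[j]
        max_delta = min(60, (e - s) - 30)
        delta = int(rng.integers(6, max_delta, endpoint=True))
        # donor = 5' intron end in transcript orientation
        shift_start = (gene.strand == "+") == donor
        if shift_start:
            new_intron, region = (s + delta, e), (s, s + delta)
        else:
            new_intron, region = (s, e - delta), (e - delta, e)
        exons = ivl.subtract(
            [(gene.start, gene.end)],
            [iv for k, iv in enumerate(gene.introns) if k != j] + [new_intron],
        )
        return exons, [region], delta

    plant_isoform("intron_retention", build_intron_retention)
    plant_isoform("exon_skipping", build_exon_skipping)
    plant_isoform(
        "alt_donor", lambda rng, gene: _shift_boundary(rng, gene, donor=True)
    )
    plant_isoform(
        "alt_acceptor", lambda rng, gene: _shift_boundary(rng, gene, donor=False)
    )

    # ---- run-on fragments ----
    rng = streams["run_on_fragment"]
    for i in range(counts["run_on_fragment"]):
        gene = ctx.take_gene(
            lambda g: ctx.run_on_gap_index(g) in ctx.free_gaps
        )
        ctx.reserve_run_on_gap(gene)
        offset = int(rng.integers(200, 1200, endpoint=True))
        length = int(rng.integers(150, 400, endpoint=True))
        if gene.strand == "+":
            exon = (gene.end + offset, gene.end + offset + length)
        else:
            exon = (gene.start - offset - length, gene.start - offset)
        fid = f"runon{i:03d}"
        add(
            fid, "run_on_fragment",
            _observed(contig, fid, gene.strand, [exon]),
            _draw_samples(rng, config), _draw_coverage(rng, config),
            target=gene.gene_id, code="p",
        )

    # ---- intronic new genes ----
    rng = streams["intronic_new_gene"]
    for i in range(counts["intronic_new_gene"]):
        gene = ctx.take_gene(
            lambda g: max(ivl.length(iv) for iv in g.introns) >= 140
        )
        intron = max(gene.introns, key=ivl.length)
        length = min(200, ivl.length(intron) - 40)
        lo = intron[0] + 20
        start = int(rng.integers(lo, intron[1] - 20 - length, endpoint=True))
        strand = "+" if rng.random() < 0.5 else "-"
        fid = f"intg{i:03d}"
        add(
            fid, "intronic_new_gene",
            _observed(contig, fid, strand, [(start, start + length)]),
            _draw_samples(rng, config), _draw_coverage(rng, config),
            target=gene.gene_id, code="i",
        )

    # ---- intergenic new genes (two exons: splicing evidence) ----
    rng = streams["intergenic_new_gene"]
    clearance = config.run_on_window + 100
    for i in range(counts["intergenic_new_gene"]):
        e1 = int(rng.integers(100, 200, endpoint=True))
        e2 = int(rng.integers(100, 200, endpoint=True))
        ilen = int(rng.integers(80, 200, endpoint=True))
        span = e1 + ilen + e2
        gap = ctx.take_gap(min_length=2 * clearance + span)
        lo = gap[0] + clearance
        hi = gap[1] - clearance - span
        start = int(rng.integers(lo, hi, endpoint=True))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = [(start, start + e1), (start + e1 + ilen, start + e1 + ilen + e2)]
        fid = f"newg{i:03d}"
        add(
            fid, "intergenic_new_gene",
            _observed(contig, fid, strand, exons),
            _draw_samples(rng, config), _draw_coverage(rng, config),
            code="u",
        )

    # ---- single-sample noise ----
    rng = streams["single_sample_noise"]
    sample_ids = [s[0] for s in config.samples]
    for i in range(counts["single_sample_noise"]):
        fid = f"noise{i:03d}"
        sample = sample_ids[int(rng.integers(0, len(sample_ids)))]
        if i % 2 == 0:
            # genic noise: spurious junction variant of an unused gene
            gene = ctx.take_gene(lambda g: len(g.introns) >= 2)
            s, e = gene.introns[0]
            exons = ivl.subtract(
                [(gene.start, gene.end)],
                [(s + 5, e)] + gene.introns[1:],
            )
            strand = gene.strand
            target = gene.gene_id
        else:
            length = int(rng.integers(150, 400, endpoint=True))
            gap = ctx.take_gap(min_length=length + 1200)
            start = int(rng.integers(gap[0] + 600, gap[1] - 600 - length,
                                     endpoint=True))
            exons = [(start, start + length)]
            strand = "+" if rng.random() < 0.5 else "-"
            target = ""
        add(
            fid, "single_sample_noise",
            _observed(contig, fid, strand, exons),
            (sample,), _draw_coverage(rng, config),
            target=target, in_final=False,
        )

    # ---- exact reference matches on every remaining gene ----
    rng = streams["reference"]
    for idx in list(ctx.free_genes):
        gene = genes[idx]
        fid = f"match_{gene.gene_id}"
        n = int(rng.integers(2, len(sample_ids), endpoint=True))
        add(
            fid, "reference_match",
            _observed(contig, fid, gene.strand, list(gene.exons)),
            _draw_samples(rng, config, n=n), _draw_coverage(rng, config),
            target=gene.gene_id, code="=",
        )

    # the AS-mode host genes also carry their exact reference isoform so
    # that novel isoforms pair with an expressed reference chain
    for plant in list(plants):
        if plant.category.startswith("new_isoform_"):
            gene = next(
                g for g in genes if g.gene_id == plant.truth.target_gene
            )
            fid = f"match_{gene.gene_id}"
            if any(p.feature_id == fid for p in plants):
                continue
            add(
                fid, "reference_match",
                _observed(contig, fid, gene.strand, list(gene.exons)),
                _draw_samples(rng, config), _draw_coverage(rng, config),
                target=gene.gene_id, code="=",
            )

    # ---- distribute plants over the per-sample annotations ----
    rng_expr = streams["expression"]
    per_sample: dict[str, AnnotationSet] = {
        sid: AnnotationSet() for sid in sample_ids
    }
    for plant in plants:
        fpkm = round(float(rng_expr.uniform(*config.fpkm_range)), 3)
        for sid in plant.samples:
            cov = plant.coverage
            if len(plant.samples) > 1 and sid != plant.samples[0]:
                cov = round(float(rng_expr.uniform(
                    min(1.0, plant.coverage), plant.coverage
                )), 2)
            per_sample[sid].add(
                plant.transcript.with_attributes(
                    cov=cov, fpkm=fpkm, sample_ids=sid
                )
            )
    samples = [
        SampleAnnotation(sid, sex, strain, per_sample[sid])
        for sid, sex, strain in config.samples
    ]
    return samples, TruthTable([p.truth for p in plants])


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Genome + reference + observed samples + truth, deterministically."""
    config = config or GeneratorConfig()
    genome = generate_genome(config)
    reference, genes, gaps = generate_reference(config, genome)
    samples, truth = plant_variants(config, reference, genome, genes, gaps)
    return Cohort(
        config=config, genome=genome, reference=reference,
        samples=samples, truth=truth,
    )


# ---------------------------------------------------------------------------
# emit / reload
# ---------------------------------------------------------------------------


def emit(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, reference and per-sample GTFs and the truth
    TSV; re-reading the files reproduces the in-memory objects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["genome"] = out / "genome.fa"
    cohort.genome.to_fasta(paths["genome"])
    paths["reference"] = out / "reference.gtf"
    write_gtf(cohort.reference, paths["reference"])
    for sample in cohort.samples:
        p = out / f"sample_{sample.sample_id}.gtf"
        write_gtf(sample.annotation, p)
        paths[sample.sample_id] = p
    paths["truth"] = out / "truth.tsv"
    cohort.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


def load_samples(
    config: GeneratorConfig, out_dir: str | Path
) -> list[SampleAnnotation]:
    out = Path(out_dir)
    return [
        SampleAnnotation(sid, sex, strain,
                         read_gtf(out / f"sample_{sid}.gtf"))
        for sid, sex, strain in config.samples
    ]
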