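"""Genome sequence access (FASTA in, oriented sub-sequences out)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation_io import TranscriptModel

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """In-memory nucleotide sequences keyed by contig name."""

    def __init__(self, sequences: dict[str, str]) -> None:
        self.sequences = {k: v.upper() for k, v in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        return cls(
            {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        )

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences

    def contig_length(self, contig: str) -> int:
        return len(self.sequences[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Sub-sequence [start, end); reverse-complemented on '-'."""
        seq = self.sequences[contig][start:end]
        return reverse_complement(seq) if strand == "-" else seq


def transcript_sequence(genome: Genome, transcript: TranscriptModel) -> str:
    """Spliced transcript sequence in transcript (5'->3') orientation."""
    return _spliced(genome, transcript.contig, transcript.exon_bounds,
                    transcript.strand)


def cds_sequence(genome: Genome, transcript: TranscriptModel) -> str:
    """Spliced CDS sequence in transcript orientation."""
    return _spliced(genome, transcript.contig, transcript.cds_bounds,
                    transcript.strand)


def _spliced(
    genome: Genome, contig: str, bounds: Iterable[tuple[int, int]], strand: str
) -> str:
    parts = [genome.fetch(contig, s, e) for s, e in bounds]
    seq = "".join(parts)
    return reverse_complement(seq) if strand == "-" else seq
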