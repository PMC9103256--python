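"""Core genomic value types shared across the pipeline.

All internal coordinates are 0-based, half-open ``[start, end)``. Conversions
to/from 1-based formats (cytosine reports, GFF3) happen only at I/O boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field

CONTEXTS = ("CG", "CHG", "CHH")

#: fine-grained gene sub-features, in tie-break priority order
#: (promoter > exon > intron > downstream)
FEATURE_CLASSES = (
    "distal_promoter",
    "intermediate_promoter",
    "proximal_promoter",
    "first_exon",
    "internal_exon",
    "last_exon",
    "first_intron",
    "internal_intron",
    "last_intron",
    "downstream",
)


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic span, 0-based half-open, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be +, - or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """A gene with its exon structure.

    ``exons`` are 0-based half-open intervals sorted by genomic coordinate;
    transcription order (first/internal/last) is derived from ``strand``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid span")
        self.exons = sorted(self.exons)
        for (s, e) in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside gene span"
                )

    @property
    def tss(self) -> int:
        """0-based transcription start site."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, genomic order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    def exons_transcription_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def introns_transcription_order(self) -> list[tuple[int, int]]:
        return self.introns if self.strand == "+" else self.introns[::-1]
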