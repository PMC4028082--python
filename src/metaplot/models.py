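"""Core genomic domain types.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Strand is ``"+"``, ``"-"`` or ``"."`` (unstranded). These types are deliberately
small, immutable containers; the algorithms that operate on them live in
:mod:`metaplot.annotation`, :mod:`metaplot.regions` and :mod:`metaplot.coverage`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-", ".")

#: gene / transcript biotypes recognised by the annotation store
BIOTYPES = ("protein_coding", "pseudogene", "lincRNA", "miRNA", "misc")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = f"{self.chrom}:{self.start}-{self.end}"
        return s if self.strand == "." else f"{s}({self.strand})"


@dataclass(frozen=True, slots=True)
class TranscriptModel:
    """One isoform: an ordered chain of non-overlapping exons on one strand."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be +/-, got {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"transcript {self.transcript_id} spans chromosomes")
        prev_end = -1
        for e in self.exons:
            if e.start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons unsorted or overlapping"
                )
            prev_end = e.end

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span_start(self) -> int:
        return self.exons[0].start

    @property
    def span_end(self) -> int:
        return self.exons[-1].end

    @property
    def genomic_span(self) -> int:
        return self.span_end - self.span_start

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start: lowest coordinate for ``+``, highest for ``-``."""
        return self.span_start if self.strand == "+" else self.span_end

    @property
    def tes(self) -> int:
        return self.span_end if self.strand == "+" else self.span_start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.span_start, self.span_end, self.strand)

    def exons_5to3(self) -> tuple[GenomicInterval, ...]:
        """Exons in transcription order (reverse genomic order on ``-``)."""
        return self.exons if self.strand == "+" else self.exons[::-1]


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene with its isoforms and a designated representative isoform."""

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]
    representative: str
    gene_name: str = ""

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        ids = {t.transcript_id for t in self.transcripts}
        if self.representative not in ids:
            raise ValueError(
                f"representative {self.representative!r} not among transcripts of "
                f"{self.gene_id}"
            )
        if any(t.gene_id != self.gene_id for t in self.transcripts):
            raise ValueError(f"gene {self.gene_id}: transcript gene_id mismatch")

    @property
    def rep(self) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == self.representative:
                return t
        raise AssertionError("unreachable")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.rep.strand

    @property
    def tss(self) -> int:
        return self.rep.tss

    @property
    def tes(self) -> int:
        return self.rep.tes

    @property
    def span(self) -> GenomicInterval:
        return self.rep.span

    @property
    def biotype(self) -> str:
        return self.rep.biotype
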