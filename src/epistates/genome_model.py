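"""Core genomic coordinate types and interval arithmetic.

All coordinates are 0-based, half-open (BED convention). GFF3 input is
converted on read (start - 1) by :mod:`epistates.io_formats`; everything
downstream assumes the single internal convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "TSSWindow",
    "tss_of",
    "overlap_length",
    "contains",
]

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open, 0-based, optionally stranded interval on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome identifier; must be non-empty.
    start, end : int
        0-based half-open bounds; ``0 <= start < end`` is enforced.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded, the default).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        """Midpoint in continuous coordinates (may be half-integral)."""
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with a stranded body interval.

    The TSS is taken from the gene-body 5' end: ``start`` for plus-strand
    genes and ``end - 1`` for minus-strand genes (the last covered base
    under the half-open convention).
    """

    gene_id: str
    body: GenomicInterval
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.body.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be + or -, got {self.body.strand!r}"
            )

    @property
    def tss(self) -> int:
        return tss_of(self)


def tss_of(gene: GeneAnnotation) -> int:
    """Transcription start site of *gene* as a 0-based position.

    Plus-strand genes start at ``body.start``; minus-strand genes start at
    ``body.end - 1``, the biological 5' end in half-open coordinates.
    """
    strand = gene.body.strand
    if strand == "+":
        return gene.body.start
    if strand == "-":
        return gene.body.end - 1
    raise ValueError(f"gene {gene.gene_id!r} is unstranded; TSS requires + or -")


@dataclass(frozen=True)
class TSSWindow:
    """Symmetric window of ``+- halfwidth`` bases around a TSS anchor.

    The derived interval is ``[anchor - halfwidth, anchor + halfwidth + 1)``
    clipped at zero, so the anchor base is always contained.
    """

    chrom: str
    anchor: int
    halfwidth: int = 500
    interval: GenomicInterval = field(init=False)

    def __post_init__(self) -> None:
        if self.halfwidth < 0:
            raise ValueError("halfwidth must be >= 0")
        if self.anchor < 0:
            raise ValueError("anchor must be >= 0")
        iv = GenomicInterval(
            self.chrom,
            max(0, self.anchor - self.halfwidth),
            self.anchor + self.halfwidth + 1,
        )
        object.__setattr__(self, "interval", iv)

    def contains_position(self, pos: float) -> bool:
        """True if *pos* (a base or continuous midpoint) falls in the window."""
        return self.interval.start <= pos < self.interval.end


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by *a* and *b* (0 on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def contains(outer: GenomicInterval, inner: GenomicInterval, slack: int = 0) -> bool:
    """True iff *inner* lies within *outer* extended by *slack* bases each side.

    Containment is non-strict: an interval contains itself at slack 0.
    """
    if slack < 0:
        raise ValueError("slack must be >= 0")
    if outer.chrom != inner.chrom:
        return False
    return outer.start - slack <= inner.start and inner.end <= outer.end + slack
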