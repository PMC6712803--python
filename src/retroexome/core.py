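"""Domain types and coordinate conventions.

All internal coordinates are 0-based half-open intervals. The 1-based
conventions of SAM (POS) and VCF (POS) are converted at the reader/writer
boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

STRANDS = ("+", "-", ".")
GENOTYPES = ("het", "hom")
BASES = ("A", "C", "G", "T")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene as the union of its exons over all isoforms.

    ``exons`` are disjoint, sorted by start; ``introns`` are the gaps
    between consecutive exons, so a gene with n exons has n-1 introns.
    Retrocopy detection only operates on intron-bearing genes (n >= 2),
    because an intronless retrocopy of a single-exon gene leaves no
    intron-removal footprint.
    """

    symbol: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.symbol}: at least one exon required")
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"gene {self.symbol}: exons not sorted/disjoint at {prev} vs {cur}"
                )
        for e in self.exons:
            if e.chrom != self.chrom:
                raise ValueError(f"gene {self.symbol}: exon on wrong chromosome {e}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def cdna_length(self) -> int:
        return sum(e.length() for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)


@dataclass(frozen=True)
class MateAlignment:
    """One mate's aligned reference block (0-based half-open) and MAPQ."""

    start: int
    end: int
    mapq: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty mate alignment")
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"MAPQ out of range: {self.mapq}")

    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedPairRecord:
    """A read pair mapped to one chromosome.

    The ostensible template length is the reference-coordinate span of the
    pair. For genomic fragments it approximates the true fragment length;
    for fragments reverse-transcribed from spliced mRNA it is inflated by
    every intron lying between the mates, which is the detection signal.
    It is always recomputed from the mates' coordinates, never taken from
    the SAM TLEN column.
    """

    sample_id: str
    fragment_id: str
    chrom: str
    mate1: MateAlignment
    mate2: MateAlignment
    proper_orientation: bool = True

    @property
    def ostensible_tlen(self) -> int:
        return max(self.mate1.end, self.mate2.end) - min(self.mate1.start, self.mate2.start)

    @property
    def min_mapq(self) -> int:
        return min(self.mate1.mapq, self.mate2.mapq)


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the retrocopy caller.

    Defaults mirror the reference behaviour: both mates MAPQ >= 20,
    pair span >= 1000 bp, an exon is supported by >= 2 read ends, and a
    candidate needs >= 3 supported exons (i.e. more than 2 discrete exons).
    """

    min_mapq: int = 20
    min_tlen: int = 1000
    min_supported_exons: int = 3
    min_reads_per_exon: int = 2
    recurrence_fraction: float = 1.0

    def __post_init__(self) -> None:
        if min(self.min_mapq, self.min_tlen, self.min_reads_per_exon) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_supported_exons < 2:
            raise ValueError("min_supported_exons must be >= 2")
        if not 0.0 <= self.recurrence_fraction <= 1.0:
            raise ValueError("recurrence_fraction must be in [0, 1]")


KNOWN_RETROCOPY = "known_retrocopy"
RECURRENT_RELIC = "recurrent_relic"


@dataclass
class RetroCandidate:
    """One putative retrotransposed gene in one sample."""

    sample_id: str
    gene: GeneModel
    supported_exons: frozenset[int]
    reads_per_exon: dict[int, int]
    n_supporting_pairs: int
    flags: set[str] = field(default_factory=set)

    @property
    def symbol(self) -> str:
        return self.gene.symbol

    @property
    def chrom(self) -> str:
        return self.gene.chrom


@dataclass(frozen=True)
class SomaticVariant:
    """A single-nucleotide difference between an iPSC line and its parent.

    ``pos`` is 0-based; ``context3`` is the reference trinucleotide centred
    on the site (middle base == ref_allele) when known. ``depth`` is total
    read depth at the site in the iPSC sample, None when the caller did not
    report it (such variants fail any positive depth filter downstream).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    depth: Optional[int] = None
    genotype: str = "het"
    context3: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_allele not in BASES or self.alt_allele not in BASES:
            raise ValueError(
                f"alleles must be single bases, got {self.ref_allele}>{self.alt_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be het or hom, got {self.genotype!r}")
        if self.context3 is not None:
            if len(self.context3) != 3:
                raise ValueError(f"context3 must have length 3: {self.context3!r}")
            if self.context3[1] != self.ref_allele:
                raise ValueError(
                    f"context3 middle base {self.context3[1]!r} != ref {self.ref_allele!r}"
                )


@dataclass
class SignatureCounts:
    """Counts over the 96 single-base-substitution classes."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        from .signatures import SBS96_CLASSES  # local import avoids a cycle

        if set(self.counts) != set(SBS96_CLASSES):
            raise ValueError("counts must have exactly the 96 canonical class keys")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative class count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())
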