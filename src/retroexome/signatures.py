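"""SBS96 mutational signatures from iPSC-versus-parent variant calls.

Somatic single-nucleotide variants are the calls private to the iPSC line
(an iPSC derives from one cell, so its somatic mutations are clonal and
callable, unlike in the parental bulk). Variants are filtered on read
depth and on structural-mutation exclusion regions, then tabulated over
the 96 classes defined by the pyrimidine-strand substitution and its two
flanking reference bases.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .core import GenomicInterval, SignatureCounts, SomaticVariant

log = logging.getLogger(__name__)

PYRIMIDINES = ("C", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: Canonical ordering: six substitution blocks, contexts lexicographic.
SBS96_CLASSES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SignatureFilterParams:
    """Variant filters applied before signature counting.

    ``min_depth`` is total read depth at the site in the iPSC sample
    (default 8 reads); variants inside any ``excluded_regions`` interval
    (structural mutations from SNP-array genotyping: deletions, CN gains,
    CN-LOH) are removed.
    """

    min_depth: int = 8
    excluded_regions: list[GenomicInterval] = field(default_factory=list)
    require_pass: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


def somatic_diff(
    ipsc_variants: Iterable[SomaticVariant],
    parent_variants: Iterable[SomaticVariant],
) -> list[SomaticVariant]:
    """Variants present in the iPSC call set and absent (same chrom, pos,
    alt) from the parental set. Homozygous iPSC calls are retained: a
    somatic mutation followed by gene conversion presents as hom.

    Raises ValueError if the two sets disagree on the reference base at a
    shared position (different reference builds).
    """
    parent_ref: dict[tuple[str, int], str] = {}
    parent_keys: set[tuple[str, int, str]] = set()
    for v in parent_variants:
        parent_keys.add((v.chrom, v.pos, v.alt_allele))
        parent_ref[(v.chrom, v.pos)] = v.ref_allele
    out: list[SomaticVariant] = []
    for v in ipsc_variants:
        known_ref = parent_ref.get((v.chrom, v.pos))
        if known_ref is not None and known_ref != v.ref_allele:
            raise ValueError(
                f"reference mismatch at {v.chrom}:{v.pos + 1}: "
                f"{v.ref_allele} vs {known_ref} — different references?"
            )
        if (v.chrom, v.pos, v.alt_allele) not in parent_keys:
            out.append(v)
    return out


def apply_filters(
    variants: Iterable[SomaticVariant],
    params: SignatureFilterParams,
    stats: Optional[Counter] = None,
) -> list[SomaticVariant]:
    """Drop variants below min_depth or inside any excluded region."""
    counters = stats if stats is not None else Counter()
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in params.excluded_regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    kept: list[SomaticVariant] = []
    for v in variants:
        if v.depth is None or v.depth < params.min_depth:
            if params.min_depth > 0:
                counters["dropped_low_depth"] += 1
                continue
        if any(iv.start <= v.pos < iv.end for iv in by_chrom.get(v.chrom, ())):
            counters["dropped_in_excluded_region"] += 1
            continue
        counters["variants_retained"] += 1
        kept.append(v)
    return kept


def _context_of(variant: SomaticVariant, reference: Optional[dict[str, str]]) -> Optional[str]:
    if variant.context3 is not None:
        return variant.context3
    if reference is None:
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos + 1} has no context3 and no "
            "reference was provided"
        )
    seq = reference.get(variant.chrom)
    if seq is None or not 1 <= variant.pos <= len(seq) - 2:
        return None
    ctx = seq[variant.pos - 1 : variant.pos + 2].upper()
    if ctx[1] != variant.ref_allele:
        raise ValueError(
            f"reference base {ctx[1]} at {variant.chrom}:{variant.pos + 1} "
            f"does not match variant ref {variant.ref_allele}"
        )
    return ctx


def classify_96(
    variant: SomaticVariant, reference: Optional[dict[str, str]] = None
) -> Optional[str]:
    """Class label X[R>A]Y on the pyrimidine strand.

    Purine-reference variants are reverse-complemented (ref, alt and
    context) before labelling. Returns None when the trinucleotide context
    contains N or lies at a contig edge.
    """
    ctx = _context_of(variant, reference)
    if ctx is None or "N" in ctx:
        return None
    ref, alt = variant.ref_allele, variant.alt_allele
    if ref not in PYRIMIDINES:
        ctx = revcomp(ctx)
        ref = revcomp(ref)
        alt = revcomp(alt)
    return f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"


def count_signature(
    variants: Iterable[SomaticVariant],
    reference: Optional[dict[str, str]] = None,
    stats: Optional[Counter] = None,
) -> SignatureCounts:
    """Tabulate classifiable variants over the 96 classes."""
    counters = stats if stats is not None else Counter()
    counts = {label: 0 for label in SBS96_CLASSES}
    for v in variants:
        label = classify_96(v, reference)
        if label is None:
            counters["unclassifiable_excluded"] += 1
            continue
        counts[label] += 1
    return SignatureCounts(counts)


def dipyrimidine_fraction(
    variants: Iterable[SomaticVariant],
    reference: Optional[dict[str, str]] = None,
) -> Optional[float]:
    """Fraction of classifiable variants whose pyrimidine-strand 5' or 3'
    neighbour is also a pyrimidine (C or T).

    Adjacent pyrimidines are the substrate of UV lesions (cyclobutane
    dimers), so this fraction is elevated in UV-driven, NER-deficient
    signatures. Returns None when no variant is classifiable.
    """
    n = 0
    hits = 0
    for v in variants:
        label = classify_96(v, reference)
        if label is None:
            continue
        n += 1
        if label[0] in PYRIMIDINES or label[-1] in PYRIMIDINES:
            hits += 1
    if n == 0:
        return None
    return hits / n


def write_signature_tsv(
    counts: SignatureCounts,
    path: str | Path,
    dipyrimidine: Optional[float] = None,
) -> None:
    """96-row TSV in canonical order, plus a trailing summary comment."""
    with open(path, "w") as out:
        out.write("class\tcount\n")
        for label in SBS96_CLASSES:
            out.write(f"{label}\t{counts.counts[label]}\n")
        dipy = "NA" if dipyrimidine is None else f"{dipyrimidine:.4f}"
        out.write(f"# total={counts.total}\tdipyrimidine_fraction={dipy}\n")
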