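"""Retrocopy detection from intron-spanning exome read pairs.

A fragment reverse-transcribed from a spliced mRNA and reintegrated into
the genome lacks introns. Its reads still map back to the exons of the
source gene, but the pair's reference-coordinate span (ostensible template
length) is inflated by every intron between the mates. The caller keeps
pairs with both mates at MAPQ >= 20 and a span >= 1000 bp, accumulates
read-end counts per exon, and reports a gene when at least three discrete
exons each carry at least two read ends. Genes incorporated in the
reference as intronless copies cannot be detected this way; they surface
as recurrent relics handled by the cohort module.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

from .core import (
    KNOWN_RETROCOPY,
    AlignedPairRecord,
    DetectionParams,
    GeneModel,
    RetroCandidate,
)
from .io import read_gene_models, read_known_genes, read_sam

log = logging.getLogger(__name__)


@dataclass
class ExonSupport:
    """Per-gene evidence accumulator: read-end counts per exon index and
    the pairs whose mates fall in two different exons (bridging pairs)."""

    symbol: str
    reads_per_exon: Counter = field(default_factory=Counter)
    bridging_pairs: list[tuple[str, int, int]] = field(default_factory=list)
    n_pairs: int = 0


def filter_pairs(
    pairs: Iterable[AlignedPairRecord],
    params: DetectionParams,
    stats: Optional[Counter] = None,
) -> Iterator[AlignedPairRecord]:
    """Keep pairs with both mates' MAPQ >= min_mapq and ostensible template
    length >= min_tlen (both boundaries inclusive)."""
    counters = stats if stats is not None else Counter()
    for pair in pairs:
        if pair.min_mapq < params.min_mapq:
            counters["dropped_low_mapq"] += 1
            continue
        if pair.ostensible_tlen < params.min_tlen:
            counters["dropped_short_tlen"] += 1
            continue
        counters["pairs_retained"] += 1
        yield pair


class GeneIndex:
    """Per-chromosome interval index over exons for overlap queries."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = list(genes)
        self.by_symbol = {g.symbol: g for g in self.genes}
        if len(self.by_symbol) != len(self.genes):
            raise ValueError("duplicate gene symbols in gene set")
        self._trees: dict[str, IntervalTree] = {}
        for gi, gene in enumerate(self.genes):
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            for ei, exon in enumerate(gene.exons):
                tree.addi(exon.start, exon.end, (gi, ei))

    def exon_hits(self, chrom: str, start: int, end: int) -> dict[int, list[int]]:
        """Map gene index -> exon indices overlapping [start, end)."""
        tree = self._trees.get(chrom)
        hits: dict[int, list[int]] = {}
        if tree is None:
            return hits
        for iv in tree.overlap(start, end):
            gi, ei = iv.data
            hits.setdefault(gi, []).append(ei)
        for eis in hits.values():
            eis.sort()
        return hits


def assign_to_genes(
    pairs: Iterable[AlignedPairRecord],
    genes: list[GeneModel] | GeneIndex,
    stats: Optional[Counter] = None,
) -> dict[str, ExonSupport]:
    """Accumulate exon support per gene.

    A pair contributes to a gene iff both mates overlap exons of that
    gene; each mate then increments the read-end count of every exon it
    overlaps. When the mates' (first-overlapped) exons differ the pair is
    recorded as bridging. A pair inside nested/overlapping genes credits
    every gene whose exons contain both mates; the ambiguity is counted.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    counters = stats if stats is not None else Counter()
    support: dict[str, ExonSupport] = {}
    for pair in pairs:
        h1 = index.exon_hits(pair.chrom, pair.mate1.start, pair.mate1.end)
        h2 = index.exon_hits(pair.chrom, pair.mate2.start, pair.mate2.end)
        shared = sorted(set(h1) & set(h2))
        if not shared:
            counters["pairs_outside_exons"] += 1
            continue
        if len(shared) > 1:
            counters["pairs_in_overlapping_genes"] += 1
        for gi in shared:
            gene = index.genes[gi]
            sup = support.setdefault(gene.symbol, ExonSupport(gene.symbol))
            sup.n_pairs += 1
            for ei in h1[gi]:
                sup.reads_per_exon[ei] += 1
            for ei in h2[gi]:
                sup.reads_per_exon[ei] += 1
            if h1[gi][0] != h2[gi][0]:
                sup.bridging_pairs.append((pair.fragment_id, h1[gi][0], h2[gi][0]))
    return support


def call_candidates(
    support: dict[str, ExonSupport],
    genes: list[GeneModel] | GeneIndex,
    params: DetectionParams,
    sample_id: str = "",
) -> list[RetroCandidate]:
    """Emit a candidate for every intron-bearing gene whose set of exons
    with read-end count >= min_reads_per_exon has size >= min_supported_exons.

    Output is sorted by descending supporting-pair count, then symbol.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    out: list[RetroCandidate] = []
    for symbol, sup in support.items():
        gene = index.by_symbol[symbol]
        if gene.n_exons < 2:
            continue
        supported = frozenset(
            ei for ei, c in sup.reads_per_exon.items() if c >= params.min_reads_per_exon
        )
        if len(supported) < params.min_supported_exons:
            continue
        out.append(
            RetroCandidate(
                sample_id=sample_id,
                gene=gene,
                supported_exons=supported,
                reads_per_exon=dict(sup.reads_per_exon),
                n_supporting_pairs=sup.n_pairs,
            )
        )
    out.sort(key=lambda c: (-c.n_supporting_pairs, c.symbol))
    return out


def annotate_known(
    candidates: list[RetroCandidate], known: set[str]
) -> list[RetroCandidate]:
    """Flag candidates whose symbol appears in a known-retrocopy list
    (e.g. UCSC retroposed genes, retrogeneDB). Nothing is removed."""
    if not known:
        log.warning("known-retrocopy list is empty; no candidates flagged")
        return candidates
    for cand in candidates:
        if cand.symbol in known:
            cand.flags.add(KNOWN_RETROCOPY)
    return candidates


CANDIDATE_TSV_COLUMNS = (
    "sample",
    "gene",
    "chrom",
    "n_supported_exons",
    "supported_exon_indices",
    "n_pairs",
    "flags",
)


def write_candidates_tsv(candidates: list[RetroCandidate], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(CANDIDATE_TSV_COLUMNS) + "\n")
        for c in candidates:
            exon_idx = ",".join(str(i) for i in sorted(c.supported_exons))
            flags = ",".join(sorted(c.flags)) if c.flags else "."
            out.write(
                f"{c.sample_id}\t{c.symbol}\t{c.chrom}\t{len(c.supported_exons)}\t"
                f"{exon_idx}\t{c.n_supporting_pairs}\t{flags}\n"
            )


def detect_sample(
    sam_path: str | Path,
    gene_model_path: str | Path,
    params: DetectionParams = DetectionParams(),
    dialect: str = "refflat",
    sample_id: Optional[str] = None,
    known_path: Optional[str | Path] = None,
    out_tsv: Optional[str | Path] = None,
) -> tuple[list[RetroCandidate], Counter]:
    """Full per-sample pipeline: read pairs, filter, assign, call, annotate.

    Returns the candidate list and a Counter of per-stage counts.
    """
    stats: Counter = Counter()
    genes = read_gene_models(gene_model_path, dialect=dialect)
    index = GeneIndex(genes)
    sample = sample_id if sample_id is not None else Path(sam_path).stem
    pairs = read_sam(sam_path, sample_id=sample, stats=stats)
    kept = filter_pairs(pairs, params, stats=stats)
    support = assign_to_genes(kept, index, stats=stats)
    candidates = call_candidates(support, index, params, sample_id=sample)
    if known_path is not None:
        candidates = annotate_known(candidates, read_known_genes(known_path))
    stats["candidates"] = len(candidates)
    log.info("%s: %s", sample, dict(stats))
    if out_tsv is not None:
        write_candidates_tsv(candidates, out_tsv)
    return candidates, stats
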