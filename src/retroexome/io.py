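"""Readers and writers for the standard formats.

SAM and VCF are 1-based on disk; every coordinate is converted to the
internal 0-based half-open convention here and only here.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam
from Bio import SeqIO

from .core import (
    AlignedPairRecord,
    GeneModel,
    GenomicInterval,
    MateAlignment,
    SomaticVariant,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# SAM


def read_sam(
    path: str | Path,
    sample_id: Optional[str] = None,
    stats: Optional[Counter] = None,
) -> Iterator[AlignedPairRecord]:
    """Stream mate-matched read pairs from a SAM/BAM file.

    Only primary alignments with both mates mapped to the same chromosome
    are paired and emitted. The ostensible template length is recomputed
    from the two mates' reference coordinates; the TLEN column is ignored.
    Unmatched mates remaining at EOF are dropped with a warning.
    """
    path = Path(path)
    sample = sample_id if sample_id is not None else path.stem
    counters = stats if stats is not None else Counter()
    pending: dict[str, pysam.AlignedSegment] = {}
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for aln in fh:
                counters["alignments_read"] += 1
                if aln.is_secondary or aln.is_supplementary:
                    counters["secondary_or_supplementary_skipped"] += 1
                    continue
                if aln.is_unmapped or aln.mate_is_unmapped:
                    counters["unmapped_skipped"] += 1
                    continue
                qname = aln.query_name
                other = pending.pop(qname, None)
                if other is None:
                    pending[qname] = aln
                    continue
                if aln.reference_name != other.reference_name:
                    counters["cross_chromosome_pairs_skipped"] += 1
                    continue
                left, right = sorted(
                    (other, aln), key=lambda a: (a.reference_start, a.reference_end)
                )
                rec = AlignedPairRecord(
                    sample_id=sample,
                    fragment_id=qname,
                    chrom=aln.reference_name,
                    mate1=MateAlignment(
                        left.reference_start, left.reference_end, left.mapping_quality
                    ),
                    mate2=MateAlignment(
                        right.reference_start, right.reference_end, right.mapping_quality
                    ),
                    proper_orientation=(not left.is_reverse) and right.is_reverse,
                )
                counters["pairs_emitted"] += 1
                yield rec
    except (ValueError, OSError) as exc:
        # htslib reports the offending line number on stderr
        raise ValueError(f"malformed SAM {path}: {exc}") from exc
    if pending:
        counters["unmatched_mates_dropped"] += len(pending)
        log.warning("%s: %d unmatched mates dropped at EOF", path, len(pending))


# ---------------------------------------------------------------------------
# Gene models (refFlat / BED12)


def _merge_intervals(chrom: str, strand: str, raw: list[tuple[int, int]]) -> tuple[GenomicInterval, ...]:
    raw = sorted(raw)
    merged: list[list[int]] = []
    for s, e in raw:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple(GenomicInterval(chrom, s, e, strand) for s, e in merged)


def read_gene_models(path: str | Path, dialect: str = "refflat") -> list[GeneModel]:
    """Read gene models, unioning exons over all isoforms of a symbol.

    ``dialect`` is ``refflat`` (UCSC refFlat: geneName first column) or
    ``bed12``. Both use 0-based half-open exon coordinates on disk already.
    """
    dialect = dialect.lower().replace("_", "")
    if dialect not in ("refflat", "bed12"):
        raise ValueError(f"unknown gene-model dialect {dialect!r}")
    per_gene: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                if dialect == "refflat":
                    symbol, chrom, strand = f[0], f[2], f[3]
                    n = int(f[8])
                    starts = [int(x) for x in f[9].rstrip(",").split(",") if x]
                    ends = [int(x) for x in f[10].rstrip(",").split(",") if x]
                else:
                    chrom, symbol, strand = f[0], f[3], f[5]
                    chrom_start = int(f[1])
                    n = int(f[9])
                    sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
                    offsets = [int(x) for x in f[11].rstrip(",").split(",") if x]
                    starts = [chrom_start + o for o in offsets]
                    ends = [s + z for s, z in zip(starts, sizes)]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed {dialect} line: {exc}") from exc
            if n == 0:
                raise ValueError(f"{path}:{lineno}: zero-exon record for {symbol}")
            if len(starts) != n or len(ends) != n:
                raise ValueError(
                    f"{path}:{lineno}: exon start/end count mismatch for {symbol}"
                )
            entry = per_gene.setdefault((symbol, chrom), {"strand": strand, "exons": []})
            entry["exons"].extend(zip(starts, ends))
    genes = [
        GeneModel(symbol, chrom, entry["strand"], _merge_intervals(chrom, entry["strand"], entry["exons"]))
        for (symbol, chrom), entry in per_gene.items()
    ]
    genes.sort(key=lambda g: (g.chrom, g.exons[0].start, g.symbol))
    return genes


def write_gene_models_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as out:
        for g in genes:
            start = g.exons[0].start
            end = g.exons[-1].end
            sizes = ",".join(str(e.length()) for e in g.exons) + ","
            offsets = ",".join(str(e.start - start) for e in g.exons) + ","
            strand = g.strand if g.strand in "+-" else "+"
            out.write(
                f"{g.chrom}\t{start}\t{end}\t{g.symbol}\t0\t{strand}\t{start}\t{end}\t0\t"
                f"{g.n_exons}\t{sizes}\t{offsets}\n"
            )


def write_gene_models_refflat(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as out:
        for g in genes:
            start = g.exons[0].start
            end = g.exons[-1].end
            starts = ",".join(str(e.start) for e in g.exons) + ","
            ends = ",".join(str(e.end) for e in g.exons) + ","
            strand = g.strand if g.strand in "+-" else "+"
            out.write(
                f"{g.symbol}\t{g.symbol}\t{g.chrom}\t{strand}\t{start}\t{end}\t{start}\t{end}\t"
                f"{g.n_exons}\t{starts}\t{ends}\n"
            )


# ---------------------------------------------------------------------------
# VCF


def read_vcf_snvs(
    path: str | Path, stats: Optional[Counter] = None
) -> list[SomaticVariant]:
    """Read biallelic single-nucleotide records from a VCF 4.x file.

    Indels and multi-allelic sites are skipped (counted in ``stats``).
    A missing DP leaves depth as None, which fails any positive depth
    filter downstream. Genotype is taken from the first sample column.
    """
    counters = stats if stats is not None else Counter()
    variants: list[SomaticVariant] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            counters["records_read"] += 1
            if rec.alts is None or len(rec.alts) != 1:
                counters["multiallelic_or_altless_skipped"] += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                counters["non_snv_skipped"] += 1
                continue
            depth: Optional[int] = None
            genotype = "het"
            if rec.samples:
                sample = rec.samples[0]
                gt = sample.get("GT")
                if gt is not None:
                    alleles = [a for a in gt if a is not None]
                    if alleles and all(a == 0 for a in alleles):
                        counters["hom_ref_skipped"] += 1
                        continue
                    genotype = "hom" if alleles and all(a == 1 for a in alleles) else "het"
                dp = sample.get("DP")
                if dp is not None:
                    depth = int(dp)
            if depth is None and "DP" in rec.info:
                depth = int(rec.info["DP"])
            variants.append(
                SomaticVariant(
                    chrom=rec.chrom,
                    pos=rec.start,  # pysam .start is already 0-based
                    ref_allele=ref,
                    alt_allele=alt,
                    depth=depth,
                    genotype=genotype,
                )
            )
            counters["snvs_kept"] += 1
    return variants


def write_vcf(
    variants: Iterable[SomaticVariant],
    path: str | Path,
    contigs: dict[str, int],
    sample_name: str = "SAMPLE",
) -> None:
    """Write SNVs as a minimal VCF 4.2 with GT and DP FORMAT fields."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            out.write(f"##contig=<ID={name},length={length}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        out.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_name}\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            gt = "1/1" if v.genotype == "hom" else "0/1"
            dp = "." if v.depth is None else str(v.depth)
            out.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t.\t"
                f"GT:DP\t{gt}:{dp}\n"
            )


# ---------------------------------------------------------------------------
# BED (exclusion regions, known-retrocopy loci) and FASTA


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read plain BED3+ intervals (0-based half-open, as BED is defined)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as out:
        for iv in intervals:
            out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_known_genes(path: str | Path) -> set[str]:
    """Read a known-retrocopy list: gene symbols, one per line, or BED with
    the symbol in column 4."""
    symbols: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            symbols.add(f[3] if len(f) >= 4 else f[0])
    return symbols


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
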