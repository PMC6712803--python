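"""Synthetic exome data with the statistical structure the analysis assumes.

Generates a random reference with intron-bearing gene models, paired-end
exome reads with and without retrocopy evidence, parent/iPSC VCF pairs
whose somatic SNVs follow a chosen 96-class profile, and read sets for
cis/trans phasing — all deterministic for a fixed seed, with ground truth
recorded for every planted event.

The retrocopy evidence model: fragments are sampled along the gene's
cDNA (the spliced transcript) and their reads written as mapped to the
source locus, the way a DNA aligner places retrocopy-derived reads. A
mate crossing an exon junction is soft-clipped to the block containing
its outer end, so the pair's reference span equals the fragment length
plus the introns lying strictly between the mates — the ostensible
template length identity that detection exploits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from .core import AlignedPairRecord, GeneModel, GenomicInterval, MateAlignment
from .io import write_bed, write_fasta, write_gene_models_refflat, write_vcf
from .core import SomaticVariant
from .signatures import SBS96_CLASSES, revcomp

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the study conditions: 101-bp paired-end exome reads,
    ~300 +/- 50 bp inserts, 100x exonic coverage, and introns long enough
    (>= 1200 bp) that intron removal pushes bridging pairs past the
    1000-bp template-length threshold. ``retrocopy_fraction`` models
    clonality: 1.0 for an iPSC line (clonal), small for a parental bulk.
    """

    seed: int = 0
    chrom: str = "chrS"
    n_genes: int = 20
    exon_count_range: tuple[int, int] = (2, 8)
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (1200, 3000)
    intergenic_gap_range: tuple[int, int] = (500, 2000)
    read_length: int = 101
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    exonic_coverage: float = 100.0
    retrocopy_genes: tuple[str, ...] = ()
    retrocopy_fraction: float = 1.0
    error_rate: float = 0.0
    n_snvs: int = 0
    n_germline: int = 50
    signature_profile: Optional[dict[str, float]] = None
    depth_mean: float = 30.0
    min_depth_boundary: int = 8
    frac_low_depth: float = 0.1
    frac_hom: float = 0.05
    n_excluded_regions: int = 2
    frac_in_excluded: float = 0.05

    def __post_init__(self) -> None:
        for name in ("exon_count_range", "exon_length_range", "intron_length_range",
                     "intergenic_gap_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        if not 0.0 <= self.retrocopy_fraction <= 1.0:
            raise ValueError("retrocopy_fraction must be in [0, 1]")
        if self.read_length <= 0 or self.insert_mean <= 0 or self.insert_sd < 0:
            raise ValueError("read/insert parameters must be positive")
        if self.signature_profile is not None:
            total = sum(self.signature_profile.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"signature_profile sums to {total}, not 1")


@dataclass
class TruthRecord:
    """Ground truth for one planted event."""

    event: str  # "retrocopy" or "snv"
    locus: str  # gene symbol or chrom:pos
    haplotype: str = "."
    params: dict = field(default_factory=dict)


@dataclass
class Genome:
    sequences: dict[str, str]
    genes: list[GeneModel]

    def gene(self, symbol: str) -> GeneModel:
        return next(g for g in self.genes if g.symbol == symbol)


def make_genome(config: SimulationConfig) -> Genome:
    """Random reference with non-overlapping genes laid out left to right.

    Deterministic for a fixed config (byte-identical FASTA on rewrite).
    """
    rng = np.random.default_rng(config.seed)
    cursor = int(rng.integers(*_hi(config.intergenic_gap_range)))
    genes: list[GeneModel] = []
    width = max(3, len(str(config.n_genes)))
    for i in range(config.n_genes):
        n_exons = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
        exons: list[GenomicInterval] = []
        pos = cursor
        for e in range(n_exons):
            ex_len = int(rng.integers(*_hi(config.exon_length_range)))
            exons.append(GenomicInterval(config.chrom, pos, pos + ex_len, "+"))
            pos += ex_len
            if e < n_exons - 1:
                pos += int(rng.integers(*_hi(config.intron_length_range)))
        genes.append(GeneModel(f"G{i + 1:0{width}d}", config.chrom, "+", tuple(exons)))
        cursor = pos + int(rng.integers(*_hi(config.intergenic_gap_range)))
    chrom_len = cursor + int(rng.integers(*_hi(config.intergenic_gap_range)))
    seq = "".join(rng.choice(_BASES, size=chrom_len))
    return Genome(sequences={config.chrom: seq}, genes=genes)


def _hi(rng_pair: tuple[int, int]) -> tuple[int, int]:
    return rng_pair[0], rng_pair[1] + 1


# ---------------------------------------------------------------------------
# cDNA <-> genome coordinate mapping


def map_cdna_to_genome(gene: GeneModel, cdna_interval: tuple[int, int]) -> list[GenomicInterval]:
    """Genomic footprint of a cDNA interval via cumulative exon offsets.

    A cDNA interval crossing an exon junction maps to >= 2 genomic blocks.
    """
    start, end = cdna_interval
    if not 0 <= start < end <= gene.cdna_length:
        raise ValueError(
            f"cDNA interval [{start}, {end}) outside [0, {gene.cdna_length})"
        )
    blocks: list[GenomicInterval] = []
    offset = 0
    for exon in gene.exons:
        ex_len = exon.length()
        lo = max(start, offset)
        hi = min(end, offset + ex_len)
        if lo < hi:
            blocks.append(
                GenomicInterval(
                    gene.chrom, exon.start + (lo - offset), exon.start + (hi - offset), gene.strand
                )
            )
        offset += ex_len
    return blocks


def cdna_exon_index(gene: GeneModel, cdna_pos: int) -> int:
    """Index of the exon containing a cDNA position."""
    offset = 0
    for i, exon in enumerate(gene.exons):
        offset += exon.length()
        if cdna_pos < offset:
            return i
    raise ValueError(f"cDNA position {cdna_pos} outside [0, {gene.cdna_length})")


def cdna_sequence(gene: GeneModel, sequences: dict[str, str]) -> str:
    seq = sequences[gene.chrom]
    return "".join(seq[e.start : e.end] for e in gene.exons)


def intervening_intron_length(gene: GeneModel, cdna_start: int, cdna_end: int) -> int:
    """Summed lengths of introns strictly between the exons holding the
    first and last base of a cDNA fragment [cdna_start, cdna_end)."""
    e1 = cdna_exon_index(gene, cdna_start)
    e2 = cdna_exon_index(gene, cdna_end - 1)
    return sum(iv.length() for iv in gene.introns[e1:e2])


# ---------------------------------------------------------------------------
# Read-pair simulation


@dataclass(frozen=True)
class SimRead:
    qname: str
    flag: int
    chrom: str
    pos: int  # 0-based leftmost aligned
    mapq: int
    cigar: str
    seq: str
    mate_pos: int
    tlen: int


@dataclass(frozen=True)
class SimulatedPair:
    record: AlignedPairRecord
    reads: tuple[SimRead, SimRead]
    gene_symbol: Optional[str]
    cdna_start: int  # -1 for background (genomic) pairs
    cdna_end: int
    fragment_length: int


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def simulate_retrocopy_pairs(
    genome: Genome,
    gene: GeneModel,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "sim",
    qname_prefix: str = "retro",
) -> list[SimulatedPair]:
    """Read pairs from an intronless retrocopy of ``gene``.

    Fragments ~ Normal(insert_mean, insert_sd) sampled along the cDNA;
    junction-crossing mates are soft-clipped to their outer block, so
    ostensible_tlen == fragment length + introns strictly between the
    mates' footprints, by construction.
    """
    if gene.n_exons < 2:
        raise ValueError(f"retrocopy of single-exon gene {gene.symbol} is undetectable")
    cdna = cdna_sequence(gene, genome.sequences)
    clen = len(cdna)
    r = config.read_length
    if clen < r:
        raise ValueError(f"cDNA of {gene.symbol} shorter than a read")
    n_pairs = max(
        1,
        int(round(config.exonic_coverage * config.retrocopy_fraction * clen / (2 * r))),
    )
    out: list[SimulatedPair] = []
    for i in range(n_pairs):
        L = 0
        for _ in range(100):
            L = int(round(rng.normal(config.insert_mean, config.insert_sd)))
            if r <= L <= clen:
                break
        else:
            L = min(max(L, r), clen)
        a = int(rng.integers(0, clen - L + 1))
        b = a + L
        blocks1 = map_cdna_to_genome(gene, (a, a + r))
        blocks2 = map_cdna_to_genome(gene, (b - r, b))
        keep1, keep2 = blocks1[0], blocks2[-1]  # outer-end anchored blocks
        m1, s1 = keep1.length(), r - keep1.length()
        m2, s2 = keep2.length(), r - keep2.length()
        cigar1 = f"{m1}M{s1}S" if s1 else f"{r}M"
        cigar2 = f"{s2}S{m2}M" if s2 else f"{r}M"
        seq1 = _apply_errors(cdna[a : a + r], config.error_rate, rng)
        seq2 = _apply_errors(cdna[b - r : b], config.error_rate, rng)
        qname = f"{qname_prefix}:{gene.symbol}:{i}"
        tlen = keep2.end - keep1.start
        reads = (
            SimRead(qname, 99, gene.chrom, keep1.start, 60, cigar1, seq1, keep2.start, tlen),
            SimRead(qname, 147, gene.chrom, keep2.start, 60, cigar2, seq2, keep1.start, -tlen),
        )
        record = AlignedPairRecord(
            sample_id=sample_id,
            fragment_id=qname,
            chrom=gene.chrom,
            mate1=MateAlignment(keep1.start, keep1.end, 60),
            mate2=MateAlignment(keep2.start, keep2.end, 60),
        )
        out.append(SimulatedPair(record, reads, gene.symbol, a, b, L))
    return out


def simulate_background_pairs(
    genome: Genome,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "sim",
    genes: Optional[Sequence[GeneModel]] = None,
) -> list[SimulatedPair]:
    """Concordant exome pairs: contiguous genomic fragments overlapping
    exons, no intron removal, so ostensible_tlen follows the insert
    distribution (a 14-sigma tail away from the 1000-bp threshold)."""
    genes = list(genes) if genes is not None else genome.genes
    r = config.read_length
    out: list[SimulatedPair] = []
    for gene in genes:
        seq = genome.sequences[gene.chrom]
        exon_lens = np.array([e.length() for e in gene.exons], dtype=float)
        n_frags = int(round(config.exonic_coverage * exon_lens.sum() / (2 * r)))
        for i in range(n_frags):
            ei = int(rng.choice(len(exon_lens), p=exon_lens / exon_lens.sum()))
            exon = gene.exons[ei]
            center = int(rng.integers(exon.start, exon.end))
            L = max(r, int(round(rng.normal(config.insert_mean, config.insert_sd))))
            start = min(max(center - L // 2, 0), len(seq) - L)
            qname = f"bg:{gene.symbol}:{i}"
            seq1 = _apply_errors(seq[start : start + r], config.error_rate, rng)
            seq2 = _apply_errors(seq[start + L - r : start + L], config.error_rate, rng)
            reads = (
                SimRead(qname, 99, gene.chrom, start, 60, f"{r}M", seq1, start + L - r, L),
                SimRead(qname, 147, gene.chrom, start + L - r, 60, f"{r}M", seq2, start, -L),
            )
            record = AlignedPairRecord(
                sample_id=sample_id,
                fragment_id=qname,
                chrom=gene.chrom,
                mate1=MateAlignment(start, start + r, 60),
                mate2=MateAlignment(start + L - r, start + L, 60),
            )
            out.append(SimulatedPair(record, reads, None, -1, -1, L))
    return out


def write_sam(
    reads: Sequence[SimRead], sequences: dict[str, str], path: str | Path
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in sequences.items()],
    }
    ref_ids = {name: i for i, name in enumerate(sequences)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.qname
            a.flag = read.flag
            a.reference_id = ref_ids[read.chrom]
            a.reference_start = read.pos
            a.mapping_quality = read.mapq
            a.cigarstring = read.cigar
            a.query_sequence = read.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
            a.next_reference_id = ref_ids[read.chrom]
            a.next_reference_start = read.mate_pos
            a.template_length = read.tlen
            out.write(a)


def simulate_sample(
    genome: Genome,
    config: SimulationConfig,
    sample_id: str,
    out_sam: str | Path,
    sample_seed: Optional[int] = None,
) -> tuple[list[SimulatedPair], list[TruthRecord]]:
    """One sample's SAM: background over every gene plus retrocopy pairs
    for config.retrocopy_genes. Returns the pairs and the truth log."""
    rng = np.random.default_rng(config.seed if sample_seed is None else sample_seed)
    pairs = simulate_background_pairs(genome, config, rng, sample_id=sample_id)
    truth: list[TruthRecord] = []
    for symbol in config.retrocopy_genes:
        gene = genome.gene(symbol)
        retro = simulate_retrocopy_pairs(genome, gene, config, rng, sample_id=sample_id)
        pairs.extend(retro)
        truth.append(
            TruthRecord(
                "retrocopy",
                symbol,
                params={
                    "n_pairs": len(retro),
                    "n_exons": gene.n_exons,
                    "fraction": config.retrocopy_fraction,
                },
            )
        )
    reads = [read for p in pairs for read in p.reads]
    write_sam(reads, genome.sequences, out_sam)
    return pairs, truth


# ---------------------------------------------------------------------------
# Parent/iPSC variant pairs with a planted 96-class profile


def _context_index(seq: str) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for p in range(1, len(seq) - 1):
        idx.setdefault(seq[p - 1 : p + 2], []).append(p)
    return idx


def _class_parts(label: str) -> tuple[str, str, str]:
    """(pyrimidine context, ref, alt) of a class label X[R>A]Y."""
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return five + ref + three, ref, alt


def simulate_variant_pair(
    genome: Genome,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SomaticVariant], list[SomaticVariant], list[TruthRecord], list[GenomicInterval]]:
    """Parent and iPSC call sets sharing germline variants, with n_snvs
    somatic SNVs in the iPSC drawn from ``signature_profile``.

    Classes are realized on either strand with equal probability at sites
    whose reference trinucleotide matches. Depths straddle the depth
    filter boundary and a few somatic variants fall inside generated
    structural-exclusion regions, so every downstream filter is
    exercised. Returns (parent, ipsc, truth, excluded_regions).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    profile = config.signature_profile
    if profile is None:
        profile = {c: 1.0 / 96 for c in SBS96_CLASSES}
    labels = list(profile)
    probs = np.array([profile[c] for c in labels])
    probs = probs / probs.sum()
    chrom = config.chrom
    seq = genome.sequences[chrom]
    ctx_index = _context_index(seq)
    used: set[int] = set()

    germline: list[SomaticVariant] = []
    while len(germline) < config.n_germline:
        p = int(rng.integers(1, len(seq) - 1))
        if p in used:
            continue
        used.add(p)
        ref = seq[p]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        depth = max(1, int(rng.poisson(config.depth_mean)))
        germline.append(
            SomaticVariant(chrom, p, ref, alt, depth=depth, genotype="het",
                           context3=seq[p - 1 : p + 2])
        )

    somatic: list[SomaticVariant] = []
    classes_drawn: list[str] = []
    redraws = 0
    while len(somatic) < config.n_snvs:
        label = labels[int(rng.choice(len(labels), p=probs))]
        ctx, ref, alt = _class_parts(label)
        strand = "+" if rng.random() < 0.5 else "-"
        want = ctx if strand == "+" else revcomp(ctx)
        sites = ctx_index.get(want, [])
        if not sites:
            strand = "-" if strand == "+" else "+"
            want = ctx if strand == "+" else revcomp(ctx)
            sites = ctx_index.get(want, [])
        if not sites:
            redraws += 1
            if redraws > 100 * max(config.n_snvs, 1):
                raise RuntimeError("no sites available for the drawn contexts")
            continue
        p = int(sites[int(rng.integers(len(sites)))])
        if p in used:
            redraws += 1
            continue
        used.add(p)
        v_ref = ref if strand == "+" else revcomp(ref)
        v_alt = alt if strand == "+" else revcomp(alt)
        if rng.random() < config.frac_low_depth:
            depth = int(rng.integers(1, max(config.min_depth_boundary, 2)))
        else:
            depth = max(config.min_depth_boundary, int(rng.poisson(config.depth_mean)))
        genotype = "hom" if rng.random() < config.frac_hom else "het"
        somatic.append(
            SomaticVariant(chrom, p, v_ref, v_alt, depth=depth, genotype=genotype,
                           context3=seq[p - 1 : p + 2])
        )
        classes_drawn.append(label)

    # structural-exclusion regions: some drawn around planted variants so
    # the region filter has work to do, the rest at random positions
    excluded: list[GenomicInterval] = []
    n_inside = min(
        int(round(config.frac_in_excluded * len(somatic))), config.n_excluded_regions
    )
    for v in somatic[:n_inside]:
        half = int(rng.integers(200, 800))
        excluded.append(
            GenomicInterval(chrom, max(0, v.pos - half), min(len(seq), v.pos + half))
        )
    while len(excluded) < config.n_excluded_regions:
        s = int(rng.integers(0, max(1, len(seq) - 2000)))
        excluded.append(GenomicInterval(chrom, s, s + int(rng.integers(500, 2000))))

    truth: list[TruthRecord] = []
    for v, label in zip(somatic, classes_drawn):
        in_excluded = any(iv.start <= v.pos < iv.end for iv in excluded)
        passes = (v.depth is not None and v.depth >= config.min_depth_boundary
                  and not in_excluded)
        truth.append(
            TruthRecord(
                "snv",
                f"{chrom}:{v.pos + 1}",
                params={"class": label, "depth": v.depth, "expected_pass": passes,
                        "in_excluded": in_excluded},
            )
        )
    ipsc = germline + somatic
    return list(germline), ipsc, truth, excluded


# ---------------------------------------------------------------------------
# Phasing read sets


def simulate_phasing_reads(
    var_a,
    var_b,
    configuration: str,
    coverage: int,
    error_rate: float,
    seed: int,
    out_sam: str | Path,
    reference: Optional[dict[str, str]] = None,
    read_length: int = 101,
) -> dict[str, str]:
    """Paired reads from two haplotypes phased ``cis`` or ``trans``.

    trans: haplotype 1 carries variant A's alternate allele, haplotype 2
    carries B's. cis: haplotype 1 carries both, haplotype 2 neither.
    Every fragment is placed so that one mate covers locus A and the
    other covers locus B, so ``coverage`` fragments (split evenly across
    haplotypes) are all informative. Returns the reference used.
    """
    if configuration not in ("cis", "trans"):
        raise ValueError("configuration must be 'cis' or 'trans'")
    if var_a.chrom != var_b.chrom:
        raise ValueError("variants must share a chromosome")
    va, vb = sorted((var_a, var_b), key=lambda v: v.start)
    rng = np.random.default_rng(seed)
    chrom = var_a.chrom
    margin = 400
    if reference is None:
        # random sequence only around the variants; constant-base padding
        # keeps far-away coordinates cheap
        length = vb.end + margin + 200
        pad = max(0, va.start - margin)
        seq = "A" * pad + "".join(rng.choice(_BASES, size=length - pad))
        if va.kind == "snv" and va.ref:
            seq = seq[: va.start] + va.ref + seq[va.start + 1 :]
        if vb.kind == "snv" and vb.ref:
            seq = seq[: vb.start] + vb.ref + seq[vb.start + 1 :]
        reference = {chrom: seq}
    seq = reference[chrom]
    window = vb.end - va.start
    max_span = 2 * read_length + 200
    if window > max_span:
        raise ValueError(
            f"variants span {window} bp, beyond the {max_span} bp a fragment can cover"
        )

    def haplotype(with_a: bool, with_b: bool) -> tuple[str, list[tuple[int, int, int]]]:
        """Haplotype sequence and deletion list [(hap_pos, ref_pos, del_len)]."""
        s = seq
        dels: list[tuple[int, int, int]] = []
        for v, carry in sorted(
            ((va, with_a), (vb, with_b)), key=lambda t: -t[0].start
        ):
            if not carry:
                continue
            if v.kind == "snv":
                s = s[: v.start] + v.alt + s[v.start + 1 :]
            else:
                s = s[: v.start] + s[v.end :]
                dels.append((v.start, v.start, v.end - v.start))
        # haplotype position of each deletion accounts for upstream ones
        dels.sort(key=lambda t: t[1])
        shift = 0
        adjusted = []
        for _, rp, d in dels:
            adjusted.append((rp - shift, rp, d))
            shift += d
        return s, adjusted

    if configuration == "trans":
        haps = [haplotype(True, False), haplotype(False, True)]
    else:
        haps = [haplotype(True, True), haplotype(False, False)]

    def start_window(v, hap_dels, hap_len: int) -> tuple[int, int]:
        """Haplotype start positions from which one read observes variant v."""
        carried = any(rp == v.start for _, rp, _ in hap_dels) if v.kind == "del" else None
        if v.kind == "snv":
            hp = _hap_coord(hap_dels, v.start)
            lo, hi = hp - read_length + 1, hp
        elif carried:
            hp = _hap_coord(hap_dels, v.start)  # deletion point; anchor both sides
            lo, hi = hp - read_length + 1, hp - 1
        else:
            lo, hi = v.end + 1 - read_length, v.start - 1  # align across, no gap
        return max(0, lo), min(hi, hap_len - read_length)

    reads: list[SimRead] = []
    for i in range(coverage):
        hap_seq, hap_dels = haps[i % 2]
        wa = start_window(va, hap_dels, len(hap_seq))
        wb = start_window(vb, hap_dels, len(hap_seq))
        if wa[1] < wa[0] or wb[1] < wb[0]:
            raise ValueError("variant not observable within one read length")
        sa = int(rng.integers(wa[0], wa[1] + 1))
        sb = int(rng.integers(wb[0], wb[1] + 1))
        s1, s2 = min(sa, sb), max(sa, sb)
        qname = f"ph:{configuration}:{i}"
        tlen = s2 - s1 + read_length
        for mate_i, s in enumerate((s1, s2)):
            rseq = _apply_errors(hap_seq[s : s + read_length], error_rate, rng)
            cigar, ref_start = _cigar_for(hap_dels, s, read_length)
            mate_start = _cigar_for(hap_dels, s2 if mate_i == 0 else s1, read_length)[1]
            flag = 99 if mate_i == 0 else 147
            reads.append(
                SimRead(qname, flag, chrom, ref_start, 60, cigar, rseq,
                        mate_start, tlen if mate_i == 0 else -tlen)
            )
    write_sam(reads, reference, out_sam)
    return reference


def _hap_coord(hap_dels, ref_pos: int) -> int:
    """Haplotype coordinate of a reference position at or after all dels."""
    shift = sum(d for hp, rp, d in hap_dels if rp < ref_pos)
    return ref_pos - shift


def _cigar_for(hap_dels, hap_start: int, read_length: int) -> tuple[str, int]:
    """CIGAR and reference start of a read at a haplotype interval."""
    shift = sum(d for hp, _, d in hap_dels if hp <= hap_start)
    ref_start = hap_start + shift
    inner = [
        (hp, d) for hp, _, d in hap_dels if hap_start < hp < hap_start + read_length
    ]
    if not inner:
        return f"{read_length}M", ref_start
    parts = []
    cur = hap_start
    for hp, d in sorted(inner):
        parts.append(f"{hp - cur}M{d}D")
        cur = hp
    parts.append(f"{hap_start + read_length - cur}M")
    return "".join(parts), ref_start


# ---------------------------------------------------------------------------
# Cohort-level convenience


@dataclass(frozen=True)
class SamplePlan:
    sample_id: str
    cell_type: str  # "parental" or "iPSC"
    donor_id: str
    spiked_genes: tuple[str, ...] = ()
    retrocopy_fraction: float = 1.0


def simulate_cohort(
    genome: Genome,
    config: SimulationConfig,
    plan: Sequence[SamplePlan],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write one SAM per planned sample plus a pairs.tsv metadata table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for k, sp in enumerate(plan):
        cfg = replace(
            config,
            retrocopy_genes=sp.spiked_genes,
            retrocopy_fraction=sp.retrocopy_fraction,
        )
        sam_path = out_dir / f"{sp.sample_id}.sam"
        simulate_sample(
            genome, cfg, sp.sample_id, sam_path, sample_seed=config.seed + 1000 + k
        )
        paths[sp.sample_id] = sam_path
    with open(out_dir / "pairs.tsv", "w") as fh:
        fh.write("sample_id\tdonor_id\tcell_type\n")
        for sp in plan:
            fh.write(f"{sp.sample_id}\t{sp.donor_id}\t{sp.cell_type}\n")
    paths["pairs"] = out_dir / "pairs.tsv"
    return paths


def write_simulation_outputs(genome: Genome, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "reference.fa"
    refflat = out_dir / "genes.refflat"
    write_fasta(genome.sequences, fasta)
    write_gene_models_refflat(genome.genes, refflat)
    return {"fasta": fasta, "refflat": refflat}
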