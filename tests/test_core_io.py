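"""Domain types, coordinate conventions, and format readers/writers."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retroexome.core import (
    AlignedPairRecord,
    GeneModel,
    GenomicInterval,
    MateAlignment,
    SomaticVariant,
)
from retroexome.io import (
    read_gene_models,
    read_sam,
    read_vcf_snvs,
    write_gene_models_bed12,
    write_vcf,
)
from conftest import make_pair


class TestGenomicInterval:
    def test_length_is_end_minus_start(self):
        assert GenomicInterval("chr1", 10, 25).length() == 15

    @pytest.mark.parametrize("start,end", [(5, 5), (10, 3), (-1, 4)])
    def test_degenerate_intervals_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_overlap_requires_same_chromosome(self):
        a = GenomicInterval("chr1", 0, 10)
        assert a.overlaps(GenomicInterval("chr1", 9, 20))
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))
        assert not a.overlaps(GenomicInterval("chr2", 0, 10))


class TestGeneModel:
    def test_introns_are_gaps_between_exons(self, three_exon_gene):
        introns = three_exon_gene.introns
        assert [(i.start, i.end) for i in introns] == [(1200, 1500), (1700, 2000)]
        assert three_exon_gene.cdna_length == 600

    def test_single_exon_gene_has_no_introns(self):
        g = GeneModel("X", "chr1", "+", (GenomicInterval("chr1", 0, 100),))
        assert g.introns == ()

    def test_n_exons_matches_n_introns_plus_one(self, small_genome):
        for g in small_genome.genes:
            assert len(g.introns) == g.n_exons - 1

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            GeneModel(
                "X", "chr1", "+",
                (GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)),
            )


class TestAlignedPairRecord:
    def test_tlen_is_reference_span(self):
        pair = make_pair((1050, 1150), (1550, 1650))
        assert pair.ostensible_tlen == 600

    @given(
        s1=st.integers(0, 10_000),
        l1=st.integers(1, 300),
        gap=st.integers(-200, 5000),
        l2=st.integers(1, 300),
    )
    @settings(max_examples=200, deadline=None)
    def test_tlen_at_least_each_mate_length(self, s1, l1, gap, l2):
        s2 = max(0, s1 + gap)
        pair = make_pair((s1, s1 + l1), (s2, s2 + l2))
        assert pair.ostensible_tlen >= max(l1, l2)


REFFLAT_TWO_ISOFORMS = (
    "GENE1\tNM_1\tchr1\t+\t100\t400\t100\t400\t2\t100,300,\t200,400,\n"
    "GENE1\tNM_2\tchr1\t+\t100\t400\t100\t400\t2\t100,300,\t250,400,\n"
    "SOLO\tNM_3\tchr2\t-\t10\t90\t10\t90\t1\t10,\t90,\n"
)


class TestGeneModelReaders:
    def test_isoform_exons_are_unioned(self, tmp_path):
        p = tmp_path / "genes.refflat"
        p.write_text(REFFLAT_TWO_ISOFORMS)
        genes = {g.symbol: g for g in read_gene_models(p, "refflat")}
        exons = [(e.start, e.end) for e in genes["GENE1"].exons]
        assert exons == [(100, 250), (300, 400)]
        assert genes["SOLO"].introns == ()

    def test_bed12_block_count(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text(
            "chr1\t1000\t2200\tG\t0\t+\t1000\t2200\t0\t3\t200,200,200,\t0,500,1000,\n"
        )
        (g,) = read_gene_models(p, "bed12")
        assert g.n_exons == 3 and len(g.introns) == 2
        assert [(e.start, e.end) for e in g.exons] == [
            (1000, 1200), (1500, 1700), (2000, 2200)
        ]

    def test_exon_count_mismatch_is_error(self, tmp_path):
        p = tmp_path / "bad.refflat"
        p.write_text("G\tNM\tchr1\t+\t0\t100\t0\t100\t2\t0,\t100,\n")
        with pytest.raises(ValueError, match="mismatch"):
            read_gene_models(p, "refflat")

    def test_zero_exon_record_is_error(self, tmp_path):
        p = tmp_path / "bad.refflat"
        p.write_text("G\tNM\tchr1\t+\t0\t100\t0\t100\t0\t,\t,\n")
        with pytest.raises(ValueError, match="zero-exon"):
            read_gene_models(p, "refflat")

    def test_bed12_round_trip_preserves_exons(self, tmp_path, small_genome):
        p = tmp_path / "rt.bed"
        write_gene_models_bed12(small_genome.genes, p)
        back = read_gene_models(p, "bed12")
        orig = sorted(small_genome.genes, key=lambda g: (g.chrom, g.exons[0].start))
        assert [(g.symbol, [(e.start, e.end) for e in g.exons]) for g in back] == [
            (g.symbol, [(e.start, e.end) for e in g.exons]) for g in orig
        ]


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:10000\n@SQ\tSN:chr2\tLN:10000\n"


def _sam_pair(qname, chrom, p1, p2, mapq=60, tlen_column=0, chrom2=None):
    chrom2 = chrom2 or chrom
    r1 = (f"{qname}\t99\t{chrom}\t{p1}\t{mapq}\t100M\t{'=' if chrom2 == chrom else chrom2}"
          f"\t{p2}\t{tlen_column}\t{'A' * 100}\t{'I' * 100}\n")
    r2 = (f"{qname}\t147\t{chrom2}\t{p2}\t{mapq}\t100M\t{'=' if chrom2 == chrom else chrom}"
          f"\t{p1}\t{-tlen_column}\t{'A' * 100}\t{'I' * 100}\n")
    return r1 + r2


class TestReadSam:
    def test_clean_pairs_all_emitted(self, tmp_path):
        sam = SAM_HEADER + "".join(
            _sam_pair(f"q{i}", "chr1", 101 + i, 501 + i) for i in range(10)
        )
        p = tmp_path / "ten.sam"
        p.write_text(sam)
        records = list(read_sam(p))
        assert len(records) == 10

    def test_tlen_recomputed_not_copied(self, tmp_path):
        # SAM POS is 1-based: POS 1051 with 100M spans [1050, 1150) internally
        p = tmp_path / "one.sam"
        p.write_text(SAM_HEADER + _sam_pair("q", "chr1", 1051, 1551, tlen_column=9999))
        (rec,) = list(read_sam(p))
        assert rec.mate1.start == 1050 and rec.mate2.end == 1650
        assert rec.ostensible_tlen == 600

    def test_cross_chromosome_pairs_excluded(self, tmp_path):
        p = tmp_path / "cross.sam"
        p.write_text(
            SAM_HEADER
            + _sam_pair("good", "chr1", 101, 501)
            + _sam_pair("cross", "chr1", 101, 501, chrom2="chr2")
        )
        records = list(read_sam(p))
        assert [r.fragment_id for r in records] == ["good"]

    def test_unmatched_mate_dropped_with_count(self, tmp_path):
        from collections import Counter

        p = tmp_path / "orphan.sam"
        lines = _sam_pair("q0", "chr1", 101, 501).splitlines(keepends=True)
        p.write_text(SAM_HEADER + lines[0])  # only mate1
        stats = Counter()
        assert list(read_sam(p, stats=stats)) == []
        assert stats["unmatched_mates_dropped"] == 1

    def test_malformed_sam_raises_with_filename(self, tmp_path):
        p = tmp_path / "bad.sam"
        p.write_text(SAM_HEADER + "not a sam line\n")
        with pytest.raises(ValueError, match="bad.sam"):
            list(read_sam(p))


VCF_BODY = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chr1\t100\t.\tC\tT\t.\tPASS\t.\tGT:DP\t0/1:30
chr1\t200\t.\tCA\tC\t.\tPASS\t.\tGT:DP\t0/1:30
chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT:DP\t1/1:25
chr1\t400\t.\tA\tG\t.\tPASS\t.\tGT\t0/1
"""


class TestReadVcf:
    def test_snv_field_mapping_and_indel_skip(self, tmp_path):
        from collections import Counter

        p = tmp_path / "v.vcf"
        p.write_text(VCF_BODY)
        stats = Counter()
        variants = read_vcf_snvs(p, stats=stats)
        assert len(variants) == 3
        het = variants[0]
        assert (het.chrom, het.pos, het.ref_allele, het.alt_allele) == ("chr1", 99, "C", "T")
        assert het.depth == 30 and het.genotype == "het"
        assert stats["non_snv_skipped"] == 1

    def test_homozygous_call_retained(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(VCF_BODY)
        hom = [v for v in read_vcf_snvs(p) if v.genotype == "hom"]
        assert len(hom) == 1 and hom[0].pos == 299

    def test_missing_dp_leaves_depth_unknown(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(VCF_BODY)
        nodp = [v for v in read_vcf_snvs(p) if v.pos == 399]
        assert nodp and nodp[0].depth is None

    def test_write_read_round_trip(self, tmp_path):
        variants = [
            SomaticVariant("chr1", 41, "C", "T", depth=12, genotype="het"),
            SomaticVariant("chr1", 99, "G", "A", depth=30, genotype="hom"),
        ]
        p = tmp_path / "rt.vcf"
        write_vcf(variants, p, contigs={"chr1": 1000})
        back = read_vcf_snvs(p)
        assert [(v.chrom, v.pos, v.ref_allele, v.alt_allele, v.depth, v.genotype)
                for v in back] == [
            (v.chrom, v.pos, v.ref_allele, v.alt_allele, v.depth, v.genotype)
            for v in variants
        ]
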