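"""Retrocopy detection: pair filtering, exon assignment, candidate calling."""

import itertools

import pytest

from retroexome.core import DetectionParams, GeneModel, GenomicInterval
from retroexome.detect import (
    GeneIndex,
    annotate_known,
    assign_to_genes,
    call_candidates,
    detect_sample,
    filter_pairs,
)
from retroexome.io import write_gene_models_refflat
from retroexome.simulate import SimulationConfig, make_genome, simulate_sample
from conftest import make_pair

PARAMS = DetectionParams()


class TestFilterPairs:
    @pytest.mark.parametrize(
        "mapq,span,kept",
        [
            ((20, 20), 1000, True),   # both thresholds inclusive
            ((19, 60), 5000, False),  # one mate below MAPQ cut
            ((60, 60), 999, False),   # just under the template-length cut
            ((60, 60), 1000, True),
        ],
    )
    def test_threshold_boundaries(self, mapq, span, kept):
        pair = make_pair((0, 100), (span - 100, span), mapq=mapq)
        assert pair.ostensible_tlen == span
        assert (list(filter_pairs([pair], PARAMS)) == [pair]) is kept

    def test_drop_reasons_counted(self):
        from collections import Counter

        pairs = [
            make_pair((0, 100), (1900, 2000), mapq=(10, 60)),
            make_pair((0, 100), (400, 500)),
            make_pair((0, 100), (1900, 2000)),
        ]
        stats = Counter()
        kept = list(filter_pairs(pairs, PARAMS, stats=stats))
        assert len(kept) == 1
        assert stats["dropped_low_mapq"] == 1 and stats["dropped_short_tlen"] == 1


def brute_force_assignment(pairs, genes):
    """Independent oracle: per gene, scan every pair against every exon."""
    support = {}
    for pair in pairs:
        for gene in genes:
            if gene.chrom != pair.chrom:
                continue
            hits1 = [i for i, e in enumerate(gene.exons)
                     if e.start < pair.mate1.end and pair.mate1.start < e.end]
            hits2 = [i for i, e in enumerate(gene.exons)
                     if e.start < pair.mate2.end and pair.mate2.start < e.end]
            if hits1 and hits2:
                counts = support.setdefault(gene.symbol, {})
                for i in hits1 + hits2:
                    counts[i] = counts.get(i, 0) + 1
    return support


class TestAssignToGenes:
    def test_bridging_pair_counts_both_exons(self, three_exon_gene):
        pair = make_pair((1050, 1150), (2050, 2150))  # exon 0 and exon 2
        support = assign_to_genes([pair], [three_exon_gene])
        sup = support["G"]
        assert dict(sup.reads_per_exon) == {0: 1, 2: 1}
        assert sup.bridging_pairs == [("f", 0, 2)]

    def test_intronic_mate_contributes_nothing(self, three_exon_gene):
        pair = make_pair((1050, 1150), (1300, 1400))  # mate2 in intron 0
        assert assign_to_genes([pair], [three_exon_gene]) == {}

    def test_nested_genes_both_accumulate(self, three_exon_gene):
        nested = GeneModel(
            "H", "chr1", "+",
            (GenomicInterval("chr1", 1040, 1160), GenomicInterval("chr1", 2040, 2160)),
        )
        genes = [three_exon_gene, nested]
        pairs = [make_pair((1050, 1150), (2050, 2150), fragment=f"f{i}") for i in range(3)]
        support = assign_to_genes(pairs, genes)
        oracle = brute_force_assignment(pairs, genes)
        assert {s: dict(v.reads_per_exon) for s, v in support.items()} == oracle
        assert set(support) == {"G", "H"}

    def test_agrees_with_brute_force_on_simulated_reads(self, small_genome):
        cfg = SimulationConfig(seed=11, n_genes=6, exon_count_range=(2, 6),
                               exonic_coverage=5, retrocopy_genes=("G1",))
        import numpy as np
        from retroexome.simulate import simulate_background_pairs

        rng = np.random.default_rng(2)
        pairs = [p.record for p in
                 simulate_background_pairs(small_genome, cfg, rng)]
        support = assign_to_genes(pairs, small_genome.genes)
        oracle = brute_force_assignment(pairs, small_genome.genes)
        assert {s: dict(v.reads_per_exon) for s, v in support.items()} == oracle


def brute_force_candidates(support, genes, params):
    """Test every gene directly against the candidate definition."""
    out = []
    for gene in genes:
        sup = support.get(gene.symbol)
        if sup is None or gene.n_exons < 2:
            continue
        supported = [i for i in range(gene.n_exons)
                     if sup.reads_per_exon.get(i, 0) >= params.min_reads_per_exon]
        if len(supported) >= params.min_supported_exons:
            out.append(gene.symbol)
    return sorted(out)


class TestCallCandidates:
    def _support(self, gene, counts):
        from retroexome.detect import ExonSupport
        from collections import Counter

        sup = ExonSupport(gene.symbol, Counter(counts))
        sup.n_pairs = sum(counts.values()) // 2 or 1
        return {gene.symbol: sup}

    def _gene(self, n_exons, symbol="G"):
        exons = tuple(
            GenomicInterval("chr1", 1000 + 2000 * i, 1200 + 2000 * i) for i in range(n_exons)
        )
        return GeneModel(symbol, "chr1", "+", exons)

    def test_three_supported_exons_is_candidate(self):
        gene = self._gene(6)
        support = self._support(gene, {1: 4, 3: 2, 5: 2})
        (cand,) = call_candidates(support, [gene], PARAMS)
        assert cand.supported_exons == frozenset({1, 3, 5})

    def test_two_supported_exons_is_not(self):
        gene = self._gene(6)
        support = self._support(gene, {1: 4, 3: 2, 5: 1})
        assert call_candidates(support, [gene], PARAMS) == []

    def test_single_exon_gene_never_called(self):
        gene = self._gene(1)
        support = self._support(gene, {0: 100})
        assert call_candidates(support, [gene], PARAMS) == []

    def test_agrees_with_brute_force_over_random_supports(self):
        import random

        rnd = random.Random(0)
        genes = [self._gene(n, f"G{k}") for k, n in enumerate([1, 2, 3, 4, 6, 8])]
        for _ in range(50):
            support = {}
            for gene in genes:
                counts = {i: rnd.randint(0, 4) for i in range(gene.n_exons)}
                support.update(self._support(gene, counts))
            got = sorted(c.symbol for c in call_candidates(support, genes, PARAMS))
            assert got == brute_force_candidates(support, genes, PARAMS)

    def test_output_sorted_by_pairs_then_symbol(self):
        genes = [self._gene(4, s) for s in ("B", "A", "C")]
        support = {}
        for gene, n in zip(genes, (5, 5, 9)):
            sup = self._support(gene, {0: 3, 1: 3, 2: 3})[gene.symbol]
            sup.n_pairs = n
            support[gene.symbol] = sup
        out = call_candidates(support, genes, PARAMS)
        assert [c.symbol for c in out] == ["C", "A", "B"]


class TestAnnotateKnown:
    def _candidates(self, *symbols):
        from collections import Counter
        from retroexome.detect import ExonSupport

        genes = []
        support = {}
        for k, s in enumerate(symbols):
            exons = tuple(GenomicInterval("chr1", 10_000 * (k + 1) + 2000 * i,
                                          10_000 * (k + 1) + 2000 * i + 200)
                          for i in range(3))
            gene = GeneModel(s, "chr1", "+", exons)
            genes.append(gene)
            sup = ExonSupport(s, Counter({0: 2, 1: 2, 2: 2}))
            sup.n_pairs = 3
            support[s] = sup
        return call_candidates(support, genes, PARAMS)

    def test_known_symbols_flagged_others_not(self):
        cands = self._candidates("TDG", "CBX3", "NOVEL")
        annotate_known(cands, {"TDG", "CBX3"})
        flags = {c.symbol: c.flags for c in cands}
        assert flags["TDG"] == {"known_retrocopy"} == flags["CBX3"]
        assert flags["NOVEL"] == set()

    def test_empty_inputs_are_no_ops(self):
        assert annotate_known([], {"TDG"}) == []
        cands = self._candidates("TDG")
        annotate_known(cands, set())
        assert cands[0].flags == set()


@pytest.fixture(scope="module")
def spiked_sample(tmp_path_factory):
    """One simulated sample: 10 genes, retrocopies spiked into a 5-exon
    gene (detectable) and a 2-exon gene (below the exon threshold)."""
    tmp = tmp_path_factory.mktemp("spiked")
    cfg = SimulationConfig(seed=21, n_genes=10, exon_count_range=(2, 6))
    genome = make_genome(cfg)
    five = next(g.symbol for g in genome.genes if g.n_exons >= 5)
    two = next(g.symbol for g in genome.genes if g.n_exons == 2)
    cfg_sp = SimulationConfig(seed=21, n_genes=10, exon_count_range=(2, 6),
                              retrocopy_genes=(five, two))
    sam = tmp / "s1.sam"
    simulate_sample(genome, cfg_sp, "s1", sam)
    refflat = tmp / "genes.refflat"
    write_gene_models_refflat(genome.genes, refflat)
    return genome, sam, refflat, five, two


class TestDetectSample:
    def test_spiked_multi_exon_gene_recovered_exactly(self, spiked_sample):
        _, sam, refflat, five, two = spiked_sample
        cands, _ = detect_sample(sam, refflat)
        assert [c.symbol for c in cands] == [five]

    def test_two_exon_spike_rejected(self, spiked_sample):
        _, sam, refflat, _, two = spiked_sample
        cands, _ = detect_sample(sam, refflat)
        assert two not in {c.symbol for c in cands}

    def test_background_only_sample_yields_nothing(self, tmp_path, small_genome):
        cfg = SimulationConfig(seed=11, n_genes=6, exon_count_range=(2, 6),
                               exonic_coverage=50)
        sam = tmp_path / "bg.sam"
        simulate_sample(small_genome, cfg, "bg", sam)
        refflat = tmp_path / "genes.refflat"
        write_gene_models_refflat(small_genome.genes, refflat)
        cands, _ = detect_sample(sam, refflat)
        assert cands == []

    def test_report_written_with_header(self, spiked_sample, tmp_path):
        _, sam, refflat, five, _ = spiked_sample
        out = tmp_path / "cand.tsv"
        detect_sample(sam, refflat, out_tsv=out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("sample\tgene\tchrom")
        assert any(five in line for line in lines[1:])


class TestThresholdMonotonicity:
    def test_candidate_count_nonincreasing_in_each_threshold(self, spiked_sample):
        genome, sam, refflat, _, _ = spiked_sample
        sweeps = {
            "min_mapq": (0, 20, 70),
            "min_tlen": (500, 1000, 2500),
            "min_supported_exons": (2, 3, 5),
            "min_reads_per_exon": (1, 2, 20),
        }
        for name, values in sweeps.items():
            counts = []
            for v in values:
                params = DetectionParams(**{name: v})
                cands, _ = detect_sample(sam, refflat, params)
                counts.append(len(cands))
            assert counts == sorted(counts, reverse=True), (name, counts)
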