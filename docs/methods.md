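# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open. SAM POS and VCF POS
(1-based) are converted in the readers/writers and nowhere else; the
phasing CLI accepts 1-based inclusive coordinates because that is how
genome browsers print them (a deletion printed as 505–527 spans
`end − start + 1 = 23` bases).

## Retrocopy detection

**Evidence model.** A retrocopy is an intron-less cDNA copy of a spliced
gene. Short reads from it align to the source gene's exons, and a pair
whose fragment crossed a removed intron acquires an ostensible template
length (reference span of the pair) equal to the true fragment length
plus every intron strictly between the mates. Detection needs no
knowledge of the integration site — only the source-locus footprint —
and therefore cannot see retrocopies that are already assembled in the
reference.

**Thresholds** (defaults; all exposed as `DetectionParams` fields and
CLI flags):

| parameter | default | meaning |
|---|---|---|
| `min_mapq` | 20 | required of **both** mates |
| `min_tlen` | 1000 bp | ostensible template length, inclusive |
| `min_reads_per_exon` | 2 | read **ends** (not pairs) overlapping an exon |
| `min_supported_exons` | 3 | distinct exons meeting the line above |
| `recurrence_fraction` | 1.0 | cohort fraction at which a gene is a relic |

Interpretation choices where the rule could be read two ways:

- The MAPQ cut applies to both mates: a confidently mapped read paired
  with a multi-mapper fabricates long templates, which is exactly the
  artifact the filter exists to remove.
- "More than 1 read per exon" counts read ends; every supported exon
  must individually meet it. The pair-based reading is one parameter
  change away.
- "More than 2 discrete exons" is an aggregate gene-level requirement
  (≥ 3 supported exons), not a per-pair one — a two-read pair can touch
  at most two exons.
- Both mates must be exonic for a pair to credit a gene; retrocopy
  sequence is entirely exonic, so an intronic mate is background.
- No orientation filter: insertion context can perturb orientation, and
  the span/exon rules carry the specificity.
- A pair inside nested or overlapping genes credits every gene whose
  exons contain both mates; the ambiguity is counted in the run stats.
- Single-exon genes are never candidates: without introns the retrocopy
  is indistinguishable from segmental duplication at the source locus.
- Report ordering is supporting pairs descending, ties broken by symbol.

Gene models are read from refFlat or BED12; exons of all isoforms of a
symbol are unioned, because the unit of detection is the gene, not the
transcript. Which annotation track to use is the caller's choice via the
`dialect` parameter.

## Cohort analyses

The presence matrix (genes × samples, boolean) is the substrate for all
cross-sample summaries. Genes called in ≥ `recurrence_fraction` of
samples (default: all) are flagged **reference relics** — recurrent
signals caused by intron-less paralogues absent from the reference
assembly — and excluded from exclusive counts, iPSC-minus-parent
subtraction, and per-chromosome counts, while remaining visible in the
matrix itself. Subtraction is per iPSC line (parental counts averaged if
a donor somehow has several parental samples); exclusive counts are per
sample, counting genes present in exactly one column.

Clustering uses Jaccard distance on the boolean sample vectors with
average linkage (scipy). The distance/linkage choice affects leaf order
only, never the matrix; both are parameters. A pair of all-false columns
has undefined Jaccard distance and is treated as distance 0. The
dendrogram is emitted as Newick text.

## Mutational signatures

Somatic set = iPSC calls absent (same chrom/pos/alt) from the parental
calls. Homozygous iPSC-private calls are retained: a somatic mutation
followed by gene conversion presents as hom. Filters: total site depth
in the iPSC sample ≥ 8 (alt-allele-count mode would be a one-line
variant; total depth is the plain reading of "supported by N reads"),
and position outside every structural-mutation region (BED; in practice
SNP-array-derived deletion/CN-gain/CN-LOH calls). A missing DP fails any
positive depth filter rather than passing silently.

Classes are `X[R>A]Y` with R ∈ {C,T}: purine-reference variants are
reverse-complemented (ref, alt and trinucleotide context) before
labelling, giving the canonical 96 = 2 × 3 × 16 classes in the usual
block order (C>A, C>G, C>T, T>A, T>C, T>G; contexts lexicographic).
Contexts containing N are excluded and counted.

The **dipyrimidine fraction** is the fraction of classifiable variants
whose pyrimidine-strand 5′ or 3′ neighbour is C or T — the adjacent-
pyrimidine geometry of UV photoproducts. Either-neighbour on the
pyrimidine strand is the chosen definition; under a uniform class mix
its expectation is 12/16 = 0.75 (both flanks purine in 4 of 16 context
combinations), which the tests verify by enumeration. With zero
classifiable variants the statistic is undefined and reported as such.

## Phasing

Fragments (read pairs) are classified at the two loci from their
alignments: an SNV observation is the aligned base at the site; a
deletion observation requires the alignment to anchor on both sides and
either show a deletion operation covering the whole interval (alt) or
align straight across it (ref). Mates disagreeing at a locus make the
fragment uninformative there. Verdicts: *trans* requires
≥ `min_fragments` (default 3) fragments carrying each single alternate
and **zero** carrying both; *cis* is the mirror; anything else is
ambiguous. The strict zero is deliberate — the compound-heterozygosity
claim rests on the absence of dual-variant fragments — and
`min_fragments` is the slack knob for error-prone data.

## Synthetic data

The generator emulates the study conditions: 101-bp paired-end exome
reads, fragment length Normal(300, 50) bp, 100× exonic coverage, genes
of 2–8 exons with 150–400 bp exons and 1200–3000 bp introns (so a
single removed intron already exceeds the 1000-bp template threshold),
and somatic SNV counts per line in the hundreds-to-~1000 range.
`retrocopy_fraction` models clonality: 1.0 for iPSC-like (clonal)
samples, small values for parental-bulk-like samples where a subclonal
event contributes proportionally fewer pairs.

Retrocopy reads are emitted as mapped to the source locus directly — the
aligner itself is not simulated, since source-locus mapping *is* the
evidence model. Fragments are sampled along the cDNA and converted to
genomic coordinates by cumulative exon offsets. A mate crossing an exon
junction is soft-clipped to the block containing its **outer** end
(leftmost block of the left mate, rightmost of the right mate), the way
a non-splicing DNA aligner clips a retrocopy read. Outer-end anchoring
makes the template-length identity
`tlen − fragment = Σ intervening introns` hold exactly for every pair,
which the tests verify against a base-by-base cDNA→genome oracle with
zero tolerated exceptions.

Somatic SNVs are drawn class-first from a 96-class profile and placed at
reference positions whose trinucleotide matches the class context,
realized on either strand with equal probability; depths straddle the
depth-8 boundary and a few variants are wrapped in generated exclusion
regions so every filter is exercised, with the expected outcome of each
variant recorded in the truth log. Phasing read sets are built from two
explicit haplotype sequences with correct deletion CIGARs, every
fragment placed to observe both loci.

What the generator does **not** emulate: realistic base-quality and
error profiles (errors are uniform substitutions), PCR duplicates, GC
bias, capture-kit boundary effects, mapping ambiguity in paralogous
regions, and real reference relics. Passing tests therefore demonstrate
the correctness of the detection and counting logic under the stated
evidence model, not robustness to alignment artifacts in real exomes —
on real data the relic/known-retrocopy annotations and the cohort
recurrence filter carry that weight.

## Numerical and test design choices

- All randomness flows from `numpy.random.default_rng(seed)`; identical
  configs give byte-identical FASTA/SAM/VCF outputs.
- Degenerate inputs: empty candidate sets build a 0-row matrix with a
  warning; a donor missing one cell type is skipped in subtraction;
  zero informative fragments give an ambiguous phase call; zero
  classifiable variants give an undefined dipyrimidine fraction.
- The signature round-trip test checks all 96 per-class exact binomial
  bounds simultaneously, so each is taken at the Bonferroni level
  0.01/96 (99% family-wise coverage); 96 marginal 99% intervals would
  reject an unbiased sampler about half the time. A chi-square goodness-
  of-fit test backs the per-class bounds globally.
- Problem sizes in the test suite (20-gene genomes, 100× coverage,
  10,000-pair identity checks, 1,000-SNV signature runs, 6-sample
  cohorts) were chosen as the smallest scales at which every property is
  statistically meaningful; the whole suite runs in well under a minute.
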