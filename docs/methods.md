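# Methods

## Coordinate conventions

Gene models hold CDS intervals 0-based half-open (BED convention),
non-overlapping, single-chromosome, single-strand, with total length
divisible by three. VCF positions are 1-based and converted at parse
time. On the minus strand the spliced CDS is the reverse complement of
the genome-order exon concatenation, so CDS offset 0 is always the
first base of the start codon. Both coordinate maps (genome→CDS and
CDS→genome) are exact inverses and are property-tested as such.

Annotations are accepted as BED12 (blocks = CDS pieces) or a minimal
GFF3 subset (`gene`/`mRNA`/`CDS`, `ID`/`Parent` attributes only). Full
GFF3 semantics (phase, isoforms, aliases) are deliberately out of
scope: the pipeline targets a small curated gene panel, not genome
annotation.

## Variant effect calling

Records are first decomposed to biallelic form (one record per alt;
genotypes recoded so the retained alt is 1, reference and other alts 0)
and indels left-aligned against the reference by the standard
right-trim / left-extend / left-trim loop, which is idempotent.
Genotypes with read depth below `min_depth` (default 5×) are set
missing per genotype — stricter and more auditable than a per-site
rule — and sites losing every genotype are dropped.

A SNP is classified by substituting the alt base into its codon of the
spliced CDS (complemented on the minus strand) and retranslating that
codon. In-frame indels (length ≡ 0 mod 3) are reported as
`inframe_insertion` at the codon following the last unaffected codon,
or `inframe_deletion` at the first removed codon; other length changes
are `frameshift`. Variants spanning an exon boundary, or whose
reference codon contains N, are `unknown` — never guessed. Each record
is classified independently: adjacent SNPs are not merged into
haplotype-aware codons. This matches how per-SNP catalogues are
reported, and is a known limitation where two same-codon substitutions
co-occur on one haplotype.

The caller is verified against an independent brute-force oracle that
rebuilds the entire CDS per variant and compares full translations, on
plus- and minus-strand fixtures (1,000 random SNPs in the acceptance
suite, 100% concordance required).

Codon accessibility uses exhaustive enumeration over the standard
genetic code: `min_codon_substitutions` is a minimum Hamming distance
over the target amino acid's codons, and `aa_transition_bound`
min/maxes that over the source amino acid's codons. These reproduce the
published arguments that Gly→Ser (ace-1 G119S) and Met→Ser (GSTe2
M111S in *An. gambiae*) need two nucleotide hits while Leu→Ser/Phe
(*Ae. aegypti* GSTe2 111) needs one.

## Cross-species residue renumbering

Native protein positions are mapped to the canonical reference species
by global pairwise alignment: BLOSUM62, affine gaps (open 10, extend
0.5), Biopython's deterministic traceback. The choice of scoring is a
package default — the renumbering convention itself, not any particular
aligner, is what the field fixes — and any co-optimal-alignment
ambiguity is resolved deterministically. Query residues aligned to a
reference gap or beyond the reference termini receive no canonical
coordinate and keep native-only labels (the acetylcholinesterase N- and
C-termini are the canonical example: its reference protein does not
cover them). Canonical numbering starts at 1 on the provided canonical
sequence; species-specific numbering conventions must be encoded in the
sequence supplied, not in code. The map is monotone and invertible on
aligned residues (property-tested).

## Population summaries

Allele-frequency tables default to carrier fraction (samples with ≥1
alt allele / genotyped samples) because surveillance reports quote
"n = x/y" sample counts; allele dosage over 2N is available and both
are emitted by the CLI. Missing genotypes leave both numerator and
denominator. The ≥10-carrier inclusion rule is applied cohort-wide,
not per population. Panel co-occurrence counts *distinct* panel sites
per sample (het or hom both count as carrying) and excludes populations
with ≤10 samples.

Structure clustering uses Russell–Rao dissimilarity d = (n − a)/n on
binary presence vectors (joint absence carries no similarity — two
all-zero samples are maximally distant, a documented quirk), a UMAP
embedding of the precomputed distance matrix, and HDBSCAN on the
embedding (scikit-learn implementation). Defaults: `n_neighbors` 15,
`min_dist` 0.1, `min_cluster_size` 10, chosen so that exchangeable
single-population data is essentially never split (≤1 spurious split in
20 seeds) while three well-separated populations are recovered with
ARI ≥ 0.9; all values are recorded in run metadata. UMAP runs
single-threaded with a fixed seed, so runs are reproducible.
Resistance-gene and background-gene variant sets are clustered as
separate analyses, since strong selection at resistance loci can
distort the genealogy relative to genome background.

## Linkage disequilibrium

r² is computed per population from two-locus haplotype frequencies:
direct gamete counting when both loci are fully phased, otherwise a
two-locus EM over the coupling/repulsion split of double heterozygotes
(initialised at linkage equilibrium, tolerance 1e-8 on frequencies, cap
1000 iterations, observed-data log-likelihood asserted non-decreasing
every step). On phase-known data the EM has no latent variables and
equals counting exactly, which is tested. Monomorphic loci yield an
undefined r² and are reported missing rather than zero. Individuals
missing either genotype are dropped pairwise per locus pair;
populations with fewer than 5 complete diploids at a pair are skipped.
Pairs with r² above the reporting threshold (default 0.5) are flagged
without multiple-testing adjustment, mirroring surveillance practice;
the number of tests is emitted so a Bonferroni-minded reader can adjust.
Colony samples are excluded from LD by default (flag to include).

## Copy-number detection

Depth tables (samtools-depth dialect) are restricted to annotated gene
spans and exon-masked; intronic positions are retained in the matrix
but excluded from every statistic, because intronic repeats inflate and
distort mapping depth. Each sample's depths are divided by its median
over the exons of the included (putatively single-copy) genes; the
candidate CNV genes — *vgsc* and *GSTe2* by default — are excluded from
the normaliser so a duplication cannot deflate its own baseline. The
median is numpy's midpoint convention, used identically in scaling and
checking, making "included-gene scaled median = 1" exact. Per-(sample,
gene) fold is the median scaled exonic value; calls use explicit bins
([0,1.3) normal, [1.3,3) duplication, [3,6) multi-copy, ≥6 high
amplification) that bracket the fold tiers a global coverage survey
resolves (~1.0, ~1.4, ~4.2, ~9.3). An explicit threshold rule replaces
by-eye cluster reading from an embedding: the UMAP coverage embedding
is retained for visual QC only and never feeds the calls (tested:
changing its seed cannot change a call). Genes with <50 covered exonic
positions are flagged low-confidence. Folds are relative coverage, not
ploidy-resolved copy numbers.

## Bioassay classification

Filters: target species only, collection year strictly after 2000,
WHO tube/bottle or CDC bottle assays only, and exclusion of records
whose method note marks a PCR/RT-PCR-only determination (genotyping is
not a phenotype). Mortality bands follow standard guideline
interpretation — WHO: ≥98 susceptible, 90–<98 possible resistance,
<90 resistant; CDC: 97 cut-off — and are configuration, not constants,
because guideline editions differ. Genotype–phenotype joining is
descriptive (side-by-side per-country tables); no association tests are
performed. Intensity (×5/×10 dose) assays are excluded by default.

## Synthetic cohort

The generator emulates a multi-country surveillance cohort on a toy
genome: three chromosomes, the four resistance genes (multi-exon,
*rdl* on the minus strand) and five background genes. Planted
resistance codons reuse the field's canonical labels (V410L, S723T,
G923V, S989P, I1011M, V1016I/G, T1520I, F1534C; G12S, C699S; A301S;
L9I, L111S, C115F, I150V, I169S, A198E) at their conventional canonical
positions; the canonical reference proteins are synthetic stand-ins
derived from the toy natives (identity for vgsc/GSTe2, a 10-residue
N-terminal truncation for rdl so native 311 ≡ canonical 301, an
internal window for ace-1 so its termini are unmappable, as for the
real reference).

Default conditions: three populations of 50 samples whose frequency
profiles follow the qualitative geography of kdr surveys — an
Asian-type population (high F1534C with V1016G/S989P/T1520I and no
GSTe2 variation), an American-type one (F1534C with fully coupled
V410L–S723T and V1016I), and a West-African-type one (lower kdr
frequencies, GSTe2 variation with strong L9I–I169S and I150V–A198E
coupling). Two-locus coupling is parameterised as
p(AB) = c·min(f_A, f_B), so c = 1 gives r² = 1 at equal frequencies.
Diploids are formed from independent haplotype draws; the VCF is
emitted phased (option to strip phase) with per-sample depth ≈ 30×.
Depth is Poisson(λ·fold) on exons (λ = 30 by default) and negative
binomial with ~5× Poisson variance in introns, giving exon masking
something real to do. CNV plans assign fold groups per (sample, gene);
a four-rung demo ladder {1.0, 1.4, 4.2, 9.3} with 20 samples per rung
on the largest gene is used for recovery checks. Bioassay tables plant
a 60/25/15 susceptible/possible/resistant mix per cell plus three
decoy records (year-2000, PCR-only, wrong species) that the filters
must remove.

Each component (genome, genotypes, depth, bioassays) draws from its own
stream seeded by a hash of (master seed, component name), so fixtures
are individually reproducible and byte-identical across runs.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: linked background variation and recombination
(variants are exchangeable within populations; no coalescent), mapping
artefacts beyond inflated intron variance (no paralog mis-mapping, the
actual failure mode motivating exon-unique gene panels), genotype
error, admixed individuals, and multi-copy reference genes (the real
*GSTe2* region has reference-strain paralogy the toy genome lacks).
Recovery results on the synthetic cohort are therefore a correctness
floor, not a field-performance estimate.

## Problem sizes and numerics

Default test and acceptance runs use the 150-sample cohort, ~100
variant sites, ~16 kb of depth positions and 80-sample CNV ladders —
sizes chosen so the whole suite exercises every stage end-to-end in
well under a minute of compute apart from UMAP's one-off numba
compilation. EM tolerance 1e-8, frequency-sum sanity at 1e-6, r²
clipped to [0,1] against rounding. Ties in alignment traceback and in
fold binning (left-closed intervals) are fixed by convention so all
outputs are deterministic given a seed.
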