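# resistscan

A tested, reusable pipeline for surveying genetic diversity in the four
canonical insecticide-resistance genes of *Aedes aegypti* — the
voltage-gated sodium channel (*vgsc*/*kdr*), acetylcholinesterase-1
(*ace-1*), the GABA receptor (*rdl*) and the glutathione-S-transferase
*GSTe2* — across a multi-country whole-genome-sequenced cohort.

It is aimed at vector-surveillance bioinformaticians who have a
multi-sample VCF, per-base read depths and a sample manifest, and want
per-population answers to: which amino-acid substitutions are present,
at what frequency, in which combinations, with what copy-number
background, and how that squares with local bioassay phenotypes.

## What it computes

- **Codon-level variant effects.** Each biallelic VCF record overlapping
  a gene's CDS is substituted into the spliced, strand-aware coding
  sequence and retranslated: synonymous / missense / stop gained or lost
  / in-frame indel / frameshift. Codon-accessibility arithmetic
  (minimum nucleotide changes for an amino-acid transition, by
  exhaustive enumeration over the standard code) supports arguments such
  as why Gly→Ser at ace-1 119 needs two hits in this species while
  Leu→Ser at GSTe2 111 needs one.
- **Cross-species residue renumbering.** Native residue numbers are
  lifted onto the reference species conventionally used for each gene
  (*M. domestica* VGSC, *T. californica* ACE1, *D. melanogaster* RDL,
  *An. gambiae* GSTe2) via global BLOSUM62 alignment, so "F1534C" or
  "A301S" mean the same residue they mean in the literature. Residues
  aligned to a gap or outside the canonical termini keep native-only
  labels.
- **Per-population summaries.** Carrier-fraction and allele-dosage
  frequency tables (variants with ≥10 carrier samples cohort-wide), and
  the distribution of per-sample counts over a configurable resistance
  panel (rdl A301S plus eight *vgsc* kdr sites) for populations with
  more than 10 samples.
- **Two-locus LD.** Per-population r² = D²/(p_A(1−p_A) p_B(1−p_B))
  between missense variants, from direct gamete counting on phased data
  or maximum-likelihood haplotype frequencies via the classic two-locus
  EM on unphased genotypes; pairs with r² > 0.5 are flagged.
- **Coverage-based duplication detection.** Exon-masked per-base depth,
  scaled by each sample's median over putatively single-copy gene exons
  (candidate CNV genes excluded from the normaliser); per-(sample, gene)
  fold = median scaled exonic coverage, binned into explicit
  copy-number groups bracketing the empirically observed ~1.0 / ~1.4 /
  ~4.2 / ~9.3 fold tiers.
- **Population structure.** Russell–Rao dissimilarity on binary variant
  presence, UMAP embedding, HDBSCAN density clustering — run separately
  on resistance-gene and background-gene variant sets.
- **Bioassay summaries.** WHO tube/bottle and CDC bottle mortality
  records filtered (post-2000, target species, no PCR-only
  determinations) and banded into susceptible / possible resistance /
  resistant per standard WHO (≥98% / 90–<98% / <90%) and CDC (97%
  cut-off) interpretation.
- **Synthetic cohort generator.** A fully specified multi-country toy
  cohort — genome, gene models, phased genotypes with planted
  frequencies and LD, depth with planted folds, manifest, bioassays —
  with machine-readable truth, so every stage is testable offline.

## Worked example

Generate the default synthetic cohort (three populations × 50 samples)
and scan it for linkage between resistance mutations:

```bash
resistscan simulate --out fixtures --seed 1
cat > config.yaml <<EOF
reference: fixtures/reference.fa
annotation: fixtures/genes.bed
canonical_proteins: fixtures/canonical_proteins.fa
vcf: fixtures/cohort.vcf
manifest: fixtures/manifest.tsv
depth: fixtures/depth.tsv
bioassay: fixtures/bioassays.csv
EOF
resistscan ld --config config.yaml --out ld_out
```

`ld_out/ld_pairs.tsv` then contains, among the full per-population r²
matrix, the flagged rows (columns abridged, r² rounded to 6 d.p.):

```
population  label_a  label_b  r2        method  flagged
Ghana       V410L    S723T    1.000000  count   True
USA         V410L    S723T    1.000000  count   True
Ghana       L9I      I169S    0.858731  count   True
Ghana       I150V    A198E    0.676741  count   True
USA         I150V    A198E    0.835918  count   True
```

Read: in the simulated USA population the kdr mutation V410L and the
linked S723T ride on the same haplotypes (r² = 1.0, the planted
coupling), while the GSTe2 pairs L9I–I169S and I150V–A198E show the
strong-but-imperfect linkage they were planted with. `method=count`
means phased gamete counting was used; unphased input would fall back
to the two-locus EM. Every output directory carries a
`run_metadata.json` with the package version, config hash and all
hyperparameters.

The other subcommands (`annotate`, `frequencies`, `panel`, `cnv`,
`structure`, `phenotype`, `report`) write analogous TSVs; `report` runs
them all.

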