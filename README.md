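# guidesmith

Design of genome-wide CRISPR/Cas9 knockout guide libraries that jointly
optimize Cas9 enzymatic activity and *what* each guide cuts — in particular,
protein regions whose length has been invariant across evolution, where even
in-frame indels are likely to destroy gene function.

The package is aimed at functional-genomics groups building pooled knockout
screens: it turns a genome (FASTA), gene models (GTF), variants (VCF),
domain/structure annotations, per-gene ortholog protein sets and a table of
cleavage-efficacy scores into a tiered, spaced library of N sgRNAs per gene,
and provides the training machinery used to justify the feature weights.

## What it computes

**Guide database.** Every NGG protospacer on both strands is enumerated and
anchored to its blunt cut site (3 bp 5′ of the PAM). Each guide is annotated
with:

- *intrinsic features* — homopolymer runs (polyA/C/G/T over the synthesized
  construct, so runs may span the vector/scaffold junctions), inadvertent
  Esp3I sites (CGTCTC / GAGACG), nearest-neighbor melting temperature
  (Allawi & SantaLucia parameters), and a pluggable cleavage-efficacy score;
- *specificity* — all NGG-anchored sites within Hamming distance 4 are found
  with a pigeonhole k-mer seed index and aggregated with the position-weighted
  score `s = Π(1 − W[p]) · [((19 − d̄)/19)·4 + 1]⁻¹ · m⁻²` per site and
  `S = 100 / (100 + Σᵢ 100·sᵢ)` per guide, genome-wide and restricted to
  protein-coding sequence;
- *target features* — %CDS of the cut, NMD competence of the two frameshift
  frames under the 50-nt rule, exon symmetry, splice-site proximity, ESE
  motif overlap, domain/site/secondary-structure overlap, and common-variant
  (VAF ≥ 10 %) overlap with the 23-nt target;
- *conservation* — a per-residue deletion-conservation score: the negated
  semi-global alignment delta of deleting each residue (or 2–3-residue
  window) against the gene's ortholog set, PROVEAN-style. Residues in
  length-invariant regions score high; a score > 7 marks a conserved target.

**Library selection.** Binary cutoffs (efficacy > 0.40, conservation > 7,
%CDS < 95 %, no AAAAA/CCCCC/GGGGG/TTT, no Esp3I, no common SNP, specificity
> 0.50 with zero ≤1-mismatch off-targets) define tier 1; constraints are
iteratively relaxed down a configurable ladder, with specificity held as the
top-priority constraint (tiers 7.1–7.6 take 0.25 < S ≤ 0.50; tier 8 is
non-specific). Guides are sorted by (tier, efficacy) and picked ≥ 3 nt apart,
with top-tier guides auto-included regardless of spacing.

**Training analysis.** Screen log2-fold-changes are z-scored per
(experiment, gene), filtered to specific CDS-targeting guides, fit with OLS
on the full feature set, and decomposed into per-feature importance shares
by averaging incremental R² over predictor orderings (LMG). Screen dropout
metrics (negative-control-normalized RPM, guide/gene LFC, intra-gene CV,
hit calls at LFC < −1) and a binomial coverage calculator
P(≥ k of n guides effective) round out the analysis.

A deterministic synthetic-data generator (`guidesmith.synth`) builds toy
genomes, multi-exon genes, ortholog sets with a planted conserved core,
planted off-targets and variants, so the whole pipeline runs and is tested
without any downloads.

## Worked example

```
$ guidesmith fixtures --seed 7 --out demo
wrote 6 files + manifest to demo
$ guidesmith annotate demo/genome.fa demo/genes.gtf \
    --efficacy-table demo/efficacy.tsv --vcf demo/variants.vcf \
    --annotations-tsv demo/annotations.tsv \
    --ese-motifs demo/ese_motifs_synthetic.txt \
    --orthologs-dir demo/orthologs --out demo/db.tsv
76 annotated guides -> demo/db.tsv
$ guidesmith design demo/db.tsv --out demo/library.tsv
24 picks -> demo/library.tsv
$ head -4 demo/library.tsv | cut -f1-9
gene_id pick_index guide_id    tier rank_in_tier efficacy specificity conservation pct_cds
G001    1          chrT:474:-  1    1            0.5621   1.0000      17.0000      0.4208
G001    2          chrT:429:-  2    1            0.6726   1.0000      7.2500       0.1749
G001    3          chrT:411:+  2    2            0.5716   1.0000      7.6250       0.1530
```

The first pick for gene G001 is a tier-1 guide: it clears every cutoff —
efficacy 0.56 > 0.40, unique in the toy genome (specificity 1.0), cuts at
42 % of the CDS inside the planted conserved core (deletion-conservation 17
> 7). The next picks step down the tier ladder (tier 2 drops the domain
requirement) and sit ≥ 3 nt away from earlier cuts.

```
$ guidesmith coverage -n 4 -k 3 -p 0.8
{"n": 4, "k": 3, "p": 0.8, "probability": 0.8192}
```

With four guides per gene and an 80 % effective-guide rate, 81.9 % of genes
receive at least three effective guides.

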