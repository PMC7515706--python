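# Methods

This note documents the models, conventions and default parameters behind
guidesmith, the design choices made where several reasonable options
existed, and what the synthetic-fixture tests do and do not demonstrate.

## Guide enumeration and the cut-site convention

Only NGG PAMs are enumerated: SpCas9's affinity for NGG is far stronger
than for any alternative PAM, and the downstream feature model assumes NGG
chemistry. Every 23-mer window ending in GG on either strand yields one
guide; guides containing N in the protospacer+PAM, or whose 30-nt efficacy
context (4 nt + 20-nt protospacer + PAM + 3 nt) is clipped by a contig
edge, are discarded — 30-mer context scorers cannot score them, and Cas9
targeting of ambiguous bases is undefined.

The cut is modeled as the blunt double-strand break between protospacer
positions 17 and 18 (3 bp 5′ of the PAM), the consensus SpCas9 cut. It is
stored as a genomic breakpoint coordinate — the index of the first
reference-strand base 3′ of the severed bond — which makes the cut site of
two guides on opposite strands of the same physical bond identical, and
gives every positional feature (%CDS, splice class, annotation overlap) a
single unambiguous anchor.

All internal genomic intervals are 0-based half-open; GTF I/O converts to
and from the format's 1-based inclusive convention at the file boundary
only. Principal isoforms are taken from a `tag "principal"` GTF attribute
rather than re-derived: isoform curation is treated as an input. Transcripts
failing CDS invariants (frame, internal stops, CDS outside exons) are
rejected with a logged reason, never fatally.

## Intrinsic features

Homopolymer runs and Esp3I sites are evaluated over the synthesized
construct — vector flank + protospacer + scaffold flank (defaults: `CACCG`
upstream, the first 17 nt of a standard optimized scaffold downstream,
both overridable) — so runs spanning the guide/flank junction are caught.
Only runs and sites overlapping the protospacer count: the scaffold itself
contains fixed TTT runs and the cloning step intentionally uses Esp3I, so
counting flank-only occurrences would make PolyT ≥ 3 and the Esp3I flag
constant-true for every guide and useless as a discriminative feature.
Esp3I is scanned on both strands (CGTCTC and GAGACG) by default because
restriction of double-stranded cloned DNA is strand-symmetric; a
single-motif mode is available.

Melting temperature uses the unified Allawi & SantaLucia nearest-neighbor
ΔH/ΔS parameters with initiation terms, Tm = ΔH / (ΔS + R·ln(C_T/4)) −
273.15, an entropic monovalent-salt correction, and defaults C_T = 0.25 µM,
[Na⁺] = 50 mM. Absolute Tm shifts with the assumed conditions; the tested
contract is rank order across guides, which the conditions do not change.

Cleavage efficacy is a pluggable contract: production scores come from an
external trained model through a TSV table (`TableEfficacyScorer`, which
errors loudly on missing guide ids); `SurrogateEfficacyScorer` is a
deterministic position-weight function of the 30-mer used only to exercise
the pipeline in tests and fixtures. It has no experimental basis.

## Off-target search and specificity

Candidate off-targets are NGG-anchored 20-mers within Hamming distance 4
(no bulges). The protospacer is split into five non-overlapping 4-mers; by
pigeonhole, any site with ≤ 4 mismatches matches at least one 4-mer exactly
at its slot, so a seed index over all NGG sites guarantees completeness,
verified against a brute-force full scan in the tests. Enumeration
truncates at 5,000 sites with a flag; flagged guides are treated as
non-specific downstream.

Each site scores `s = Π_p (1 − W[p]) × [((19 − d̄)/19)·4 + 1]⁻¹ × m⁻²`,
where W is the shipped 20-entry experimentally derived position-weight
vector (any vector is injectable), d̄ is the mean pairwise distance between
mismatch positions and m the mismatch count. Two conventions the formula
leaves open are fixed as: a perfect-match site scores 1.0 (maximally
dangerous — m⁻² is undefined at m = 0), and for m < 2 the distance factor
is 1 (the d̄ → 19 limit). The guide-level score is
`100 / (100 + Σ 100·sᵢ)` over all sites except the one at the guide's own
locus; duplicate perfect sites therefore halve the score. The
proteome-restricted score runs the identical code path over concatenated
spliced CDS sequences. The hard filter used in training and tier 1 requires
specificity strictly > 0.50 *and* zero non-self sites with ≤ 1 mismatch.

## Target features

%CDS is the fraction of spliced CDS 5′ of the cut; the design flag fires
when it is ≥ 0.95 (pass is strictly < 0.95). NMD competence uses a stated
frameshift model: a net +1 or +2 nt insertion at the cut shifts the mature
mRNA reading frame downstream of the cut; the first complete shifted codon
3′ of the cut that is a stop is the premature termination codon, and the
frame counts as NMD-inducing iff that stop starts more than 55 nt (the
conservative end of the published 50–55 nt range, configurable) upstream of
the last exon–exon junction. Single-exon transcripts and last-exon cuts
score 0 by construction. Exon symmetry (exonic CDS length mod 3 ≠ 0) is
reported for internal exons only. Splice classes sd/sa +0/+1/+2 measure the
breakpoint's distance into the donor or acceptor splice site; they are
annotated but deliberately not a tier criterion (splice-site cuts risk
unpredictable change-of-function variants rather than clean knockouts).
The ESE flag requires a motif occurrence to be split by the cut (the
mechanism is abrogation of the enhancer); an exon-presence mode is
available since the alternative reading is defensible. Variant overlap uses
the reference footprint of each VCF allele against the 23-nt
protospacer+PAM interval at VAF ≥ 0.10.

## Deletion-based conservation

For residue window [i, i+w), the variant protein with that window deleted
and the wild type are each aligned to every ortholog with a semi-global
(free end gaps) affine-gap aligner; the per-ortholog score differences are
averaged within sequence clusters, cluster means are averaged, and the sign
is flipped so larger positive values mean higher conservation. Defaults:
BLOSUM62, gap open 10 / extend 1 with a gap of length L costing
`open + L·extend`; an identity matrix (+5/−2) is shipped for comparison.
Each sequence is its own cluster by default; a greedy ≥ 75 %-identity
clustering is available. For w > 1 the window's score is attributed to
every residue in it, averaging overlapping windows — per-residue
attribution of multi-residue deletions is a package choice, as is the gap
convention, and both are config-exposed. The substitution mode (mean
negated delta over all 20 replacements, self contributing 0) exists for
method comparison. A residue is a conserved target when its score is
strictly > 7.

## Tier ladder and picking

Tier 1 requires all of: domain, conservation > 7, efficacy > 0.40,
%CDS < 95 %, clean construct (no Esp3I, no AAAAA/CCCCC/GGGGG/TTT), no
common SNP, full specificity. Tiers 2–6 relax constraints *cumulatively* —
2 drops domain, 3 also conservation, 4 also efficacy, 5 also %CDS, 6 also
construct/SNP cleanliness — keeping full specificity throughout; tiers
7.1–7.6 repeat the ladder under relaxed specificity (0.25 < S ≤ 0.50), and
tier 8 collects the rest. The cumulative order (positive-selection features
relaxed before exclusion features, specificity last) is a documented
package assumption shipped as a data file (`data/tier_table.json`); any
ladder in that format can be supplied, and a guide is assigned the first
tier whose requirements its feature mask satisfies, which makes assignment
monotone in the mask.

Picking sorts by (tier, efficacy descending, genomic coordinate), includes
every top-tier guide unconditionally (truncated by efficacy if they alone
exceed the per-gene quota, default 6; a 12-guide format is a parameter),
and fills remaining slots with the subset of candidates that maximizes
first the number of picks and then their summed rank, subject to all cut
sites — including the waived top-tier ones — being ≥ 3 nt apart. The
subset search is exhaustive over the 20 best-ranked candidates (verified
against a full exhaustive oracle for genes with ≤ 12 candidates) with a
greedy top-up beyond that; ties break toward the lower genomic coordinate,
making the output deterministic.

## Training analysis

LFCs are z-scored per (experiment, gene) with the sample (n−1) standard
deviation; groups of size 1 or zero variance are dropped with a log entry,
and enrichment-readout experiments are expected pre-negated. Records are
filtered to CDS-targeting guides passing the hard specificity filter. The
activity model is OLS of z on efficacy, specificity, conservation, Tm, PAM,
NMD class, and the binary construct/target flags, with categorical
expansion. Relative importance is the LMG decomposition — the average over
predictor-group orderings of each group's incremental R² — computed exactly
by subset enumeration up to 15 groups and by Monte-Carlo over 10,000
orderings (fixed seed) beyond; shares are non-negative and sum to the model
R². Aliased or constant predictor groups are dropped with a warning.

Screen metrics: reads per million per sample, rescaled so the summed RPM of
guides targeting negative-control genes is identical across samples (the
cross-sample mean), which removes the composition shift real dropout
induces; guide LFC = log2((RPM_end + c)/(RPM_ref + c)) with c = 0.5 RPM by
default and replicate RPMs averaged within role; gene LFC is the mean guide
LFC, intra-gene CV is sd/|mean| (signed means would flip the sign of CV
meaninglessly), and a gene is a hit at mean LFC < −1.

## Synthetic fixtures: what they show and what they don't

The generator builds, from one integer seed (byte-identical reruns), a toy
contig of multi-exon protein-coding genes with UTRs and GT…AG introns,
per-gene ortholog sets sharing a verbatim conserved core flanked by
substitution- and indel-ridden tails, planted off-target copies with known
mismatch patterns, variants straddling the 10 % VAF cutoff, domain/site/
helix annotations centred on the core, a synthetic stand-in ESE motif list,
and a seeded uniform efficacy table. Fixture sizes (4–6 genes of 60
residues, ~4–6 kb of genome, 100-kb random genomes for the off-target
equivalence check) were chosen so brute-force oracles run in seconds.

Passing tests on these fixtures demonstrate correctness of the algorithms
— coordinate arithmetic, search completeness, score formulas, selection
optimality — under planted ground truth. They do not demonstrate that the
feature weights transfer to real genomes: fixture efficacies are random
rather than sequence-driven, ortholog divergence is i.i.d. rather than
phylogenetic, and gene structure statistics (exon lengths, GC, repeat
content) are unrealistic. Conclusions about real screen performance require
real genomes, curated ortholog sets and an external efficacy model supplied
through the documented inputs.

## Known limitations

- Hamming-only off-target search: DNA/RNA bulges are not modeled.
- No chromatin accessibility, isoform expression weighting, or microhomology
  misrepair prediction; these are context-dependent and out of scope.
- The deletion-conservation score depends on the supplied ortholog set;
  sparse or redundant sets shift scores (clustering mitigates redundancy).
- The tiers 2–6 relaxation order is an assumption encoded as data, not a
  fitted result; library outputs record the ladder used.
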