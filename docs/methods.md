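# Methods

This note documents the models, statistics and design choices behind
`startscan`, module by module, in the package's own terms.

## Coordinates, frames and gene models

All positions are 0-based and signed on the transcript (5′UTR + ORF): position
0 is the 'A' of the main START ATG and −1 the last 5′UTR nucleotide, so
`frame = pos mod 3` holds exactly (frame 0 = the ORF reading frame). A gene
model must satisfy: ORF length ≥ 6 and divisible by 3, starts with ATG, ends
with a stop, all characters in {A,C,G,T}; violating records are dropped at
load with per-reason counts. Genes with a 5′UTR shorter than 6 nt (the context
window) are retained for ORF-only analyses and excluded from UTR/context
analyses. ATGs overlapping the UTR/ORF junction are binned by the sign of
their start position — a convention, though in practice an ATG cannot start at
−1 or −2 (it would have to overwrite the START's own nucleotides), so the
first UTR position an ATG can occupy is −3.

## START-context PSSM and the relative context score

The context window spans offsets −6..−1 and +1..+3 around the ATG triplet.
The training set is a seeded random half of the top 4% of genes ranked by
ribosomal load (mRNA level × ribosomal density), i.e. 2% of the genome;
training genes are excluded from downstream profile and predictor stages to
avoid over-fitting. PSSM cells are `(count + pseudocount)/(N + 4·pseudocount)`
with pseudocount 0.5 by default (configurable), so probabilities are strictly
positive. Positional entropy is Shannon entropy in bits
(−Σ p·log₂p, 0·log 0 ≡ 0, range [0,2]), optionally z-scored across the
window's positions.

The **raw context score** of an ATG is the geometric mean of the PSSM
probabilities of its nine flanking nucleotides; the **relative score** divides
by the raw score of the gene's own START, making every START exactly 1 and the
measure scale-free. This functional form is this package's definition: it is
monotone in each matching probability, reduces to 0.25 under a uniform PSSM,
and needs no reference beyond the gene itself. Sites whose window is truncated
by the transcript's 5′ end are scored over available positions (geometric mean
renormalized) and flagged partial; genes whose own START lacks a full context
are unscored (missing, never zero). Position-averaged profiles use 30-nt
sliding windows (the ribosome footprint scale) with a 1-nt slide; the START
itself is never averaged into "alternative" means.

## Null genomes and empirical flags

- `CODON_RESAMPLE`: every internal codon is redrawn from its amino acid's
  synonymous-codon distribution with probabilities proportional to genome-wide
  codon counts; the stop is resampled among stops by genome stop frequencies.
  Each gene translates to the identical protein and frame-0 ORF ATG positions
  (Met codons) are untouched, so frame-0 ORF profiles are identical between
  real and resampled genomes by construction.
- `CODON_PERMUTE`: internal codons permuted per gene; START and terminal stop
  stay fixed (permuting them would break the gene model — the source method is
  silent, this is our choice).
- `RAMP_PRESERVING`: as resampling, but synonymous frequencies for the first
  40 codons (configurable) are estimated from, and applied to, that region
  only — preserving the distinct codon distribution at the start of coding
  sequences; amino acids absent from the ramp fall back to genome-wide
  frequencies (logged).

5′UTRs are randomized by permuting their own nucleotides in all schemes,
preserving each UTR's nucleotide multiset (hence GC and length) exactly.
Twenty replicates are generated by default; replicate *r* uses seed
`base + r` so each is independently reproducible.

A position is flagged **DEPLETED** when ≥ ⌈0.95·n⌉ of n null replicates show
more ATGs than the real genome there (ENRICHED for the mirror rule); ties
count toward neither side, which is conservative.

## Region-of-selection estimators

Counts are tallied per in-frame position over −90..+89 nt, with per-position
denominators for variable-length UTRs (counts are deliberately *not*
denominator-normalized in the KS estimator: longer-reachable positions nearer
the boundary can only strengthen, not fabricate, a depletion signal; a
normalized variant exists for control codons).

**KS estimator** (lower-bound flavor): 11-codon windows (the ribosome's
approximate footprint) slide one codon at a time from the boundary outward —
ascending from +3 on the ORF side, descending from −3 on the UTR side.
Positions whose triplet overlaps the START codon (−2..+2) are excluded from
both estimators: they are structural zeros in every genome (position 0 *is*
the START; ±1, ±2 would overwrite it) and would otherwise masquerade as
depletion or, in the vs-null estimator, as permanent ties. Each window's
per-position counts are compared to all remaining in-frame positions of the
span by a two-sample KS test using the asymptotic two-sided p-value (the
classical `kstest2` convention; slightly conservative at these window sizes),
gated so that only windows whose mean lies *below* the remainder's extend the
region. Region length = (window − 1) + the number of consecutive significant
windows from the boundary; 0 when the first window is not significant. On a
sharp planted zone of L codons the estimator reads L + 2 ± 1: windows
containing ≥ 8 of 11 zone positions remain significant past the zone edge, so
detected lengths slightly exceed L (the recovery band used in tests is
[L − 1, L + window − 1]).

**Vs-null estimator** (upper-bound flavor): the boundary-anchored run of
consecutive in-frame DEPLETED positions, in codons. Organism-level summaries
average frames within organism, then organisms.

**Expression-stratified comparison**: the top/bottom 15% of genes by ribosomal
load are compared on per-gene ATG counts in the 30 codons upstream and
downstream of the START (START excluded), per frame and pooled — 8 KS tests.

## Cost of alternative initiation

From each out-of-frame ATG within ±300 nt of the START, in-frame triplets are
scanned to the first stop; scanning continues from UTR sites into the ORF (a
uORF may terminate downstream of the START). Distance is reported in nt from
the ATG's first nucleotide to the stop's first nucleotide; sites with no stop
before the transcript end are flagged open-ended and excluded from means. The
peptide's synthesis cost sums per-amino-acid ATP costs (built-in default:
respiratory-condition biosynthesis costs; any TSV can be supplied); the
initiator Met is included by default (toggleable); the total adds 7 ATP per
incorporated amino acid for translation. "Near" sites lie within 6 codons
(< 18 nt) of the START; near/far groups are compared per region by two-sample
KS. The real-vs-null comparison plants the real genome's alternative ATGs at
their original positions in each codon-resampled replicate (sites colliding
with the START or terminal stop are skipped and logged), measuring what the
same sites would cost absent selection on the surrounding sequence.

## Folding-energy control

For 13-codon (39-nt) windows sliding 1 nt over ±37 nt around the START, each
gene's window is re-randomized 20 times: synonymous codon resampling over the
ORF-covered codons (uniform among synonyms; amino acids and the START fixed),
nucleotide permutation over the UTR portion. Variants split into ATG-free and
ATG-containing classes (ATGs counted in all frames); genes with an empty class
are dropped at that position; per-gene class means form the pairs for a
two-sided paired t-test per window position, with the sign of the mean
difference reported separately. The minimum-free-energy engine is a pluggable
contract — a constant stub, a deterministic base-pair-count heuristic
(−0.3·(2·min(#G,#C) + min(#A,#T)) kcal/mol: 0 for empty or homopolymer input),
an ATG-shift wrapper for planted-direction checks, and a ViennaRNA adapter.
Engine choice never changes the pairing/dropping/test bookkeeping. Variant
class means weight each variant equally.

## Predictor ladder

Features per gene: (1) Kozak hamming distance of the START context from
ACC|ATG|G; (2) the raw PSSM score of the START context (the *relative* START
score is identically 1, so the raw score is the informative quantity);
(3) the number of alternative ATGs, all frames, starting less than 30 codons
downstream of the START; (4) the mean relative context score of those sites
(missing when there are none, mean-imputed inside predictors). Predictors
A={1}, B={2}, C={2,3}, D={2,3,4}. Anti-correlated features (1, 3, 4) enter
negated so all features point toward higher expression. Genes are binned in
descending target order, 15 per bin (last partial bin kept); on each of 100
random 2-fold splits an ordinary-least-squares combination of the binned
features is fit on the train half and scored by Pearson correlation between
prediction and binned target on the test half (Spearman reported alongside).
The regression choice is ours — the combination rule behind the original
ladder is not specified. Adjusted correlations use the adjusted-R² form
`sqrt(max(0, 1 − (1−r²)(n−1)/(n−k−1)))` with n = test bins, k = features
(0 when n ≤ k+1). Folds with zero-variance bins are skipped and counted.
Correlations are evaluated against log-scale abundance: expression is
log-normal and the ladder is a linear model on that scale (binning order is
scale-invariant).

## Synthetic data: what it emulates, and what it does not

`simulate_genome` draws UTR lengths (gamma, mean 82 nt, floor 6) and ORF
lengths (gamma, mean 450 codons, floor ~110 codons so the ±300-nt analyses are
always in range); internal codons come from an unconditional codon-usage table
(default: typical proteome amino-acid frequencies with a 2:1 geometric
within-family bias; stops 47/23/30), so frame-0 interiors are stop-free by
construction. The START context of each gene is drawn from a mixture of a
"strong" PSSM (consensus A-rich upstream, ACC at −3..−1, G at +1, weight 0.7
per consensus base) and a uniform PSSM, with mixture weight
sigmoid(context_effect · latent expression) — this couples context strength to
expression, which is what the PSSM training stage must recover. A depletion
zone (defaults: last 16 UTR codons, first 8 ORF codons, strength 0.8, matching
the magnitudes reported for real genomes) rejects and resamples any sampled
ATG triplet in any frame with the given probability, by a sliding scan with
per-occurrence coin flips; strength 1 guarantees an ATG-free zone or raises
after bounded retries. Expression is log-normal: ribosomal load
exp(latent + N(0, σ)) split multiplicatively into mRNA and ribosomal density,
protein abundance exp(latent + N(0, σ)), σ = 0.5 by default. All draws flow
from one seeded generator; a given `SimParams` is byte-reproducible.

`plant_feature_expression` replaces expression with
exp(Σ effect·standardized feature + N(0, σ)), computing features under a
reference strong-context PSSM. The reference effects
(`DEFAULT_PLANT_EFFECTS`: kozak −0.15, START context +0.3, downstream-ATG
count −0.9, alternative-context mean −0.6; σ = 2.0) were chosen once, on two
grounds: the count receives the largest weight because it is the only feature
orthogonal to the shared context factor (the other three are mutually
correlated at |r| ≈ 0.7–0.8, partly by definition — the relative score's
denominator *is* the START score), and the noise keeps binned correlations in
the 0.3–0.9 mid-range seen for real expression data instead of saturating.
Under these conditions the A→D improvement is large and stable; the strict
per-pair chain A<B<C<D holds in most but not all seeds, because the PSSM
trained on 2% of genes makes feature 2 a noisy estimate of the planted one
(A↔B) and binning compresses the C→D increment.

What the generator does **not** emulate: IRES and non-canonical initiation,
introns and alternative transcripts, 3′UTR structure, real codon-usage tables,
dinucleotide composition, phylogenetic structure across organisms, and any
coupling between depletion strength and expression (available to tests by
construction, but not a default). Passing tests therefore demonstrate that the
estimators recover the structure they are designed to detect under controlled
conditions — not that any particular real genome exhibits that structure.

## Numerical and degenerate-input conventions

0·log 0 ≡ 0 in entropies; geometric means are computed in log space; empty
context windows yield missing scores, never zeros; empirical-flag ties are
non-significant; KS windows extend the region only with a depleted-direction
mean; zero-variance folds are skipped; the paired folding test returns p = 1
for identically-zero differences (constant engines) and p = 0 for constant
non-zero shifts; open-ended stop scans are excluded from cost means; missing
expression propagates as missing. Problem sizes in the test-suite and the
acceptance script (2,000-gene genomes, 10–50 seeds, 500 genes for folding)
were chosen as the package's standard desk-scale study conditions.

## Known limitations

The KS region estimator is granular (any detection is ≥ window length = 11
codons) and overshoots sharp zone edges by up to window − 1 codons; the
vs-null estimator conversely truncates at the first non-flagged position, so
the two bracket the truth. The context-score functional form is a documented
stand-in for an unrendered original. The OLS-on-binned-features combination is
one of several defensible readings of the original ladder. UTR nulls are plain
nucleotide permutations (no dinucleotide preservation). The folding stubs are
bookkeeping controls, not thermodynamics; use the ViennaRNA engine for real
folding energies.
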