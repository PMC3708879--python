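# startscan

Genome-wide analysis of **translation-initiation fidelity signals** around the
START codon of eukaryotic genes.

In the scanning model of eukaryotic initiation, the pre-initiation complex
walks the 5′UTR until it recognizes an AUG in a favorable nucleotide context
(the Kozak rule). Any other ATG triplet near the main START — upstream in the
5′UTR or, because recognition is leaky, in the first codons of the ORF, in any
reading frame — is a potential spurious initiation site that costs the cell
energy and produces undesired peptides. If such events matter, selection
should leave measurable footprints in transcript sequences. `startscan`
quantifies those footprints:

- **Frame-resolved ATG count profiles** around the START (positions −90..+89 nt,
  frames 0/1/2), with per-position denominators and SD-scaled values.
- A **START-context PSSM** trained on the most highly translated genes
  (top 2% by ribosomal load = mRNA · ribosomal density), its positional
  entropy, and a **relative context score** for every ATG: the geometric mean
  of PSSM probabilities over the −6..−1/+1..+3 context window, normalized by
  the gene's own START score (so every START scores exactly 1). The classical
  Kozak hamming distance to `ACC|ATG|G` is provided for comparison.
- **Null genomes**: synonymous codon resampling against genome-wide codon
  usage (identical proteins, preserved codon bias and GC), per-gene codon
  permutation, and a ramp-preserving variant that keeps the codon
  distribution of the first 40 codons; 5′UTRs are randomized by permuting
  their own nucleotides. Per-position **empirical depletion/enrichment flags**
  use the ≥95%-of-20-replicates rule.
- Two **region-of-selection estimators**: sliding 11-codon windows tested by
  two-sample KS against the remainder of a 90-nt span (boundary-anchored,
  length = window − 1 + consecutive significant windows), and the
  boundary-anchored run of positions flagged depleted vs the null genomes.
- **Metabolic cost of alternative initiation**: distance from each
  out-of-frame ATG to its first in-frame stop, the ATP biosynthesis cost of
  the implied peptide (respiratory amino-acid costs, + 7 ATP/aa translation
  cost optionally), near-START vs far comparisons, and a real-vs-null
  comparison in which the real genome's ATGs are planted into randomized
  genes.
- A **folding-energy control**: 13-codon windows around the START are
  re-randomized (synonymous in the ORF, permuted in the UTR) and a paired
  t-test per position asks whether ATG-containing variants fold differently —
  with a pluggable minimum-free-energy engine (built-in stubs; ViennaRNA
  optional).
- A staged **predictor ladder** A–D for expression: (1) Kozak distance,
  (2) START context score, (3) number of alternative ATGs < 30 codons
  downstream, (4) their mean relative context score; evaluated by 100× 2-fold
  cross-validation on 15-gene bins, with adjusted correlations
  `sqrt(max(0, 1 − (1−r²)(n−1)/(n−k−1)))`.

Real genome builds and expression compendia are not bundled; a first-class
**synthetic-data module** generates genomes with the statistical structure the
analysis assumes (codon-usage-biased ORFs, variable-length UTRs, a tunable
ATG-depletion zone, START contexts coupled to expression, log-normal noisy
measurements), so the entire pipeline is testable offline. Loaders accept
plain FASTA pairs (5′UTR + ORF per gene) or an annotation TSV, plus expression
TSVs (`gene_id, mrna, rd, pa`).

## Worked example

```python
from startscan.synthetic_data import SimParams, simulate_genome
from startscan.profiles_regions import atg_count_profile, detect_region_ks
from startscan import pssm_context

genes, expr = simulate_genome(SimParams(n_genes=2000, seed=1))
training = pssm_context.select_training_set(expr, seed=1)
pssm = pssm_context.build_pssm(genes, training)
entropy = pssm_context.positional_entropy(pssm)
print("most conserved context position:",
      entropy.offsets[entropy.entropy.argmin()])

for frame in (0, 1, 2):
    profile = atg_count_profile(genes, frame, up_span=90, down_span=90)
    utr = detect_region_ks(profile, region="UTR5")
    orf = detect_region_ks(profile, region="ORF")
    print(f"frame {frame}: depleted region = {utr.length_codons} codons (5'UTR), "
          f"{orf.length_codons} codons (ORF)")
```

prints

```
most conserved context position: -3
frame 0: depleted region = 16 codons (5'UTR), 12 codons (ORF)
frame 1: depleted region = 17 codons (5'UTR), 12 codons (ORF)
frame 2: depleted region = 16 codons (5'UTR), 12 codons (ORF)
```

The default simulation plants a 16-codon 5′UTR / 8-codon ORF depletion zone at
strength 0.8; the KS estimator recovers the UTR zone at 16–17 codons and —
because a boundary-anchored window extends the detected run by up to
window − 1 codons past a sharp zone edge — reads the 8-codon ORF zone as 12.
Position −3, where the simulator's strong initiation context is most biased,
comes out as the most conserved (lowest-entropy) PSSM position, as it does in
real genomes.

## Command line

The `startscan` CLI wraps the library: `simulate`, `pssm`, `profile`,
`randomize`, `regions`, `cost`, `fold`, `predict`, and `run-all` (the full
pipeline, writing TSV/JSON stage outputs with a parameter echo; byte-identical
re-runs for a fixed seed). `startscan run-all --seed 7 --outdir out/` runs
everything on a default simulated genome; point a JSON config at FASTA and
expression files to analyze real data.

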