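# Methods

This note documents the models, conventions, and numerical choices behind
`poleclass`, and what the synthetic-data generator does and does not
emulate.

## Tumor classification model

Tumors are classified from filtered somatic calls in two stages. The
hypermutator rule applies to the **nonsynonymous SNV count**: calls whose
consequence annotation is `nonsynonymous_SNV` (nonsense calls are tracked
separately and do not count toward the threshold). A count strictly above
500 makes a hypermutator. The spectrum rule is evaluated on the six
pyrimidine-normalized substitution classes; a hypermutator is POLE
category iff f(C>A) > 0.20 and f(C>G) < 0.03, both strict. The
denominator of these fractions is **all** filtered SNVs (synonymous +
nonsynonymous) by default — the larger set gives more stable fractions —
with `spectrum_set="nonsynonymous"` available because the convention is
genuinely ambiguous in the field. A hypermutator with no usable SNVs (an
impossible input in practice) falls to common-hypermutator, since it
cannot satisfy the spectrum rule.

Tumor mutational burden is `count / footprint_mb`. The callable footprint
is mandatory configuration with no default: it is a property of the
capture design, not of the method, and baking one in would silently
miscalibrate TMB.

POLE annotation flags exonuclease-domain membership (86 ≤ residue ≤ 427,
both bounds inclusive) and hotspot status (residue ∈ {286, 297, 367,
411}). Protein changes follow the `[p.]<ref><residue><alt|*>` grammar;
compound entries split on commas. All thresholds live in
`ClassifyThresholds` / `RunConfig` rather than in code: the hypermutator
definition itself varies between studies, so it must be overridable.

## False-positive filtering

The six criteria (quality < 60, depth < 20, single-strand support, clipped
length < 100, position fraction < 0.05, blacklist membership) are applied
with strict inequalities — a value exactly at a cutoff passes. A call with
zero variant reads on *both* strands is degenerate and fails the strand
criterion. A missing metric passes its criterion with a warning by
default; `strict_missing=True` inverts this for pipelines that require
complete QC annotation. Verdicts depend only on the variant and the
blacklist, making filtering idempotent and order-independent, which the
property tests assert.

## Signature refitting

Exposures are estimated against a fixed reference matrix (96 contexts ×
K signatures, convex columns, canonical context order: six substitution
blocks × 16 flank combinations, lexicographic). The per-subset fit
minimizes the sum of squares between the catalog's fraction vector and
the convex combination of the subset's columns, computed by nonnegative
least squares followed by projection onto the simplex; the selection loop
greedily adds the signature with the best resulting error and stops when
the relative improvement drops below 1e-3. Final exposures below the 0.06
cutoff (the conventional refitting default) are discarded and the
remainder renormalized; the reported reconstruction error is recomputed
from the renormalized weights. The procedure is deterministic and
invariant to scaling the catalog counts.

Catalogs with fewer than 50 mutations are refused by default
(`min_total`): sparse fraction vectors make the decomposition unstable,
and in practice only hypermutated tumors are refit. `exhaustive_refit`
fits every subset up to a size bound with the identical per-subset fit; it
is exponential in K and intended as a selection oracle for small banks.
When comparing greedy and exhaustive results, agreement is judged on the
recovered exposures (same kept signatures, weights within 0.02), with
reconstruction-error ties within 1e-6 also counting as agreement — the
cutoff-renormalization step can route the same kept set through different
intermediate subsets, producing meaningless ~1e-5 error differences.

Trinucleotide-frequency renormalization of the reference matrix (an
option in some refitting tools) is not applied; catalogs and signatures
are compared on raw context fractions.

## Statistics

* **Fisher exact (2×2), two-sided:** minimum-likelihood convention — the
  p-value sums the probabilities of all same-margin tables whose point
  probability does not exceed the observed one (small relative slack for
  ties). This is the convention that reproduces the reference cohort's
  printed p-values. `scipy.stats.fisher_exact` computes it; tests verify
  it against an independent exact-rational enumeration oracle.
* **Mann-Whitney U:** midranks for ties; exact null distribution when
  min(n, m) ≤ 8 without ties, otherwise the normal approximation with tie
  and continuity corrections.
* **No multiplicity adjustment** anywhere: the analyses are exploratory
  and p-values are reported raw, by design.
* **Expression:** raw intensities are log2-transformed and centered on
  each sample's 75th percentile (so a global scale factor between samples
  cancels); the per-patient fold change is tumor minus normal on the log2
  scale. Group comparisons of a gene compare fold-change distributions
  pairwise (NH vs CH, NH vs PC, CH vs PC). Log base 2 is the microarray
  convention; the centering percentile is computed with linear
  interpolation.

The three-group report dichotomizes pT as Tis–T2 vs T3–T4 and pStage as
0–II vs III–IV, reports `count (percent)` to one decimal and p-values to
three, and marks comparisons involving an empty group as not computable
(NaN) rather than failing.

## Synthetic cohort generator

The generator draws each tumor's class from the prevalence vector
(defaults 0.926 / 0.063 / 0.011), then everything else from
class-conditional distributions:

* **Nonsynonymous SNV counts.** Nonhypermutators: lognormal with median 71
  and σ = 0.7, resampled above 450 so that truth labels remain consistent
  with the >500 rule after filtering losses. Common-hypermutators:
  650 + lognormal(median 550, σ = 0.6), floored well above the threshold
  for the same reason (median total ≈ 1,200). POLE category: log-uniform
  on 1,700–9,500. Total SNVs are the nonsynonymous target divided by the
  nonsynonymous fraction (default 0.7, a free parameter: consequences are
  drawn per-variant as Bernoulli(0.7)).
* **Spectra.** Background and MMR-deficient-like classes are C>T-rich
  with C>A ≈ 0.08 and C>G ≈ 0.06 (violating the POLE rule by
  construction); the POLE-like class draws C>A uniformly from
  (0.28, 0.45) with C>G fixed at 0.01 (satisfying it by construction).
  Variants are placed uniformly over a random 2 × 60 kb reference genome
  (both strands represented), so trinucleotide contexts exist for catalog
  building.
* **QC noise.** Each of criteria 1–5 independently corrupts 1% of
  variants (≈4.9% discarded overall); metrics are otherwise drawn in
  comfortably passing ranges with the depth/strand-count invariant
  maintained. An optional blacklist fraction feeds criterion 6.
* **POLE protein changes.** Every POLE-category tumor receives a hotspot
  change (P286R with probability 0.7, else S297Y/F367C/V411L); passenger
  changes outside the exonuclease domain are sprinkled into the other
  classes (1.2% of nonhypermutators, 16% of common-hypermutators, 10% of
  them nonsense).
* **Clinical covariates.** Age, sex, sidedness, histology, size, pT,
  pStage, invasion, and MMR-testing frequency are class-conditional,
  giving a younger (median ≈ 45), male-dominated (90%) POLE group, a
  right-sided, MMR-deficient common-hypermutator group, and reference
  marginals for the background class.
* **Expression.** Normalized log2 tumor/normal pairs for PD-L1, PD-1,
  CTLA-4, CD8A. Fold-change shifts are +2.5 (log2) for PD-L1/PD-1 in both
  hypermutator classes and for CD8A in the POLE class, zero for CTLA-4,
  with unit fold-change noise; 2% of tumors lack expression data. The
  magnitudes are free parameters chosen by a power calculation so that
  the expected significance pattern is detectable at group sizes
  829/53/10 in ≳90% of seeds; the "CTLA-4 null" check is defined on the
  NH-vs-PC comparison.

Everything is reproducible from a single seed, and writing the same
cohort twice is byte-identical. The truth table records every latent
assignment so recovery can be scored without re-deriving it.

**What the generator does not emulate:** indels and structural variants,
realistic genome composition and trinucleotide background (the reference
is uniform-random), mutational clustering or linkage, germline
contamination, subclonality/VAF structure, correlated QC failures, and
correlations among clinical covariates beyond class conditioning. Passing
the end-to-end tests therefore demonstrates that the pipeline's logic is
correct under the stated statistical structure, not that the thresholds
are optimal for any real cohort.

## Problem sizes and tolerances in the test suite

End-to-end recovery is scored on a 1,000-tumor cohort (≥99% required;
residual misses can only come from sampling near the 500-count boundary).
Refitting recovery uses 100 two-signature catalogs of 5,000 mutations
(mean absolute exposure error < 0.05) against a deterministic synthetic
six-signature bank; single-signature catalogs must recover weight
1.0 ± 0.02. Fisher is checked against the enumeration oracle on 500
random tables of total ≤ 200. The expression pattern is scored over 100
(script) / 200 (tests) simulated cohorts at group sizes 829/53/10.

## Known limitations

* The refitting forward selection is greedy; on heavily overlapping
  signature banks it can return a near-optimal rather than optimal subset
  (the exhaustive oracle bounds this on small banks).
* The consequence annotation is consumed as given; the package does not
  re-annotate variants, so differences between annotators propagate into
  the nonsynonymous count.
* The Fisher minimum-likelihood convention is one of several two-sided
  conventions in circulation; results are only comparable across tools
  using the same convention.
* The 2×2 machinery intentionally covers only dichotomized variables;
  r×c exact tests are out of scope.
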