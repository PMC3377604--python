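# Methods

## The classification problem

Multifunctional enzymes (MFEs) — moonlighting enzymes with independent
functional domains and promiscuous enzymes whose single domain carries
several activities — are under-annotated because each extra function must
be discovered experimentally. `mfescan` treats MFE detection as binary
sequence classification: proteins longer than 100 residues are encoded as
fixed-length physicochemical feature vectors and scored by two independent
learners whose agreement at high confidence constitutes an MFE call.

## Feature encoding

The encoding is the 188-dimensional CTD scheme. The 20 amino-acid
composition fractions come first (alphabetical by one-letter code). Then,
for each of eight properties in a fixed order (hydrophobicity, normalized
van der Waals volume, polarity, polarizability, charge, surface tension,
secondary structure, solvent accessibility), the 20 residues are
partitioned into three groups and 21 descriptors are computed:

* **Composition** (3): fraction of residues in each group. Range 0–1;
  the three values sum to 1.
* **Transition** (3): for unordered group pairs (1,2), (1,3), (2,3), the
  number of adjacent residue pairs whose members fall in the two different
  groups, in either order, divided by N−1. Range 0–1; the sum is ≤ 1.
  Transitions are direction-symmetric, so sequence reversal preserves them.
* **Distribution** (15): for each group with m occurrences at 1-based
  positions p₁ < … < p_m, the five values 100·p_q/N at
  q = max(1, ⌈f·m⌉) for f ∈ {first, 0.25, 0.50, 0.75, 1.00}. Range 0–100,
  non-decreasing within a group; an absent group contributes five zeros
  (fixed vector length, conventional sentinel).

### Choices made where the scheme is conventionally under-specified

* **Group tables.** The descriptor tradition does not fix one canonical
  partition per property. We ship the widely used three-group tables (e.g.
  charge: positive {K,R} / neutral / negative {D,E}) in
  `src/mfescan/data/ctd_groupings.tsv`, versioned; a saved model records
  the table version and refuses to load against a different one, so an
  alternative grouping is a configuration change that cannot silently mix
  encodings.
* **Quantile convention.** ⌈f·m⌉ with a floor of 1, 1-based positions,
  scaled by 100/N — stated explicitly because the main code and the
  brute-force test oracle must share it.
* **Scales.** Composition/transition on 0–1, distribution on 0–100. Both
  models see a scale-consistent layout; the SVM additionally standardizes
  per feature, so the mixed scale has no downstream effect.

Only the 20 standard residues are defined for these descriptors.
Nonstandard codes (B, J, O, U, X, Z, `*`, gaps) are handled by an explicit
policy at FASTA parse time; the default skips the whole record with a
logged warning, since dropping single residues silently shifts transition
and distribution values.

## Dataset construction

Positives are the annotated MFEs longer than 100 residues (strict
inequality; the boundary case of exactly 100 is excluded, and the cutoff is
a parameter). Negatives are chosen family-aware: every domain family with
at least one MFE member is excluded, and one uniformly drawn seed protein
(> 100 residues) is taken per remaining family. Two rules cover cases the
family-level description leaves open:

* a protein carrying *any* MFE-containing family is ineligible as a
  negative seed, even if it also belongs to clean families — otherwise a
  negative could share domain architecture with a positive through its
  other family;
* a protein belonging to several clean families is sampled at most once
  (deduplicated by id; the family slot is re-drawn or dropped), so no
  feature row is duplicated.

Sampling requires an explicit integer seed; there is no hidden global
random state.

## Models

* **SVM**: RBF kernel on per-feature standardized inputs, the scaler fitted
  on training rows only. C and γ are selected by grid search over
  C ∈ {2⁻², …, 2⁶} and γ ∈ {2⁻⁷, …, 2¹} (powers of two) with 3-fold inner
  cross-validation; probabilities come from Platt-style sigmoid calibration
  on internal 5-fold CV predictions, with a final refit on all training
  rows. Grid search can be disabled (fixed C, γ) for large runs.
* **Random forest**: 500 unpruned trees (unlimited depth), √188 ≈ 14
  candidate features per split, raw (unstandardized) features; the
  probability is the fraction of trees voting for the MFE class.
* **Consensus call**: MFE iff SVM probability > 0.90 **and** RF
  probability > 0.80, both strict. The thresholds are config defaults,
  overridable; the rule is monotone in both probabilities. The asymmetric
  thresholds reflect the two learners' calibration sharpness: raising both
  requirements suppresses false positives at the cost of sensitivity,
  appropriate when screening hundreds of thousands of catalog entries.
* **Cross-validation**: stratified k-fold (default k = 5), the scaler and
  both models refitted inside each training fold; each row is predicted
  exactly once by models that never saw it, pooled counts sum the folds,
  and the fold assignment is exported for audit. Per-model counts are
  tallied at the 0.5 probability cut, consensus counts at the dual
  thresholds.

## Synthetic data generator

The generator emulates the two-class study design without any database
download: random sequences over the 20-letter alphabet, lengths uniform on
101–400, negatives from a background distribution (uniform by default; a
natural-frequency background is available), positives from the same
background with per-residue weight multipliers — by default charged
residues {K, R, D, E} up-weighted ×3, a composition shift the charge-CTD
block is directly sensitive to. Pseudo-families emulate domain-family
annotation: positives share a small pool of "MFE families", each negative
carries a private family, and 25% of negatives additionally carry an MFE
family so that family-aware negative selection has real exclusions to make.

What it does **not** emulate: residue autocorrelation and domain structure
(real transitions/distributions are far from i.i.d.), homology between
records, class imbalance, and annotation noise. Passing tests on this
generator therefore demonstrate that the pipeline recovers a planted
composition signal and that its bookkeeping (no leakage, correct pooling,
determinism) is sound — not that real-proteome performance matches any
published figure.

## Problem sizes and expected results

The test suite and acceptance script run the full pipeline at
100 sequences/class (charge-biased) and 200/class (null, bias ×1), sizes at
which the planted signal is unambiguous: pooled five-fold accuracy
typically ≥ 0.98 for both models under bias ×3, and within 0.5 ± 0.1 under
the null. The descriptor implementation is checked element-wise against an
independent brute-force counter on 1,000 random sequences (tolerance
1e-12).

## Known limitations

* The published group tables for this descriptor family vary slightly
  between implementations; numbers from other CTD codes may differ in the
  distribution block unless their quantile convention matches the one
  stated above.
* Probability calibration on small training sets (< ~50/class) is noisy;
  consensus sensitivity drops accordingly (the worked example shows 84%
  consensus sensitivity against 98–99% per-model accuracy).
* Metrics with zero denominators (e.g. PPV with no positive calls) are
  reported as NaN with a warning, never as 0.
* Reported percentages round half-up to one decimal; raw ratios are kept
  alongside for arithmetic.
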