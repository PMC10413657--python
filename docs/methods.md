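# Methods

## The allele-mixing model

A heterozygous locus expresses wild-type (wt) and mutant (mut) subunits of
a homodimer. Each dimer assembles in cis with probability `cis_fraction`
(both subunits from one transcript; the transcript is wt with probability
`wt_allele_fraction`, default 0.5), otherwise its two subunits are
independent draws from the pooled subunit population. The expected pure-wt
fraction is therefore `cis·p + (1−cis)·p²` with `p = wt_allele_fraction`;
at equal expression this interpolates from ¼ (fully posttranslational)
to ½ (fully cotranslational), while the hybrid fraction falls from
`2p(1−p)` = ½ to 0. `simulate_assembly` samples this model exactly
(binomial/multinomial draws), so reported fractions carry ordinary
Monte-Carlo error of order `√(p(1−p)/n)`.

## Solvent accessibility and interface profiles

SASA is computed with the Shrake–Rupley method: each atom is inflated by
the probe radius (1.4 Å, water) and sampled with a deterministic Fibonacci
sphere lattice (default 960 points); a sample point is accessible if it
lies outside every neighbouring inflated sphere, and the atom's SASA is
the accessible fraction of 4π(r+probe)². The Fibonacci lattice makes
results bit-reproducible at a given point count; an isolated atom recovers
the closed form exactly. Discretization error at 960 points is well below
1% for isolated atoms and a few percent for per-residue areas of packed
structures; because the lattice is not rotation-invariant, symmetric
chains in different orientations agree only up to that discretization
error, which shrinks as the point count grows.

Van der Waals radii are keyed by element (C 1.70, N 1.55, O 1.52, S 1.80,
P 1.80, H 1.20, Se 1.90 Å; generic fallback 1.80 Å); Cα-only synthetic
chains use 1.70 Å uniformly.

A subunit's interface profile is per-residue
ΔSASA = SASA(isolated) − SASA(in complex), floored at 0 since negative
values can only arise from numerical noise. With more than two chains the
subject chain's profile accumulates area lost against the full complement
of partners, i.e. the sum over all pairwise interfaces it participates in.
Subunits with total interface area ≤ 400 Å² are flagged as failing the
inclusion rule used to screen out likely crystallographic contacts.

## Interface-location metrics

The relative interface location (RIL) is defined here as the
interface-area-weighted mean of relative residue positions,
Σᵢ aᵢ·(i/L) / Σᵢ aᵢ, with i the 1-based canonical residue index and L the
chain length. This is a documented design choice: the metric's defining
property — 0 at the N terminus, 1 at the C terminus, interpretable as a
percentage of protein length — admits other summaries (median, first
contact), and the weighted mean was chosen as the simplest statistic with
an exact reversal identity (reversing the sequence maps x to
(L+1)/L − x) and scale invariance in the areas, both of which are tested.

`half_area_position` is the smallest i/L at which the running sum of the
profile reaches a given fraction (default ½) of the total — the point
during translation at which that share of the final interface has been
exposed. `interface_shift` is 100·(observed RIL − basemean); the basemean
is the unweighted mean RIL of the subunit's symmetry group, computed once
on the full dataset and passed in, so that a positive shift reads as "the
interface is this many percent of the protein's length more C-terminal
than expected for its symmetry class".

## Extent of disease clustering (EDC)

For every confidently modelled residue (pLDDT > 50 when confidence scores
are present) the Cα distance to the nearest disease-associated residue is
taken, a disease residue excluding itself (its self-distance of 0 would
make the log undefined). EDC is log₁₀ of the non-disease mean over log₁₀
of the disease mean; arithmetic means are used for both groups. At least
three pathogenic positions are required. Mean distances ≤ 1 Å would flip
the sign of a logarithm; since that is geometrically impossible for ≥3
distinct Cα positions, such input raises a degenerate-log error rather
than returning a misleading value.

On a chain-like geometry the statistic is asymmetric for sequence-
interleaved disease sets (a non-disease residue's nearest disease residue
is one backbone step away, a disease residue's two), so the null fixture
for "dispersed ⇒ EDC ≈ 1" is the globular generator, whose coordinates are
independent of sequence index; on it, any sequence-based labelling is
spatially random and EDC concentrates at 1.

## Enrichment and resampling statistics

* Hypergeometric test: one-sided in the direction of the observed
  deviation by default (the headline comparisons are directional
  depletion claims); the direction can be forced.
* Odds ratio: (a·d)/(b·c) with the SE-method CI
  exp(ln OR ± z·√(1/a+1/b+1/c+1/d)). Zero cells raise an error rather
  than receiving a continuity correction; proportion-only input yields
  the point OR without a CI. The interface-enrichment helper reports raw
  OR 0/∞ for zero cells, with the CI set to NaN.
* Jeffreys intervals: equal-tailed Beta(k+½, n−k+½) quantiles, default
  level 68% (one-standard-error bars on proportion plots).
* Wilcoxon rank-sum: normal approximation with continuity correction and
  average ranks by default; an exact mode exists for small samples. The
  effect size is r = z/√n with z recovered from the two-sided p-value and
  signed by the rank direction.
* Holm–Bonferroni: step-down adjustment with monotonicity enforcement,
  capped at 1.
* Abundance quartiles: four equal-count bins over records with abundance,
  ties broken by stable input order (bin sizes differ by ≤1). The
  ppm → molar map is linear, `ppm·total·10⁻⁶` in nM with the total
  protein concentration configurable (default 2.7×10⁶ nM ≈ 2.7 mM, a
  standard figure for cellular protein content); only the ordering
  matters downstream, so the constant is a display scale.
* Stratified bootstrap: shifts are resampled with replacement within each
  stratum B times (default 10,000); the per-resample point estimate is
  the mean shift; the CI is the 2.5/97.5 percentile interval; the
  one-sided p-value for a C-terminal shift is (1 + #{resample means ≤
  0})/(B + 1) — the add-one estimator is the finite-sampling correction,
  bounded below by 1/(B+1).

## Mechanism text classification

Sentences are split on terminal punctuation followed by whitespace;
abbreviation-induced oversplits are left to curation. Matching is
case-insensitive after hyphen→space normalization and whitespace
collapsing, so "dominant-negative" and "Dominant  Negative" both hit the
DN keyword. Keyword lists: DN {"dominant negative"}; GOF {"gain of
function", "activating mutation"}; LOF {"haploinsufficiency",
"haploinsufficient", "dosage sensitivity", "dosage sensitive",
"heterozygous loss of function"}. Retained sentences are verbatim
substrings of their source. Curation is an accept/reject map over
sentences, replacing by-hand review; the final class per gene follows the
precedence DN > GOF > LOF over accepted evidence and is independent of
evidence ordering.

## Non-LOF prioritization model

* **Redundancy filter.** Percent identity is matches over alignment
  columns of a global alignment (match 1, mismatch 0, gap open −2, gap
  extend −0.5, so substitutions are preferred over gaps). The filter
  greedily removes the gene with the most remaining ≥50%-identity
  conflicts until none remain; among ties the lexicographically last
  gene_id is removed. Greedy most-connected-first is a documented choice;
  it retains a maximal conflict-free set deterministically.
* **Preprocessing.** Numeric columns are z-scaled with NaN-tolerant
  statistics, imputed with 5-nearest-neighbour Euclidean imputation
  (pairwise-complete distances), and re-standardized so the training
  design has mean 0 / SD 1 exactly; nominal columns are one-hot encoded
  on fit-time categories (unseen categories become all-zero blocks). All
  parameters are learned on training rows only.
* **Fitting.** The per-sample penalty λ maps to scikit-learn's liblinear
  solver as C = 1/(λ·n). The default grid is 18 log-spaced values on
  [10⁻¹⁰, 1]: a log grid cannot start at 0, so the lower end is chosen
  small enough to be effectively unpenalized, and any custom grid can be
  supplied. λ is selected by mean assessment-fold accuracy over
  stratified 10-fold CV repeated 3 times (accuracy, not AUC, is the
  tuning metric); ties go to the largest λ. λ = 0 is rejected because
  unpenalized logistic regression diverges on separable data. The
  support size is recorded along the grid after refitting at each λ.
* **Reporting.** Importance is |β|/max|β| over non-intercept
  coefficients, with signs kept separately. Threshold candidates are the
  observed scores, midpoints between adjacent unique scores, and 1.0,
  making the Youden sweep exact and finite; T1 is the lowest candidate
  maximizing J and T2 the smallest candidate with zero false positives
  (T1 ≤ T2 always holds on the same score set). If a negative attains the
  maximum score, no cutoff reaches 100% specificity and T2 is NaN with a
  warning.

## Synthetic generators

All generators are bit-reproducible for a fixed seed.

* **Homodimers.** Cα-only chains with exact 3.8 Å spacing and uniform
  1.7 Å radius. Two identical straight chains cannot touch over only a
  sub-segment, so chains are piecewise-linear: straight and 5 Å apart
  inside the designated interface segment (within the 6.2 Å occlusion
  range of 1.7 Å spheres probed at 1.4 Å), flaring apart at 3 Å of
  lateral separation per residue outside it, with the x-step shortened to
  keep backbone spacing exact. Chain B is chain A under a proper rigid
  transform (180° rotation about x plus a translation). The seed applies
  only a global rigid motion, preserving every distance-based property.
  This makes the contact region — and hence the downstream interface
  profile's support — exact by construction.
* **Globules.** Dart-throwing placement inside the smallest sphere
  accommodating n points at ≥3.8 Å separation; coordinates are
  independent of sequence index (the null geometry for clustering tests).
* **Gene tables.** Per-class independent Bernoulli co-assembly flags.
  Default rates are 24.0% (AD) and 35.6% (AR) — the observed proportions
  in the human disease-gene dataset this package's analyses are modelled
  on (odds ratio 0.57); mechanism classes (DN/GOF/LOF) are recorded with
  AD inheritance.
* **Variant sets.** Clustered mode samples without replacement from a
  ±spread window; dispersed mode from the whole chain; a minimum of three
  pathogenic positions is enforced at generation time.
* **Logistic features.** Standard-normal X, labels
  Bernoulli(logistic(Xβ)), missingness completely at random — matching
  the unconditional k-NN imputation downstream.

What the generators deliberately do not emulate: real folds, side chains,
sequence-dependent contact maps, correlated features, informative
missingness, or linkage between a gene's annotations and its structure.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under its stated assumptions, not the empirical
effect sizes obtainable from real structural and clinical data.

## Problem sizes and determinism

Default analysis sizes were chosen so every computation is exact or has
negligible Monte-Carlo error at interactive scale: 10⁶ dimers for mixing
fractions (SE ≈ 0.04–0.05 points), 2×20,000 genes for odds-ratio recovery,
B = 10,000 bootstrap resamples (2,000 in nested coverage studies), 960
sphere points for SASA (5,000 where rotational symmetry is compared), and
n = 2,000 × p = 10 for lasso recovery. Every stochastic entry point takes
a seed; the pipeline writes a manifest with the configuration hash and all
derived seeds, and reruns with an identical configuration are
byte-identical.

## Known limitations

* SASA values are lattice-discretized; cross-implementation agreement is
  expected only within a few percent at default point counts.
* The RIL formula is one reasonable definition among several; analyses
  comparing against externally computed RIL values should confirm the
  convention matches.
* The keyword classifier has no semantic understanding: negated mentions
  ("rather than haploinsufficiency") still match, exactly as a keyword
  filter should; curation is the intended correction mechanism.
* The lasso's λ grid lower end stands in for "unpenalized"; coefficients
  at the smallest λ on near-separable data are large but finite due to
  the solver's convergence tolerance.
* PDB/mmCIF input uses the file's first model and assumes the biological
  assembly was extracted upstream; author residue numbering must already
  match canonical sequence positions.
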