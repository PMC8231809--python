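# Methods

This note records the scientific and numerical choices behind each stage of
the package, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Structure geometry

**SASA.** Solvent-accessible surface area is computed by Shrake–Rupley point
sampling: each atom's sphere of radius (vdW + probe) is covered with a
deterministic golden-section spiral point set and the accessible fraction is
the share of points outside every neighbour's expanded sphere.  Defaults:
probe 1.4 Å (water), 960 points per atom.  Per-atom error from the point
set is well under 1% at physically reasonable packing (verified against a
Monte-Carlo rejection oracle and against an independent third-party
implementation in the test suite).  Van-der-Waals radii are a fixed
element-keyed table (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å), overridable
per call; only heavy atoms are used (crystal structures of this resolution
carry no hydrogens).  An element missing from the radius table is an error
naming the offending atom, never a silent default.

**Burial.** Burial is judged monomer by monomer: each protein chain's SASA
is computed in isolation, per-residue values are grouped by canonical
position, and a position is *Buried* when its SASA is **strictly below** the
cutoff in at least one chain (the any-chain rule).  The default cutoff of
11 Å² marks roughly the most buried 30% of residues of the TP53 tetramer
structure.  Burial is monotone in the cutoff by construction, which the
suite asserts as the cutoff-ladder property (2.5 → 11 Å²).  Canonical
numbering: author residue numbers in 94–292 and 324–355 are taken as
canonical TP53 positions (the crystallized construct aligns identically
there); anything else maps to `None` and surfaces downstream as the
`unknown` burial level.

**Interfaces.** A residue is an interface residue between chain subsets X
and Y when its SASA computed with its own subset alone exceeds its SASA in
the X∪Y complex by more than the cutoff (default 1.0 Å²).  The definition
is symmetric in the subsets and is verified against a direct
isolated-minus-complex recomputation.

**Secondary structure** comes from the structure file's helix/sheet records
(no hydrogen-bond recomputation); unannotated protein residues are loop.
Where helix and sheet annotations overlap, helix wins — an arbitrary,
documented tie-break.  Ranges reaching outside the structure are clipped
with a warning.

**Statistical universe.** The background set for enrichment tests is every
canonical position present in at least one protein chain (231 positions for
a construct covering 94–292 ∪ 324–355).  This is a package choice — a
different universe (e.g. the full 393-residue protein) would change the
margins — and is therefore configurable and recorded in output.

## Conformation features

The continuous explanatory variables are variant-minus-wild-type
differences of external per-residue predictor scores at the substituted
position.  The predictors (disorder trained on different corpora,
backbone flexibility, secondary-structure and compactness meta-structure
scores, interaction propensity) are consumed as plain score tables; the
package defines only their file contract and never reimplements them.  The
`PPI6` profile (sensitive settings, minimum segment 6) feeds the model
variable; the less sensitive minimum-segment-10 profile is used only for
calling/plotting interaction *regions*.  Terminal trimming (first 4, last 3
positions) applies only to region calling — difference scores are never
trimmed.  Region calling keeps maximal runs of positions at ≥ 5% of the
profile maximum with length ≥ the minimum segment.

Each variant therefore carries 12 explanatory values: the three-level `Bur`
factor plus eleven `*_dif` scores.

## Enrichment statistics

Residue sets are deduplicated (a position hit by two variants counts once)
and positions outside the structure are excluded from the tables and
reported separately.  The two-sided Fisher exact test uses the
point-probability convention (sum of hypergeometric probabilities of all
tables with the observed margins that are no more probable than the
observed table) — the convention of the standard exact-test implementations
— computed via `scipy.stats.fisher_exact` and verified against a full
enumeration oracle in the tests.  Degenerate margins give p = 1; zero-cell
odds ratios are reported as 0 or infinity, never as errors.  Multiplicity is
handled by Benjamini–Hochberg step-up adjustment across one scan.

## Phenotype models

**Fitting.** Maximum likelihood by Newton–Raphson on the log-likelihood,
tolerance 1e-8, at most 50 iterations, with Newton steps capped in norm (5
per iteration) and a tiny ridge fallback for singular Hessians.  LFS is
coded 1; the burial factor enters as two dummies with *Buried* as the
reference (Surface-vs-Buried, unknown-vs-Buried).  A factor level absent
from a given sample (common inside bootstrap resamples) leaves an all-zero
design column; the fitter pins that coefficient at zero with zero
covariance so coefficient names and shapes stay stable across resamples.

**Separation.** The `unknown` level typically holds a couple of
observations of one class.  The likelihood then has no interior maximum in
that direction; the iteration cap leaves a large finite negative
coefficient with an enormous Wald interval.  This is flagged with a warning
(never an error) because it is exactly the behaviour the published
coefficient table shows, and the affected contrast is excluded from the
nomogram.

**Inference.** Odds ratios are exp(β) with Wald 95% intervals
exp(β ± 1.96·se); p-values are two-sided normal on β/se.  Published
continuous-variable odds ratios in the source table imply an unstated
per-range rescaling, so the package reports per-unit odds ratios and does
not assert equality with those printed values; the Surface-vs-Buried odds
ratios (0.09 / 0.11 / 0.15) are per-unit and are asserted.

**Selection.** Backward step-down removes, one per iteration, the term with
the largest significance while it exceeds the significance-to-stay
threshold (`sls`, default 0.13 for the main reduction and 0.16 inside
leave-one-out folds).  The burial factor moves as a block; a block's
significance is its joint Wald chi-square over its informative contrasts,
which reduces to the individual Wald test for single-column terms.  The
joint test is what lets a factor with one strong and one quasi-separated
contrast survive while a weaker single-column term is dropped — the
ordering the published model sequence exhibits.

**Validation.** Harrell optimism correction: the apparent model is selected
and scored on the full data; each of `n_boot` resamples (simple,
non-stratified, redrawn and counted if an outcome class vanishes) repeats
the *entire* step-down selection, is scored on itself (train) and on the
original data (test); optimism is the mean train−test difference and
`corrected_C = apparent_C − optimism`.  Calibration uses the same resampling
scheme on a fixed term set, correcting the observed-frequency-per-
predicted-probability-bin curve (10 equal-width bins) by the mean per-bin
train−test difference; empty bins propagate as NaN rather than being
interpolated.  The C-statistic is computed by midranks, which is identical
to the all-pairs count with ties at half credit, and equals the trapezoidal
area under the package's ROC curve by construction.

## Clinical utility

Net benefit at risk threshold p_t is TP/N − FP/N · p_t/(1−p_t), calling LFS
when the predicted probability reaches p_t, on a default grid of 0.01–0.99
in steps of 0.01; treat-all and treat-none references use their closed
forms (treat-all crosses zero exactly at the prevalence).  The nomogram
maps each variable's contribution β·value over its observed range affinely
to points, anchoring the minimum-contribution end at 0 and scaling so the
widest span runs 0–100; total points invert through the logistic to a
probability.  Because every map is affine in the linear predictor, the
nomogram probability equals the model probability up to floating-point
error (asserted at 0.01).  The quasi-separated `unknown` contrast is
excluded; its exact printed point values depend on unpublished variable
ranges and are reproduced only up to this consistency property.

## Synthetic data

The cohort generator emulates the *statistical shape* of the 48-variant
study cohort: 24 LFS + 24 HBC; burial drawn per class (P(Buried) 0.55 for
LFS vs 0.15 for HBC, with a small `unknown` probability of 0.04);
`comp_dif` and `PPI6_dif` drawn from class-conditional normals with
positive LFS-minus-HBC shifts (+12 sd 40 and +80 sd 400 on their natural
scales); the remaining nine difference scores are standard-normal noise in
both classes, with no correlation structure.  The shift sizes are
calibration constants chosen so the median apparent C of the three-variable
fit across replicates sits near 0.8, the discriminability the real cohort
shows; they are not estimates of the real (unpublished) score
distributions.  Alternatively, supplying true logistic coefficients makes
the generator draw features from pooled mixtures and outcomes from the
model — the parameter-recovery configuration.

What the generator deliberately does **not** emulate: the spatial
clustering of variants along the sequence, correlations among the eleven
predictors (the real disorder scores are strongly mutually correlated),
linkage between burial and the continuous scores, and any realistic TP53
sequence context.  Passing tests on synthetic cohorts therefore demonstrate
that the machinery is correct and well calibrated under the assumed
generating process, not that the real cohort's effect sizes are recoverable
from real predictor outputs.

Toy structures (isolated atom, distant pair, tight 30-atom cluster,
two-chain contact) are deterministic geometric fixtures; the cluster's
2.0 Å grid packs tighter than van-der-Waals contact precisely so its centre
drops below the 11 Å² burial cutoff at that size.

## Problem sizes and budgets

The test suite keeps simulations at sizes where the asserted properties are
statistically decisive: parameter recovery uses n = 5000 over 20 seeded
runs; optimism-direction experiments use 10–12 cohorts of n = 48 with 200
bootstrap replicates; type-I error uses 1000 null draws; Fisher-vs-oracle
equality is exhaustive for table totals ≤ ~20 and randomly sampled up to
60; calibration identity uses n = 3000 so per-bin binomial noise sits well
below the asserted 0.1 band.  The full pipeline example runs with
`n_boot = 30–200`; production-style runs use the 1000-replicate default.

## Limitations

* The reference crystal structure (PDB 3TS8) is not redistributable inside
  the package; geometry claims tied to it (the ~30% buried fraction, the
  DNA-contact residue list, the cohort's exact enrichment p-value) can only
  be recomputed with a local copy under `data/`, and the corresponding
  check fails without it.
* The per-variant predictor scores of the original cohort are in the
  paper's supplementary appendix, not bundled; the printed C-statistics
  (0.78–0.84), correct-prediction counts and the specific four-variable
  selection are therefore checked as machinery properties on synthetic
  cohorts rather than as numeric reproductions.
* Whether the printed C-statistics are apparent or bootstrap-corrected is
  ambiguous in the source; the validation report always carries both.
* The `unknown` burial coefficient is a quasi-separation artefact and
  should never be interpreted; predictions for `unknown` residues under
  refitted models lean entirely on the continuous variables.
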