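# Methods notes

This note records the modelling assumptions, parameter defaults, numerical
choices and known limitations of `connfp`, in the spirit of a package
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Scope and assumptions

The pipeline starts from spatially normalized 4-D volumes on a common grid:
motion correction, slice timing, coregistration and nonlinear normalization
are assumed done upstream and are deliberately out of scope. All spatial
reasoning uses 0-based voxel indices internally; millimetre coordinates
exist only through the NIfTI affine.

## Preprocessing

* **Volume dropping.** Default 5 initial frames (110 → 105), matching the
  acquisition design the defaults emulate.
* **Confound design.** Friston-24 = [m(t), m(t)², m(t−1), m(t−1)²] for the
  six realignment parameters, with the lagged row at t = 0 zero-padded;
  plus white-matter and CSF means and polynomial trend columns of order 0
  (intercept) through `poly_order` (default 1 — the linear choice is a
  convention; the trend order is genuinely underdetermined by the design
  this mirrors). Trend columns are Chebyshev-style scaled time in [−1, 1]
  for conditioning. Constant-zero columns are pruned and logged; remaining
  rank deficiency is an error that names the collinear columns (QR with
  pivoting). Global-signal regression is intentionally absent: the design
  lists WM/CSF only.
* **Band-pass.** Ideal rectangular DFT filter, 0.01–0.1 Hz, retaining bins
  with low ≤ f ≤ high and removing DC whenever low > 0. Chosen over a
  Butterworth because it is the resting-state toolbox convention this
  pipeline mirrors and because it is an orthogonal projection — idempotent
  and therefore directly testable (Parseval identities, eigenfunction
  behaviour of in-band sinusoids).
* Both cleaning steps are projections; the fixed order is
  drop → regress → filter. Voxels left with zero variance are removed from
  the analysis mask (correlations would be undefined) and counted in logs.

## Weighted degree centrality

`raw_i = Σ_{j≠i, r_ij > 0.25} r_ij` over in-mask voxels. The threshold is
strict (r > 0.25, not ≥), only positive correlations contribute, and the
self-correlation is excluded. The engine standardizes each series to unit
norm and accumulates block × all-voxel correlation panels (`block_size`
rows at a time, default 1024), so the full V×V matrix is never
materialized; peak extra memory is O(V · block_size). z-scoring is across
in-mask voxels (exact mean 0 / sd 1 before smoothing); smoothing is applied
**after** standardization, with per-axis sigma FWHM/(2√(2 ln 2))/voxel-size
so anisotropic voxels (3×3×4 mm default) are honoured. Smoothing uses a
sampled, 4σ-truncated Gaussian with nearest-edge padding, which keeps
constant maps exactly constant.

## Single-case normative inference

Crawford–Howell: t = (x − x̄_c)/(s_c √((N+1)/N)), df = N − 1, two-tailed p.
This is the canonical frequentist "modified t-test" for one case against a
small normative sample; with the study-sized N = 18 the suite verifies its
type-I error empirically at α = .005. ROI binarization follows the
"any significant voxel" rule: a voxel counts when p < α (default .005)
**and** t > 0 — the increase direction is required because only increased
hubness enters the downstream model; significant decreases are tallied
separately but never used. No voxel-level multiplicity correction is
applied within ROIs, mirroring the per-voxel-threshold-then-any-voxel
summarization this implements; α is exposed as a parameter. Percentages in
the cohort table are printed to one decimal.

## Outcome model

Outcome coding is 1 = seizure-free throughout, and the coding is printed in
every summary (reported coefficient signs are meaningless without it).
Maximum likelihood is computed by Newton/IRLS (statsmodels `Logit`,
log-likelihood tolerance 1e-8, 100 iterations); when Newton collapses under
quasi-complete separation the engine falls back to BFGS and **flags** the
fit (`separation=True`, triggered by non-convergence, a failed Hessian, or
|B| > 15 on indicator/count features) instead of raising — with 12
predictors and n = 30 separation is the expected regime, and the stepwise
removal tests remain well-defined because they compare log-likelihoods of
refitted reduced models. Backward elimination removes, at each step, the
predictor whose 1-df likelihood-ratio removal test has the largest p while
that p exceeds 0.10 (the conventional backward-LR default of the software
family this mirrors); constant columns are dropped upfront; the removal
order is logged on the results object.

Fit indices: X² = −2(LL0 − LL1); Cox–Snell R² = 1 − exp(−X²/n); Nagelkerke
R² rescales by its maximum 1 − exp(2·LL0/n). Hosmer–Lemeshow groups sorted
predicted probabilities into (by default) deciles of risk with ties kept
together; with few distinct fitted values (binary designs give ≤ 4) the
group count shrinks automatically, and below 3 effective groups the
statistic is reported with the p-value suppressed. The classification
cutoff is fixed at 0.5 (exposed as a flag). AUC is computed as the
Mann–Whitney concordance with ties credited ½; the ROC curve itself comes
from scikit-learn and the trapezoidal integral of that curve equals the
Mann–Whitney value on every fixture (tested identity).

## Group statistics

One-/two-sample pooled-variance t maps (zero-variance voxels get t = 0 and
a flag), one-tailed cluster-forming threshold (default p < .005), connected
components at 6/18/26-connectivity (default 18, the face+edge convention),
minimum extent 20 voxels. Family-wise correction uses the permutation
distribution of the **maximum cluster size** — group-label permutations for
two samples, sign flips for one sample, exhaustive enumeration whenever the
permutation group is smaller than `n_perm` (logged). This replaces the
parametric random-field/FDR cluster corrections of SPM-family software: it
is assumption-light, self-contained and has the same decision structure;
it is a deliberate deviation and its family-wise error is verified
empirically in the suite. Corrected p = (1 + #{null ≥ observed})/(n_perm+1)
for sampled permutations, the exact proportion for enumerated ones.

## Synthetic cohorts

The generator emulates the study conditions the package targets: 18
controls, 30 patients, 110 volumes at TR 2 s, 3×3×4 mm voxels. Voxel series
follow x_v(t) = λ_v·s_R(t) + a·g(t) + σ·ε_v(t) with a unit-variance latent
s_R shared within each anatomical region, a low-amplitude global signal
(a = 0.1) and white noise (σ = 1), so the expected within-hub correlation
is λ²/(λ²+σ²); the default hub loading λ = 1 puts it at 0.5. Latents are
band-limited to 0.01–0.1 Hz by default so planted effects survive the
band-pass (the option can be switched off, and the analytic correlation
tests do so). Baseline regional loading is 0.2 — weak local
synchronization well below the wDC threshold — and the rest-of-brain
compartment carries **no** shared latent: a single coherent background
region would give every background voxel thousands of partners whose sample
correlations cross r = 0.25 by estimation noise alone (only ~100 frames),
burying any genuine hub under background degree. The toy atlas is twelve
mirror-symmetric rectangular parcels (two per ROI per hemisphere) inside an
interior brain box, with small rest-of-brain gaps between adjacent ROI
sections whenever the grid allows: the any-voxel binarization is applied to
8-mm-smoothed maps, and without gaps a hub's smoothing skirt would leak
into the neighbouring ROI, so recovery scores would measure kernel bleed
rather than the method. Gaps shrink to zero at the minimum 8×8×8 grid,
where all twelve parcels are still non-empty.

Hub assignment is exact-count: each configured hub (default: ipsilateral
mesial and ipsilateral pole, prevalence 0.5, i.e. 15 of 30 patients each)
is assigned to round(prevalence·n) patients by a seeded permutation, so
ground-truth marginals are exact. Outcomes are Bernoulli with
logit P(SF) = −1.5 + 2.0·mesial + 1.5·pole by default — directionally the
association the method is meant to detect, with magnitudes chosen once as a
strong but not deterministic effect (per-patient P(SF) spans 0.18–0.88).
One master seed spawns independent per-subject substreams, so any subject
is reproducible in isolation and cohorts never need to be held in memory.

What the generator does **not** emulate: hemodynamic convolution, scanner
drift and spike artefacts, motion-correlated signal, spatial noise
autocorrelation, grey/white tissue contrast, and realistic anatomy.
Passing recovery tests therefore show that the implementation recovers its
own generative model under study-sized samples and noise — not that the
effect sizes or operating characteristics transfer to real cohorts.

## Problem sizes in the test suite

The suite exercises the full design at its native scale where that is the
point (18 + 30 subjects on a 24×24×16 grid for hub recovery; 20,000 null
cases for single-case calibration; 200 replicates × 200 permutations for
cluster-level error control; 200 replicates at n = 300 for coefficient-sign
recovery) and uses smaller grids/cohorts for orchestration and determinism
checks, keeping the default run lightweight.

## Known limitations

* The headline cohort statistics of the study design this mirrors (76.7%
  correct classification, AUC 0.777, B = −2.88/−2.91) depend on unpublished
  patient-level data and an unprinted intercept; they cannot be recomputed
  and the package does not attempt to. The two fit indices that *are*
  analytically determined by printed quantities (Cox–Snell and Nagelkerke
  R² from χ² = 15.19, n = 30, a 14/16 split) are recomputed in
  `scripts/acceptance.py`.
* Whether the original ROI "increase" classification required t > 0 or used
  |t| is not documented; this implementation requires t > 0.
* Correlation targets are all in-mask voxels (whole brain), not grey matter
  only.
* Smoothing is plain convolution, not mask-renormalized; near mask edges
  z-values are shrunk toward zero.
* The stepwise procedure is reported as-is, in-sample; no cross-validation
  or shrinkage is offered, matching the analysis it reproduces.
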