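# Methods

## What the pipeline computes

`insulafc` analyzes resting-state BOLD runs with a fixed seed-based
functional-connectivity (FC) workflow:

1. **Cleaning** (`preprocess`): discard the first `n_discard` volumes
   (default 5), smooth each volume with a Gaussian kernel (default 8 mm
   FWHM), band-pass filter every voxel time course to 0.01–0.08 Hz, and
   regress out 15 nuisance time series (6 motion parameters + 9
   physiological covariates) plus an intercept.
2. **ROI atlas** (`atlas`): twenty insular seeds, ten per hemisphere in
   three horizontal planes, each the 7-voxel digital ball of radius 1
   (center + 6 face neighbors; 189 mm³ at 3 mm isotropic). Indices carry a
   fixed subregion convention: anterior {1, 2, 4, 5, 8}, posterior
   {3, 7, 10}, transitional {6, 9}. ROI signals are unweighted means of the
   7 voxel time courses.
3. **FC statistics** (`connectivity`): the 20×20 Pearson matrix over ROI
   signals; the **integration score** per hemisphere — Pearson correlation
   between the averaged anterior-ROI signal and the averaged posterior-ROI
   signal (transitional ROIs excluded), with its Fisher transform
   z = atanh(r); and voxel-wise **seed maps** — per-voxel partial
   correlation between a seed signal and the voxel series controlling the
   15 nuisance regressors through a GLM, r = t/√(t² + df) from the seed
   coefficient, two-sided p from the t distribution with
   df = T − (number of regressors).
4. **Thresholding** (`connectivity.threshold_map`):
   Benjamini–Hochberg FDR at α (default 0.05) over in-mask voxels, then
   removal of connected components whose size fails the extent rule.
   The extent rule is *strictly greater than* k = 20 by default (a 21-voxel
   cluster survives, a 20-voxel cluster does not), with `>=` available
   because neuroimaging toolchains disagree on the convention.
   Component connectivity defaults to 26-neighborhoods (6/18 available).
5. **Group inference** (`group`): spatial-consistency maps — per voxel, the
   percentage of subjects whose significance mask covers it (12 of 30 →
   40%); pooled two-sample t tests on Fisher-z values (df = n₁ + n₂ − 2);
   per-edge group tests with BH-FDR over the 190 ROI pairs; Pearson
   brain–behavior correlations with p from t = r√((n−2)/(1−r²)).
6. **Behavior** (`behavior`): Elo expected score
   E(d) = 1/(1 + 10^(−d/400)) — the base-10/400 logistic is the unique
   standard form reproducing the conventional 64% at +100 and 76% at +200
   rating points; Pearson chi-square independence tests; group-matching
   summaries (mean ± SE + tests) for phenotype tables.

Group comparisons of correlations are always performed on Fisher-z values,
whose sampling distribution is approximately normal, which justifies the
pooled t test.

## The synthetic cohort generator

No public scanner data accompany this design, so validation runs on a
generator (`cohort`) that plants the statistical structure the analysis is
supposed to detect, on a small synthetic grid (default 20×24×20 voxels,
3 mm isotropic, 255 volumes at TR = 2 s; a 510 s scan).

**Latent model.** Each subject has an anterior ("A") and a posterior ("P")
network latent signal, band-limited to 0.01–0.08 Hz (white noise filtered
with the analysis band-pass and standardized) and correlated at the
subject's planted coupling ρ. Band-limited latents are the realistic
choice for slow hemodynamic fluctuations; white latents would concentrate
power in the filter's stopband and be discarded by the cleaning they are
supposed to survive. Each signal site (the 20 insular ROIs plus eight
extra-insular A-/P-network nodes) receives
u = √w·S + √(1−w)·ε, where S is the site's network latent (anterior ROIs →
A, posterior → P, transitional → normalized (A+P)/√(2(1+ρ))), ε is an
independent band-limited noise, and w = `rho_within` (default 0.9). The
implied population correlation between the averaged anterior and averaged
posterior ROI signals is then
wρ/√(((1+4w)/5)·((1+2w)/3)) ≈ 0.97ρ at the default w, reported per subject
as `rho_implied` alongside the planted `rho_latent`.

**Per-subject coupling.** Group-level couplings default to
`rho_ap_expert = 0.6` and `rho_ap_amateur = 0.3` (a planted difference of
0.3). Each subject's own ρ is drawn N(group ρ, `rho_sd`²) with
`rho_sd = 0.12`, truncated to (−0.95, 0.95). A scalar per-group coupling
would make recovery-versus-ground-truth correlations degenerate (zero
between-subject variance), and real cohorts vary; the draw is returned as
ground truth for recovery tests.

**Nuisance structure.** Voxel noise is AR(1) Gaussian (φ = 0.3, unit
marginal SD) plus low-frequency drift (linear trend and a 160 s cosine,
random per-voxel amplitudes), so the band-pass has real content to remove.
The 15 confounds (motion = slow random walks, physiological = AR(1)
series) leak additively into every voxel with random N(0, 0.3²) loadings,
so nuisance regression measurably changes FC.

**Phenotypes.** Weekly play time (AT) is calibrated to the study groups:
expert mean 46.67 h/week (SE 2.1 over n = 27), amateur 14.2 (SE 1.1 over
n = 30); SDs are SE·√n. For experts only, AT is coupled to the planted ρ
with slope `at_effect` = 40 h/week per unit ρ, which yields an
AT–integration correlation around 0.4 at the default spread — the order of
magnitude reported for experience–connectivity correlations in this
literature. Expert Elo ratings are uniform on [1900, 2600]; the amateur
Elo distribution is unspecified beyond an upper bound, so amateurs draw
uniform on [800, 1200) (a documented assumption). Optional grey-matter
volumes are tabular only (no morphometry is computed); the left
long-insular-gyrus/central-sulcus value carries a planted group offset and
a coupling-linked component.

**What the generator does not emulate:** hemodynamic response convolution,
scanner artifacts and spatial inhomogeneity, anatomical geometry (the grid
is not a template space; the default ROI layout is synthetic, not
anatomical), subject motion as an image transformation (motion enters only
as confound time series), and left/right lateralization of the planted
effect (both hemispheres share the same latents). Passing tests therefore
demonstrate that the statistical machinery recovers planted effects of
realistic size under realistic temporal structure — not that the pipeline
is robust to acquisition artifacts it never sees.

## Numerical choices

- **Band-pass filter**: Butterworth of even order (default 4) designed at
  half order and applied forward–backward (zero phase), preserving
  correlation structure; the residual finite-length mean is removed
  exactly. Regressors are passed through the same filter before nuisance
  regression (`residualize_first`, configurable) so regression cannot
  reintroduce filtered frequencies.
- **Smoothing**: separable Gaussian, σ = FWHM/(2√(2 ln 2)) converted to
  voxels per axis, reflective boundaries (conserves total intensity to
  well under 0.1% on these grids).
- **mm→voxel mapping**: nearest voxel with ties broken toward −∞
  (ceil(x − 0.5)); the affine origin sits at the central voxel so
  hemispheric mirroring is exact on the default layout.
- **Rank-deficient designs**: collinear regressor columns are dropped
  keep-first with a warning; the intercept is always retained.
- **Degenerate inputs**: zero-variance signals, empty masks, and
  non-finite phenotypes raise typed errors naming the offending ROI,
  column, or block rather than propagating NaNs. Identical constant groups
  define t = 0, p = 1 instead of 0/0.
- **Determinism**: per-subject random streams derive from
  (master seed, subject index), so cohorts are bitwise reproducible and
  single subjects can be regenerated independently.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run the full generator →
cleaning → integration → group-test path on 20 (tests) / 10 (script)
seeded replicates of the default 27 + 30 cohort at full scan length
(255 volumes, 250 retained). The null-calibration study uses reduced
cohorts (15 + 15 subjects, 150 volumes) across 30 (tests) / 12 (script)
replicates — a deliberate scale-down for the Monte-Carlo loop: the
false-positive rate of a between-subject t test does not depend on cohort
size, only its Monte-Carlo error does. The voxel-wise seed-map and
consistency stage is exercised end-to-end on a 14 + 15 cohort with two
posterior seeds.

## Known limitations

- Per-subject seed-map significance uses parametric t-distribution p
  values; temporal autocorrelation surviving the band-pass makes the
  effective df smaller than T − p, so per-voxel p values are liberal.
  This mirrors common practice for this workflow; the FDR + extent rule
  and the population consistency map are the intended safeguards.
- Whether per-subject FC networks use partial correlations or raw GLM
  betas is a design fork in this literature; partial correlation is
  implemented (betas are recoverable from the same fit).
- The chi-square statistic for the game-type contingency table computed
  here (≈20.0 for counts 27/0/0 vs 14/4/12) is the package's own Pearson
  computation; summary tables in the source literature round differently
  and are not exactly reconstructible from printed counts.
- The equal-variance pooled t test is the default (df = n₁ + n₂ − 2, the
  convention consistent with df = 55 for 27 + 30 subjects); Welch's test
  is available via `two_sample_t(..., equal_var=False)` but is not wired
  into the pipeline-level contrasts.
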