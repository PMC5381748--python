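# insulafc

Seed-based resting-state functional connectivity (FC) of insular
subregions, packaged as a tested, reusable pipeline with a synthetic-cohort
generator for end-to-end validation.

## The problem

The insula divides into anterior subregions tied to an attentional network
(A-network) and posterior subregions tied to a sensorimotor network
(P-network), with a transitional zone between them. Studies of intensive
sensorimotor training — action-video-game expertise is the motivating
example — compare expert and amateur groups on how strongly these
subregions couple at rest, and on whether that coupling tracks behavioral
experience measures such as weekly play time (AT) or Elo-type skill
ratings. `insulafc` provides the full analysis chain for such designs:

- **ROI atlas** — twenty insular seeds (10 per hemisphere, three
  horizontal planes, left–right mirrored), each a 7-voxel near-sphere
  (center + 6 face neighbors; 189 mm³ at 3 mm isotropic voxels).
- **BOLD cleaning** — discard initial volumes, 8 mm FWHM Gaussian
  smoothing, 0.01–0.08 Hz zero-phase band-pass, regression of 15 nuisance
  time series (6 motion + 9 physiological).
- **Insular functional integration** — per hemisphere, the Pearson
  correlation r between the averaged anterior-ROI signal (ROIs 1, 2, 4, 5,
  8) and the averaged posterior-ROI signal (ROIs 3, 7, 10), compared
  between groups on Fisher-z values with a pooled two-sample t test
  (df = n₁ + n₂ − 2).
- **Seed maps** — voxel-wise partial correlation between a seed signal and
  every voxel, controlling nuisance regressors in a GLM
  (r = t/√(t² + df)), thresholded per subject with Benjamini–Hochberg FDR
  (p < 0.05) and a cluster-extent rule (components must exceed k = 20
  voxels).
- **Spatial consistency** — population probability maps: the percentage of
  subjects whose significance mask covers each voxel (12 of 30 → 40%).
- **Group & behavior statistics** — edgewise FC group tests with FDR over
  the 190 ROI pairs, Pearson brain–behavior correlations, group-matching
  summaries, chi-square tests, and the Elo expected score
  E(d) = 1/(1 + 10^(−d/400)).

Because no public scanner data accompany this design, the package ships a
first-class synthetic cohort generator that plants a known
anterior–posterior coupling per subject (experts 0.6, amateurs 0.3 by
default, with between-subject spread), realistic AR(1)+drift noise,
confound leakage, and experience phenotypes coupled to the planted effect
in experts only — so every downstream stage can be validated against
ground truth. See `docs/methods.md` for the model and its limits.

## Worked example

```python
from insulafc import (
    CohortConfig, PipelineConfig, run_pipeline,
)

config = PipelineConfig(
    cohort=CohortConfig(n_expert=27, n_amateur=30, seed=7),
    do_seed_maps=False,          # skip the voxel-wise stage for speed
)
result = run_pipeline(config)
print(result.group_tests[["hemisphere", "t", "df", "p"]].to_string(index=False))
```

prints

```
hemisphere        t  df            p
         L 7.109077  55 2.499515e-09
         R 7.620879  55 3.627590e-10
```

i.e. with the default planted couplings (expert 0.6 vs amateur 0.3) the
pipeline recovers a strong expert > amateur integration difference in both
hemispheres on 55 pooled degrees of freedom. The per-subject integration
scores live in `result.integration`; correlating the recovered Fisher-z
values with the generator's ground truth (`result.cohort.ground_truth`)
gives r ≈ 0.86 at default noise.

The same pipeline runs from the shell:

```sh
insulafc simulate --n-expert 27 --n-amateur 30 --seed 7 --out cohort/
insulafc run --cohort-dir cohort/ --out results/
insulafc elo 100        # -> 64.0%
```

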