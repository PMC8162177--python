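# prefcorr3d

Reverse correlation of facial-attractiveness preferences in a generative 3D
face space.

## The problem

What makes a face attractive to a particular observer?  Classic accounts say
attractive faces are close to the population **average**, or that they
exaggerate **sexual dimorphism** (femininity/masculinity).  A data-driven
alternative is to *measure* each observer's preference directly: show many
randomly generated faces, collect attractiveness ratings, and regress the
stimulus parameters on the ratings.  The fitted slopes form a multivariate
preference model — a direction in face space along which faces look more
attractive to that observer — which can then be tested against the
averageness and dimorphism accounts, decomposed into cultural versus
individual components, and validated by predicting held-out ratings.

This package implements that entire pipeline for a *synthetic* generative
face space, so every stage runs end-to-end with a recoverable ground truth
and no data download.  It is aimed at researchers in computational
psychophysics and social perception who want a tested, reusable reference
implementation of the method, and a simulation harness for power and
calibration analyses.

## The model

A face is a categorical average (one per ethnicity × sex cell) plus an
identity residual through orthonormal bases: one basis for 3D shape (vertex
displacements) and one basis per spatial-frequency band for L\*a\*b\*
complexion.  For each observer and each stimulus dimension *j* the package
fits, by robust linear regression (bisquare IRLS),

&nbsp;&nbsp;&nbsp;&nbsp;coefficient*ⱼ* = β₁ⱼ + β₂ⱼ · rating

The β₂ map is the observer's preference model.  Downstream analyses:

- **Local models** — the same regression per vertex coordinate and pixel
  channel, with joint Benjamini–Hochberg FDR masks.
- **Linearity check** — rating-binned mean faces, per-vertex signed
  deviations, k-means cluster centroids against the bin-1→bin-5 line.
- **MI cross-check** — Gaussian-copula mutual information per dimension,
  signed by the regression slope.
- **Dimorphism test** — the cosine between the reduced-dimension β₂ and the
  female-minus-male direction, tested against a bootstrap self-similarity
  null.
- **Representation space** — PCA over vectorized individual models; per
  component the variance of model scores splits as
  R²<sub>group</sub> = 1 − SS₁/SS₀ and
  R²<sub>participant</sub> = SS₁/SS₀ · (1 − SS₂/SS₁),
  with permutation-null significance thresholds.
- **Validation** — 13-fold cross-validated Gamma GLM (log link) predicting
  ratings from attractiveness-space scores, scored by Kendall τ against
  averageness and dimorphism predictors.

## Worked example

```python
import numpy as np
import prefcorr3d as pc
from prefcorr3d.raters import expected_slope_direction

space   = pc.build_generative_space(seed=7)          # desk-scale face space
stimuli = pc.synthesize_stimuli(space, 1950, seed=8) # shared random faces

rng = np.random.default_rng(9)
w_shape, w_comp = pc.random_preference(space, rng)   # planted preference
rater = pc.make_participant(space, "demo", "WE", "WE",
                            w_shape, w_comp, snr=2.0, seed=10)
rated = pc.simulate_ratings(rater, stimuli, space)

model  = pc.fit_preference_model(rated, "demo", "WE_same")
target = expected_slope_direction(space, w_shape, w_comp)
b = model.concat_beta2()
print(f"recovery cosine vs planted preference: "
      f"{b @ target / (np.linalg.norm(b) * np.linalg.norm(target)):.3f}")

direction = pc.compute_dimorphism_direction(space, "WE")
res = pc.cosine_similarity_test(rated, model, direction,
                                domain="shape", n_boot=200, seed=11)
print(f"cosine(attractiveness, dimorphism) = {res.cosine:+.3f}, "
      f"self-similarity CI = [{res.ci_low:.3f}, {res.ci_high:.3f}], "
      f"different from dimorphism: {res.significant}")
```

Output:

```
recovery cosine vs planted preference: 0.991
cosine(attractiveness, dimorphism) = +0.364, self-similarity CI = [0.991, 1.000], different from dimorphism: True
```

The fitted β₂ direction recovers the planted preference almost exactly
(cosine 0.991 at 1,950 trials and drive signal-to-noise 2), and the
bootstrap cosine test correctly concludes that this observer's preference
direction is not an exaggeration of sexual dimorphism (observed cosine 0.36,
far below the 2.5th percentile of the model's own bootstrap stability).

The full pipeline — cohort simulation, model fitting, group models, feature
analyses, the representation space with variance decomposition, and
cross-validated prediction — runs from one config:

```bash
prefcorr3d run-all --seed 0 --out runs/demo    # summary in runs/demo/summary.json
```

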