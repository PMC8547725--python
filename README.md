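# flowparse

Apparatus for studying **object-speed perception during visually simulated
self-motion**. When an observer is moved through a scene, the retinal motion
of a target mixes the target's own motion with the optic flow caused by
self-motion; *flow parsing* is the visual system's subtraction of the
self-motion component. This package implements the computational machinery
of a two-interval forced-choice (2IFC) speed-discrimination experiment
probing how completely that subtraction happens, and at what cost in
precision:

- **kinematics** — deterministic trial geometry: the Gaussian self-motion
  profile (position = cumulative Gaussian in time, mean 0.25 s, SD 0.08 s,
  0.5 m displacement, hence a 1 m/s mean speed), the symmetric initial
  target placement `x_init = ½ (D_observer − v_x t)`, and the target's mean
  retinal angular speed.
- **staircase** — PEST adaptive staircases as a deterministic state machine
  (initial step 1.2 m/s, fixed steps on trials 1–5, reversal halving from
  trial 11, same-answer maintenance/doubling rules, convergence = five
  consecutive steps < 0.1 m/s after ≥ 20 trials, hard stop at 27).
- **observers** — synthetic cumulative-Gaussian observers:
  `P("comparison faster" | v) = Φ((v − PSE)/σ)` with PSE = ⅔ of the
  standard speed, ±0.125 m/s self-motion bias, σ = 10 % of the PSE inflated
  ×1.25 under self-motion, N(1, 0.1) per-participant multipliers, and
  Cauchy(1, 0.04) stimulus-strength ratios (55 trials per cell) or live
  staircase-driven sessions.
- **preprocess** — the exclusion pipeline (wrong-button trials, diverged
  staircase pairs, the self-motion rating criterion).
- **psychofit** — per-cell maximum-likelihood cumulative-Gaussian fits
  (PSE = accuracy, σ = precision proxy).
- **probit** — hierarchical probit regression with subject-level random
  effects (Laplace-approximate marginal likelihood), likelihood-ratio model
  comparison, parametric-bootstrap CIs, and compensation percentages.
- **effects** — per-participant decomposition models:
  `PSE = PSE_static + E_self·C_self + E_induced·C_induced` and
  `SD = SD_static + E_self·C_self + E_retinal·R`, fitted by RMSE
  minimization from zero.
- **power** — the simulation-based power analysis: simulate cohorts from
  the generative model, run both model comparisons, tabulate the fraction
  of significant likelihood-ratio tests per participant count.

## Worked example

Simulate an eight-participant synthetic experiment and run the full
analysis chain (the `analysis/` scripts do the same in numbered steps):

```sh
python analysis/01_simulate_sessions.py --n-participants 8 --seed 5
python analysis/02_preprocess.py
python analysis/03_fit_psychometric.py
python analysis/04_model_comparisons.py
python analysis/05_effect_models.py
```

which prints, for seed 5:

```
fitted 144 cells; 144 converged
  opposite: mean PSE 4.99 m/s, mean SD 0.517 m/s
      same: mean PSE 4.79 m/s, mean SD 0.519 m/s
    static: mean PSE 4.91 m/s, mean SD 0.450 m/s
main/precision: chi2(1) = 3.07, p = 0.07977
main/accuracy: chi2(2) = 14.31, p = 0.0007813
       effect_selfmotion: mean +0.1348, median +0.1415
          effect_induced: mean +0.0560, median +0.0476
```

Reading this: the generative observers place the point of subjective
equality (PSE) near ⅔ of the 6.6/8 m/s standards, shifted down for
same-direction self-motion and up for opposite-direction, with inflated
psychometric SDs whenever self-motion is simulated — and the analysis
recovers exactly that pattern. The accuracy model comparison detects the
PSE shift even at 8 participants (p < 0.001); the precision comparison,
a slope effect, needs larger cohorts (see the power analysis). The fitted
`effect_selfmotion` (≈ 0.13 m/s) recovers the generative ±0.125 m/s bias.

A `flowparse` console command exposes the same steps
(`simulate`, `preprocess`, `fit`, `infer`, `model`, `power`, `report`).

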