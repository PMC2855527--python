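# Methods

## Dynamical models

Sixteen named models describe two-gene (or one-gene control) circuits in
dimensionless units: concentrations of order one, time in units of the
degradation timescale. Every equation has the form
*production − linear degradation*; production is either linear in its
regulator (SIM/RC/FF/FB and the flagella control) or a Hill function
`f+(s; theta, h) = s^h/(theta^h + s^h)` / its repressive complement
`f- = 1 − f+`, composed at two-input promoters through a gate:

* **AND**: `g = f_S · f_y` (both inputs required);
* **OR**: `g = f_S + f_y − f_S·f_y`, the probabilistic sum. The exact
  OR algebra used in the literature this family of models comes from is
  not published; the probabilistic sum is used because it stays in
  [0, 1], is monotone in each input and reduces to Boolean OR at
  saturation. The gate is one function (`motifs.gate`) and is trivially
  replaceable.

Structural choices that were genuinely open and how they were fixed:

* **FB** — the feedback motif's y-equation is modelled as end-product
  repression, `dy/dt = beta_y·S·f-(z; theta_zy, 2) − alpha_y·y`, with the
  repression threshold estimated. This gives FB five penalised
  parameters, consistent with the AIC and pD bookkeeping of the
  four-motif study.
* **Cooperative variants (`.H`)** — every regulatory input is passed
  through a Hill function with fixed theta = 0.5, h = 2; for FF the Hill
  terms sit symmetrically on both inputs of z.
* **Hill constants** — h = 2 everywhere and never estimated; theta = 0.5
  wherever a model does not estimate thresholds (all data generation,
  and the `.H` variants). The FF subtypes estimate their three
  thresholds with the same prior as the rates, which is what makes the
  AND/OR/incoherent parameterisations distinguishable at all.
* **Delay models** — `FF.C1.OR.2` delays the promoter's read of the
  intermediate regulator (y(t − tau)); `FF.C1.OR.3` additionally delays
  the S→y read. Pre-initial history is constant: states frozen at their
  initial value, the input frozen at the level that preceded the step
  (`s_pre`), without which a delayed read would be uninformative under a
  constant-per-step input.

## Synthetic data

The generator reproduces the two study designs and is the package's only
data source:

* **Motif grid** — input S steps through {0, 1, 2, 0} at t = {0, 2, 6, 10};
  both variables observed at 30 equally spaced points on [0, 10]
  (60 records); all generating rates 1.
* **FF designs** — ON/OFF step experiments with canonical initial
  conditions (ON: S = 1, states at 0; OFF: S = 0, states at 1); only the
  target z observed, y hidden; record counts 30+30 (arabinose-like),
  20+17 (flagella-like), 15 ON-only (galactose-like). The duration of
  each step is not part of the published designs; 10 dimensionless time
  units per step is used so the responses both saturate and relax, and
  it is configurable.

Observation noise is additive, independent, homoscedastic Gaussian with
SD 0.05 on all variables — about 5% of the response amplitude. Every
simulation takes an explicit seed and is bit-reproducible; experiment
drivers derive per-dataset and per-chain seeds from a master seed by
fixed offsets.

What the generator does *not* emulate: extrinsic/intrinsic biological
noise (the dynamics are deterministic), heteroscedastic or correlated
measurement error, irregular sampling, normalisation artefacts, and the
unit conversions of real reporter assays. A passing test suite therefore
demonstrates that the statistics identify the right architecture *when
the model class contains the truth and the error model is correct*, not
that they would do so on any laboratory dataset.

## Inference

The likelihood is Gaussian: `log p(Y|theta, sigma^2) = sum_records
log N(y; z(t; theta), sigma^2)`. Sampling operates on
`x = [log theta_1..p, log sigma^2]`:

* **Priors** — log-normal(mean 0, SD 1 in log space) on every rate,
  threshold and delay (a weakly informative prior centred on 1 in the
  model's units, shared across models so evidence comparisons are fair);
  inverse-gamma(shape 0.5, scale 0.05) on sigma^2 (heavy-tailed, no
  mean, mode 0.1/3). Log densities include the change-of-variables
  Jacobian, so they are proper densities of x.
* **Sampler** — random-walk Metropolis, Gaussian proposals. During
  burn-in only, a scalar step size is tuned towards ~30% acceptance
  every 200 iterations and, from iteration 1000, the proposal takes the
  shape of the empirical covariance of the second half of the burn-in
  draws (2.38²/d scaling). Adaptation freezes at the end of burn-in, so
  retained draws come from a fixed kernel. Chains start from the prior
  centre jittered by N(0, 0.5²) per coordinate.
* **Protocols** — full: 5 chains × 40,000 iterations, burn-in 20,000,
  thinning 10 (10,000 retained draws); reduced (for quick studies and
  CI): 3 × 8,000 / 4,000 / 10. Convergence is checked with the classic
  Gelman–Rubin between/within statistic on the retained draws,
  threshold 1.05.
* **Failed solves** — any non-finite trajectory maps to log-likelihood
  −inf, i.e. automatic rejection; these events are counted per chain in
  the archive.
* **Frequentist counterpart** — Levenberg–Marquardt least squares on log
  parameters from several starts; unbiased noise estimate RSS/(N − p);
  95% Wald intervals from the Gauss–Newton Hessian, with a warning and
  no intervals when it is singular.

## Model comparison

* **Evidence** — Gelfand–Dey: `1/p(Y|M) ≈ mean_s h(x_s) / (p(Y|x_s)
  p(x_s))` over posterior draws, with h a multivariate t fitted to the
  draws (location = mean, scale = covariance, 4 degrees of freedom —
  heavy tails keep the ratio bounded; the dof is exposed). Computed with
  log-sum-exp; the Monte-Carlo SE comes from 20 contiguous batches and
  is reported with every estimate. A singular draw covariance is
  ridge-regularised (1e-8·I) with a warning; if every draw has
  non-finite density the estimate is flagged −inf.
* **DIC/pD** — `D-bar` averages −2 log-likelihood over the draws;
  `D(theta-bar)` plugs in the *natural-scale* posterior means (the
  geometric-mean alternative is available via ``log_scale_mean=True``).
  pD is meaningful when the plug-in point is representative; with hidden
  states and weakly identified thresholds (the FF-subtype fits) the
  natural-scale mean can sit far from the posterior mass and pD goes
  strongly negative — DIC instability that the report surfaces rather
  than hides.
* **AIC/LRT parameter counts** exclude the noise variance: p counts
  rates + estimated thresholds + delays (SIM/RC 4, FF/FB 5, FF subtypes
  7, delay models 8, controls 4/2/4). The LRT applies only to the nested
  pairs recorded in the registry (SIM ⊂ FF, RC ⊂ FF, RC ⊂ FB,
  OR.1 ⊂ OR.2/OR.3); a slightly negative statistic from sampler noise is
  clamped to zero with a warning.
* **Ties** — evidence differences below one log unit are flagged as
  ties; the report notes the pragmatic fewer-parameters preference but
  does not enforce it.

## Numerics

* **Reference integration** — `scipy.integrate.solve_ivp` (LSODA,
  rtol 1e-8/atol 1e-10), integrating segment-by-segment between input
  breakpoints so discontinuities never cross a solver step.
* **In-sampler integration** — a numba-compiled fixed-step RK4 over a
  node grid containing all observation times and breakpoints, sub-step
  ≤ 0.02 time units. For these smooth, mildly stiff systems the global
  error is orders of magnitude below the observation noise; the test
  suite pins the kernel against solve_ivp for every model and against
  exact piecewise-exponential solutions for the linear motifs
  (relative error ≤ 1e-6). Proposals with degradation rates extreme
  enough to destabilise RK4 produce non-finite values and auto-reject —
  such draws are deep in the prior tail and carry no posterior mass.
* **Delay models** — their cascade structure (y never depends on z)
  means y is piecewise-exponential in closed form; the scalar z equation
  is integrated with the exact linear one-step map, the forcing frozen
  at sub-step midpoints (default sub-step 0.002 for reference, 0.01
  inside MCMC) and evaluated as a linear recurrence via
  `scipy.signal.lfilter`. No method-of-steps loop is needed, and tau = 0
  reduces exactly to the undelayed model.

## Problem sizes used in the shipped checks

The full 5 × 40,000 protocol is used for the headline single-fit
quantities (evidence, pD, convergence). Grid-style checks — ranking
recovery across five master seeds and credible-interval coverage across
20 replicates per motif — use the reduced protocols, which the ranking
statistics tolerate well because they compare models on a common dataset.

## Known limitations

* The evidence estimator assumes a roughly unimodal posterior in log
  space; strongly multimodal posteriors would need bridge/path sampling
  or reversible-jump machinery, deliberately out of scope.
* pD/DIC are unstable whenever the plug-in mean is unrepresentative (see
  above); they are reported, not repaired.
* Only the sixteen registry models are supported — this is a study
  artifact, not a general ODE-inference framework; stochastic dynamics
  (SDE/Gillespie) are out of scope.
* The real E. coli time series behind the original arabinose/flagella/
  galactose experiments are not shipped; externally digitised series can
  be supplied through the CSV reader, but no loader for the original
  publications exists.
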