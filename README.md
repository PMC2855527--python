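# motifcompare

Statistical model comparison for small gene-regulatory network motifs.

Transcription networks are built from recurring circuits — the single
input motif (SIM), the regulatory chain (RC), the feed-forward loop (FF)
and negative feedback (FB) — but a time series rarely pins down the
architecture by eye: several candidate ODE models are usually compatible
with the data. `motifcompare` turns that question into a formal model
comparison exercise. It simulates time-course data from motif models,
infers their kinetic parameters by Markov chain Monte Carlo, and ranks
candidate architectures with both Bayesian and frequentist yardsticks.

## The model and the statistics

Each motif is a small ODE/DDE system driven by an experimentally
controlled input S(t), e.g. for the feed-forward loop

```
dy/dt = beta_y * S            - alpha_y * y
dz/dt = beta_zs * S + beta_zy * y - alpha_z * z
```

with Hill-regulated variants `f+(s; theta, h) = s^h / (theta^h + s^h)`
(and the repressive complement `f-`) composed through AND/OR promoter
gates for the coherent and incoherent FF subtypes, optionally with a
transcriptional time delay tau. Observations are the solutions plus
i.i.d. Gaussian noise, `y_ki ~ N(z_k(t_i; theta), sigma^2)`.

Inference and comparison:

* **Posterior sampling** — adaptive random-walk Metropolis on
  `[log theta, log sigma^2]`; log-normal(0, 1) priors on all kinetic
  parameters, inverse-gamma(0.5, 0.05) on sigma^2; five chains of
  40,000 iterations (burn-in 20,000, thinning 10) in the full protocol;
  convergence monitored with the Gelman–Rubin statistic.
* **Model evidence** p(Y|M) — Gelfand–Dey reciprocal importance sampling
  over the posterior draws with a multivariate-t auxiliary density;
  Bayes factors `BF = p(Y|M_i)/p(Y|M_j)` with the usual interpretation
  scale (>1 weak, >3 substantial, >10 decisive, >100 overwhelming).
* **DIC** `= D-bar + pD` with the effective parameter count
  `pD = D-bar − D(theta-bar)`.
* **Maximum likelihood** (best stored draw, and a least-squares fit with
  Hessian confidence intervals), **AIC** `= −2 log L_max + 2p`, and
  **likelihood-ratio tests** for nested pairs (SIM ⊂ FF, RC ⊂ FF, RC ⊂ FB).

## Worked example

```python
import motifcompare as mc

data = mc.simulate_motif_dataset("SIM", seed=42)   # 60 noisy records
res = mc.MotifModel(data, "SIM").fit(mc.REDUCED_CONFIG, seed=42)
print(res.summary())
```

```
Model SIM: 60 records, 3 chains x 8000 iterations (burn-in 4000, thinning 10) -> 1200 draws
------------------------------------------------------------------------
parameter         mean        sd      2.5%     97.5%   R-hat
beta_y          1.0058    0.0712    0.8761    1.1536   0.999
alpha_y         1.0012    0.0823    0.8573    1.1687   0.999
beta_z          0.9859    0.0654    0.8687    1.1232   1.000
alpha_z         0.9817    0.0770    0.8449    1.1436   1.001
sigma2          0.0034    0.0007    0.0024    0.0049   1.002
------------------------------------------------------------------------
max log-likelihood     107.57    AIC    -207.14  (p = 4)
log evidence (GD)       72.86    MC se 0.033
DIC    -196.12    pD   3.89    mean deviance -200.01
acceptance rates: [0.26 0.27 0.26]
```

All four generating rates (true value 1) are recovered inside the 95%
credible intervals, every R-hat is below 1.05, and pD ≈ 3.9 says the
four kinetic parameters are identified while the heavy-tailed noise
prior contributes almost nothing. Adding the nesting FF model shows the
expected tie — its extra branch cannot be estimated from SIM data:

```python
ff = mc.MotifModel(data, "FF").fit(mc.REDUCED_CONFIG, seed=43)
report = mc.rank_models({"SIM": res, "FF": ff})
print(report); print(report.lrt_table())
```

```
                    SIM         FF
log_evidence      72.86      74.81
dic             -196.12    -196.30
pd                 3.89       3.62
max_loglik       107.57     107.89
aic             -207.14    -205.79

  simple complex  statistic  df    pvalue
0    SIM      FF   0.650443   1  0.419954
```

The evidences differ by under two log units (a tie — a pragmatic reader
keeps the smaller model) and the LRT finds the extra FF parameter
unnecessary (p = 0.42).

Whole studies run from one call or from the shell:

```sh
motifcompare run --study motif_grid --seed 1 --out out/ --preset reduced
motifcompare simulate --model ara --seed 1 --out ara.csv
motifcompare fit --model FF.C1.AND --data ara.csv --chains 5 --iters 40000 \
    --burn 20000 --thin 10 --seed 1
```

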