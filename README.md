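# hlos — hierarchical Bayesian length-of-stay modelling

Hospital length of stay (LoS) after cardiac bypass surgery is positive and
strongly right-skewed: most patients leave within ten days, a few stay many
weeks. Models that pool all patients regress toward the modal stay and
flatten that dispersion. `hlos` is a reusable pipeline for studying this
problem on synthetic cardiac-surgery cohorts: it generates registry-like
tables with known structure, prepares them leakage-free, selects features by
permutation importance, fits simple and hierarchical Bayesian truncated-
normal regressions by MCMC next to eight frequentist baselines, and reports
the comparison. It is aimed at biostatisticians and health-services
researchers who want a tested, fully seeded reference implementation of the
hierarchical approach — including the honest version of its test-time level
assignment — without access to any real registry.

## Model

With features `x` scaled to [0, 1] and LoS `y` in days, the simple Bayesian
model (SBM) is

    y_i ~ TruncNormal(β₀ + x_i'β, σ; lower = 0)

The hierarchical model (HBM) indexes each record by its LoS level — bins
[0,10), [10,20), [20,30), [30,∞) — and learns one intercept and coefficient
vector per level with shared hyperpriors (partial pooling):

    y_i       ~ TruncNormal(β₀[ℓᵢ] + x_i'β[ℓᵢ], σ; lower = 0)
    β[ℓ, j]   ~ Normal(μ_β, σ_β)          μ_β ~ Normal(0, 1)
    β₀[ℓ]     ~ Normal(μ₀, σ₀)            σ_β ~ HalfNormal(1)
    σ         ~ HalfNormal(5)

Posterior sampling uses a seeded differential-evolution ensemble MCMC
sampler (one independent ensemble per chain) with split-chain Gelman–Rubin
diagnostics. Feature selection is permutation importance against a
random-forest base model; evaluation covers RMSE, MAE, mean, sd, min, max,
coefficient of variation, adjusted R² and Taylor-diagram statistics. See
`docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

Run the full workflow on a 1200-patient synthetic cohort, comparing the two
Bayesian models with two of the baselines:

```python
from hlos import RunConfig, run

cfg = RunConfig(out_dir="runs/demo", seed=7, n_patients=1200,
                chains=4, draws=1000, tune=1500, base_model_trees=100,
                models=("sbm", "hbm", "random_forest", "lasso"))
out = run(cfg)
print((out / "report" / "metrics.txt").read_text())
```

which prints (actual row first, models by ascending test RMSE):

```
         name mean   sd  min  max   cv adj_r2 rmse  mae
       Actual 7.96 3.91    2   22 0.49      -    -    -
          HBM 7.89 3.08    6   20 0.39  66.36 2.12 1.71
random_forest 8.01 0.63    6   10 0.08 -11.04 3.86 3.02
          SBM 8.04 0.28    7    9 0.03 -13.58 3.90 3.09
        lasso 8.05 0.53    7   10 0.07 -14.99 3.93 3.08
```

Every model estimates the mean stay (~8 days) well, but only the
hierarchical model reproduces the spread of the outcome: its prediction sd
(3.08) approaches the actual 3.91, while the pooled models collapse to
0.3–0.6 and post negative adjusted R². The run directory also holds the
posterior (NetCDF), per-level coefficient tables, the importance report and
`models/hbm_diagnostics.json` — here `max_rhat 1.022` with 0 divergences,
i.e. the four chains agree. Predictions here use oracle-mode levels (the
level is taken from the observed stay, replicating the comparison this
package models); pass `level_mode="marginal"` for the leakage-free variant.

The same stages are available from the shell:

```sh
hlos simulate --mode realistic --n 5363 --seed 1 --out runs/c
hlos preprocess --in runs/c --seed 1 --out runs/p
hlos select --in runs/p --k 10 --seed 1 --out runs/s
hlos fit --in runs/p --model hbm --chains 4 --draws 3000 --tune 1000 --seed 1 --out runs/m
hlos run --config run.yaml
```

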