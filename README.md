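# semsgd

Estimation of linear **simultaneous-equation models (SEMs)** by viewing the
system as a masked single-layer linear network and training it with
mini-batch **stochastic gradient descent**, next to a from-scratch
**two-stage least squares (2SLS)** baseline and a seeded Monte-Carlo
harness that compares the two by out-of-sample mean squared error.

SEMs are the workhorse of econometrics and are increasingly used in
epidemiology and the health sciences wherever outcomes determine each
other simultaneously — employment and mental health, risk perception and
consumption habits, fiscal policy and inequality. The package is aimed at
applied statisticians who want (a) a clean, fully seeded implementation of
the network view of SEM estimation, (b) classical baselines with honest
identification checking, and (c) a reproducible simulation harness.

## The model

With `m` endogenous variables `y_1..y_m` and `k` exogenous variables
`x_1..x_k`, each equation writes one endogenous variable as a linear
combination of (some of) the others plus (some of) the exogenous
variables plus white noise:

```
y_i = Σ_{j≠i} B_ij y_j + Σ_r Γ_ir x_r + u_i,        i = 1..m
```

Some coefficients are known a priori to be zero; that sparsity pattern is
a `StructuralSpec` (boolean masks), the values a `StructuralParams`
(`B̃` m×m with zero diagonal, `Γ` m×k). The **reduced form** expresses
the system purely in terms of the exogenous block,

```
Y = X Π + V,     Π = Γᵀ (I − B̃ᵀ)⁻¹   (k×m),
```

and is what the synthetic generator simulates. Estimators:

* **OLS** (per equation, observed regressors) — the least-squares
  minimizer of the teacher-forced loss, biased under simultaneity;
* **2SLS** — stage 1 projects every endogenous variable on all `k`
  exogenous columns, stage 2 regresses each `y_i` on the fitted
  endogenous regressors plus its included exogenous columns; refused for
  equations failing the **order condition** (excluded exogenous ≥
  included endogenous) unless explicitly allowed;
* **SGD** — the same structural coefficients viewed as weights of a
  masked linear network, trained on the MSE
  `(1/(n·m)) ΣΣ (Y − Ŷ)²` with teacher-forced predictions by default,
  elementwise gradient clipping, and either a 2SLS warm start
  (`init="twostage"`) or small random weights (`init="random"`).

## Worked example

```python
from semsgd import (GenConfig, SGDConfig, fit_2sls, generate_instance,
                    mse, predict, sgd_fit, split, standardize, substream)

cfg = GenConfig(m=2, k=4, n=1000, sigma=0.1, seed=7)
spec, truth, data = generate_instance(cfg)          # random identified SEM
train, val = split(data, 0.7, rng=substream(cfg.seed, "split"))
train_s, (val_s,), scaler = standardize(train, [val])

fit = fit_2sls(spec, train_s)
sgd = sgd_fit(spec, train_s, SGDConfig(init="twostage", seed=1))

print("2SLS validation MSE (reduced form):   %.6f"
      % mse(val_s.Y, predict(fit.params, val_s.X, mode="reduced")))
print("SGD  validation MSE (teacher-forced): %.6f"
      % mse(val_s.Y, predict(sgd.params, val_s.X, mode="structural",
                             Y_observed=val_s.Y)))
```

prints

```
2SLS validation MSE (reduced form):   0.000122
SGD  validation MSE (teacher-forced): 0.000240
```

Both scores are on the standardized (z-scored) scale; at `sigma=0.1` the
reduced-form fit is nearly exact, while the teacher-forced score carries
the structural disturbance `U = V(I − B̃ᵀ)` and is somewhat larger. The
same pipeline from the shell:

```bash
semsgd simulate --m 2 --k 4 --n 1000 --sigma 0.1 --seed 7 \
       --out data.csv --params model.json
semsgd fit --method 2sls --data data.csv --spec model.json --out fit.json
# estimated B̃[0,1] = 6.7337  vs  true 6.7277
semsgd benchmark --config examples/bench.yaml --out report.csv --plots figs/
```

`examples/bench.yaml` declares the grid (or `grid: paper` for the default 12-cell
design `{(2,4),(10,20),(20,40)} × σ∈{0.1,1.0} × n∈{100,1000}`), the SGD
configurations, the repetition count and the master seed.

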