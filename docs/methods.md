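# Methods

## Model and conventions

A linear simultaneous-equation model (SEM) with `m` endogenous and `k`
exogenous variables is stored as a sparsity structure (which coefficients
are a-priori zero) plus the free coefficient values `B̃` (m×m, zero
diagonal) and `Γ` (m×k). Two equivalent matrix forms exist in the
literature: the explicit form `Y = Y B̃ᵀ + X Γᵀ + U` and the implicit form
`Y Bᵀ + X Γᵀ + U = 0` with `B = B̃ − I`. We store only `B̃` and derive `B`
on demand; this removes the recurring sign/diagonal ambiguity between the
two notations. The reduced form is `Y = X Π + V` with
`Π = Γᵀ(I − B̃ᵀ)⁻¹` and `V = U(I − B̃ᵀ)⁻¹ᵀ`-structured noise.

No intercepts appear anywhere (generation, estimation, prediction); users
wanting a constant add a constant column to `X`. `(I − B̃ᵀ)` is declared
ill-conditioned above condition number 1e6 and the algebra refuses to
proceed, surfacing the condition estimate in the error.

## Identification

The order condition is applied per equation: with `m_i` included
endogenous regressors and `k_i` included exogenous variables, the
equation is identified only if `k − k_i ≥ m_i` (instruments at least as
numerous as the endogenous regressors they must replace). The classic
two-equation textbook system in which equation 2 excludes no exogenous
variable fails this condition; 2SLS refuses it by default, and
`allow_underidentified=True` opts into a minimum-norm stage-2 solution
with a logged warning. The order condition is necessary, not sufficient;
rank failures surface as rank-deficiency errors at solve time.

## Estimators

**OLS** solves each equation's least-squares problem on the observed
included regressors. **2SLS** regresses every endogenous variable on the
full instrument set (all `k` exogenous columns) in stage 1, then runs
per-equation OLS on fitted endogenous plus included exogenous columns.
Both use an SVD-based least-squares factorization (`numpy.linalg.lstsq`)
rather than normal-equations inversion; uniform-[0, 10] coefficient
systems routinely produce designs where the Gram matrix loses half the
available precision. Rank tolerance is the lstsq default
(machine-epsilon scaled). External instruments are not supported: the
exogenous block is the instrument set.

## The network view and the SGD trainer

The SEM is a single-layer linear network: exogenous variables are input
neurons, endogenous variables output neurons, coefficients are weights,
and a-priori-zero coefficients are masked connections. Training
minimizes the batch MSE `(1/(b·m)) ΣΣ (y − ŷ)²`.

* **Training target.** Default is the teacher-forced structural
  prediction: each equation sees the *observed* values of the other
  endogenous variables, matching the network wiring in which the output
  neurons exchange signals. This loss is convex (per-equation least
  squares) with the OLS solution as its unique minimizer on full-rank
  designs — the yardstick used by the convergence tests. A `target="reduced"`
  switch trains the pure X→Y map instead, with gradients pushed
  analytically through `Π = Γᵀ(I − B̃ᵀ)⁻¹` (`dΠ = Π dB̃ᵀ (I − B̃ᵀ)⁻¹`).
* **Hyperparameters.** Learning rate 0.01 with 5000 iterations (the
  companion setting 1e-5 pairs with 10000 iterations), batch size 32,
  elementwise gradient clipping at ±0.5 applied after the gradient
  computation and before the update, no early stopping, no momentum or
  adaptive variants. An "iteration" is one weight update from one
  mini-batch, sampled uniformly without replacement within the batch and
  independently across iterations (no epoch structure).
* **Initialization.** `twostage` starts at the 2SLS solution exactly
  (the warm start reported to work best); `random` draws free weights
  i.i.d. Normal(0, 0.1²) — a conventional small-weight choice that keeps
  large-coefficient systems from diverging at the first step. `twostage`
  is the default.
* **Masks and determinism.** Gradients at masked entries are zeroed and
  masked weights are re-zeroed after every update, so a-priori-zero
  coefficients are exactly 0.0 at all times. All randomness (init,
  batching) comes from named sub-streams of one seed; identical
  (seed, config, data) gives bit-identical fits and traces.
* **Divergence guard.** A non-finite batch loss aborts training with the
  iteration index rather than returning garbage.

## Synthetic design

The generator emulates the benchmark conditions: free coefficients
i.i.d. Uniform[0, 10]; `X` rows i.i.d. multivariate normal with mean zero
and identity covariance (the minimal reading of "multivariate normal");
`V ~ Normal(0, σ²)` elementwise with σ ∈ {0.1, 1.0}; `Y = XΠ + V`;
n ∈ {100, 1000}; model shapes (m, k) ∈ {(2,4), (10,20), (20,40)}.

Which coefficients are zero is a free design choice: each candidate
entry is included independently with probability 0.5 (`p_endo`,
`p_exo`), and the mask is resampled until every equation passes the
order condition and has at least one regressor — guaranteeing the 2SLS
baseline is feasible, which the comparison presupposes. Coefficient
draws are resampled until `cond(I − B̃ᵀ) ≤ 1e6`; without the guard,
uniform-[0, 10] endogenous blocks at m = 20 occasionally produce
near-singular systems whose reduced form overflows.

What the generator does **not** emulate: correlated or non-Gaussian
exogenous data, heteroskedasticity, structural-error covariance,
intercepts, misspecified masks, or real data of any kind. Passing tests
therefore demonstrate algorithmic correctness and estimator behaviour
under the stated stochastic design, not robustness on real datasets.

## Evaluation protocol

MSE is `(1/(n·m)) Σ_j Σ_i (Y_ij − Ŷ_ij)²` over a held-out set. The
harness supports two protocols:

* **unified** (default): one 70/30 split per repetition; every method
  fits on the train part and is scored on the same validation part, in
  both prediction modes (reduced-form, i.e. from `X` alone, and
  teacher-forced structural).
* **paper**: replicates an asymmetric historical design — 2SLS fits on
  the full dataset and is scored on a random size-300 subsample, SGD
  uses the 70/30 split. Provided for protocol replication; not a fair
  comparison.

Standardization (z-scoring with training-set statistics, identically
applied to held-out data) is on by default: on the raw uniform-[0, 10]
scale the endogenous block reaches magnitudes of 10²–10³, SGD at
learning rate 0.01 diverges, and MSEs are incomparable across grid
cells. Reported MSEs are therefore on the standardized scale; the report
settings record this, and a flag restores the raw scale. Averages and
standard deviations are across repetitions (population std; a single
repetition reports std 0 by convention). Per-cell failures are recorded
in the report's failure list, never silently dropped.

### Problem sizes used in the shipped checks

The test suite runs the full 12-cell grid with 10 repetitions at 500 SGD
iterations (a structural smoke of the protocol), and the full 5000-iteration
configuration on single cells; the acceptance script runs the full grid
at the complete 5000-iteration setting with 10 repetitions. These sizes
reproduce the protocol exactly while keeping a laptop run in minutes.

## Observed behaviour worth knowing

* Teacher-forced scores are systematically larger than reduced-form
  scores at small σ on this generator: the structural disturbance is
  `U = V(I − B̃ᵀ)`, and uniform-[0, 10] coefficients amplify `V` by one
  to two orders of magnitude. Consequently teacher-forced SGD does not
  generally undercut reduced-form 2SLS at (m, k) = (10, 20) — the
  benchmark reports the comparison rather than assuming a direction.
  For the largest shape (20, 40) at n = 100–1000 the ordering flips:
  stage-1 overfitting inflates the 2SLS score and SGD wins clearly.
* With σ = 0.1 the endogenous block is almost an exact linear function
  of `X`, so per-equation designs can be near-collinear and the
  teacher-forced Hessian nearly singular; gradient-descent convergence
  tests use σ = 1.0 data, where the noise keeps the design
  well-conditioned.

## Numerical choices

* Condition threshold 1e6 for `(I − B̃ᵀ)`; SVD condition number.
* Finite-difference gradient checks use central differences, step 1e-6,
  tolerance 1e-5 relative.
* Mask zeros are exact (`== 0.0`), not approximate, and asserted as such.
* Splits take `floor(n·fraction)` training rows; partitions are uniform
  over permutations and fully seeded.
* Seed derivation: PCG64 streams keyed by
  `SeedSequence([master, crc32(stream_name), ...])`, so stages are
  independently reproducible and adding a stage never perturbs existing
  streams.

## Limitations

Linear-in-parameters systems only; no latent-variable (covariance-based)
structural equation modelling, no time series or dynamics, no Bayesian
or full-information estimators (FIML/3SLS), no momentum or adaptive SGD
variants, no significance testing between methods, and no wall-clock
benchmarking. The `paper` protocol's 2SLS subsample score overlaps its
estimation data by design (it replicates the historical setup) and
should not be read as out-of-sample error.
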