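"""Seeded synthetic SEM generator.

Emulates the simulation design used throughout the benchmark: free
coefficients drawn Uniform[0, 10], exogenous data from a multivariate
normal (mean zero, identity covariance by default), and endogenous data
from the reduced form ``Y = X Pi + V`` with ``V ~ Normal(0, sigma^2)``,
sigma in {0.1, 1.0}, at sample sizes 100 and 1000.

Which coefficients are a-priori zero is a free choice of the design; here
each candidate entry is included independently with probability ``p_endo``
/ ``p_exo`` and the mask is resampled until every equation passes the
order condition, so the 2SLS baseline is always feasible.  Coefficient
draws are likewise resampled until ``(I - B_tilde')`` is acceptably
conditioned; uniform [0, 10] entries occasionally produce near-singular
systems whose reduced form would overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import GenerationError, UsageError
from .rng import substream
from .sem_core import (
    COND_LIMIT,
    Dataset,
    StructuralParams,
    StructuralSpec,
    to_reduced,
)

__all__ = [
    "GenConfig",
    "generate_spec",
    "generate_params",
    "generate_dataset",
    "generate_instance",
    "paper_grid",
]


@dataclass(frozen=True)
class GenConfig:
    """Knobs of the synthetic generator.

    Defaults reproduce the benchmark's conditions: coefficient range
    [0, 10], inclusion probability 0.5 per candidate coefficient, unit
    isotropic exogenous data, sigma = 0.1 noise, n = 1000 observations.
    """

    m: int = 2
    k: int = 4
    n: int = 1000
    sigma: float = 0.1
    coef_low: float = 0.0
    coef_high: float = 10.0
    p_endo: float = 0.5
    p_exo: float = 0.5
    cond_limit: float = COND_LIMIT
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_endo <= 1.0 and 0.0 <= self.p_exo <= 1.0):
            raise UsageError("inclusion probabilities must lie in [0, 1]")
        if not self.coef_low < self.coef_high:
            raise UsageError("need coef_low < coef_high")
        if self.sigma < 0:
            raise UsageError("sigma must be non-negative")
        if self.n < 2:
            raise UsageError("need n >= 2")
        if self.m < 1 or self.k < 1:
            raise UsageError("need m >= 1 and k >= 1")


def _masks_admissible(endo_mask: np.ndarray, exo_mask: np.ndarray) -> bool:
    """True iff every equation has >= 1 regressor and passes the order
    condition (excluded exogenous >= included endogenous)."""
    k = exo_mask.shape[1]
    m_i = endo_mask.sum(axis=1)
    k_i = exo_mask.sum(axis=1)
    return bool(np.all((m_i + k_i) >= 1) and np.all((k - k_i) >= m_i))


def generate_spec(cfg: GenConfig, rng: Optional[np.random.Generator] = None) -> StructuralSpec:
    """Draw a random sparsity structure; resample until admissible.

    Each off-diagonal entry of the endogenous mask is included with
    probability ``p_endo`` and each exogenous entry with ``p_exo``,
    independently.  Draws failing the order condition (or leaving an
    equation empty) are rejected, up to ``cfg.max_retries`` attempts.
    """
    rng = rng if rng is not None else substream(cfg.seed, "spec")
    offdiag = ~np.eye(cfg.m, dtype=bool)
    for _ in range(cfg.max_retries):
        endo = (rng.random((cfg.m, cfg.m)) < cfg.p_endo) & offdiag
        exo = rng.random((cfg.m, cfg.k)) < cfg.p_exo
        if _masks_admissible(endo, exo):
            return StructuralSpec(m=cfg.m, k=cfg.k, endo_mask=endo, exo_mask=exo)
    raise GenerationError(
        f"no admissible sparsity structure in {cfg.max_retries} draws for "
        f"m={cfg.m}, k={cfg.k}, p_endo={cfg.p_endo}, p_exo={cfg.p_exo}; "
        f"lower p_endo or raise k"
    )


def generate_params(
    spec: StructuralSpec,
    cfg: GenConfig,
    rng: Optional[np.random.Generator] = None,
) -> StructuralParams:
    """Draw free coefficients i.i.d. Uniform[coef_low, coef_high].

    ``Gamma`` is drawn once; ``B_tilde`` is redrawn until
    ``cond(I - B_tilde') <= cfg.cond_limit`` (up to ``max_retries``).
    Masked entries are exactly zero.
    """
    rng = rng if rng is not None else substream(cfg.seed, "params")
    G = np.zeros((spec.m, spec.k))
    G[spec.exo_mask] = rng.uniform(cfg.coef_low, cfg.coef_high, int(spec.exo_mask.sum()))
    eye = np.eye(spec.m)
    for _ in range(cfg.max_retries):
        B = np.zeros((spec.m, spec.m))
        B[spec.endo_mask] = rng.uniform(
            cfg.coef_low, cfg.coef_high, int(spec.endo_mask.sum())
        )
        if np.linalg.cond(eye - B.T) <= cfg.cond_limit:
            return StructuralParams(spec=spec, B_tilde=B, Gamma=G)
    raise GenerationError(
        f"no acceptably conditioned B_tilde in {cfg.max_retries} draws "
        f"(cond limit {cfg.cond_limit:.1e}); narrow the coefficient range"
    )


def generate_dataset(
    params: StructuralParams,
    cfg: GenConfig,
    rng: Optional[np.random.Generator] = None,
) -> Dataset:
    """Simulate ``n`` observations from the reduced form.

    ``X`` has i.i.d. standard-normal rows (identity covariance);
    ``V ~ Normal(0, sigma^2)`` elementwise; ``Y = X Pi + V``.
    """
    rng = rng if rng is not None else substream(cfg.seed, "data")
    Pi = to_reduced(params, cond_limit=cfg.cond_limit).Pi
    X = rng.standard_normal((cfg.n, params.spec.k))
    V = cfg.sigma * rng.standard_normal((cfg.n, params.spec.m))
    Y = X @ Pi + V
    return Dataset(
        X=X,
        Y=Y,
        meta={
            "sigma": cfg.sigma,
            "seed": cfg.seed,
            "n": cfg.n,
            "m": params.spec.m,
            "k": params.spec.k,
            "standardized": False,
        },
    )


def generate_instance(cfg: GenConfig):
    """Spec, params and dataset from one master seed (named sub-streams)."""
    spec = generate_spec(cfg)
    params = generate_params(spec, cfg)
    data = generate_dataset(params, cfg)
    return spec, params, data


def paper_grid(**overrides) -> list[GenConfig]:
    """The 12-cell benchmark grid: (m, k) in {(2, 4), (10, 20), (20, 40)}
    crossed with sigma in {0.1, 1.0} and n in {100, 1000}."""
    cells = []
    for m, k in [(2, 4), (10, 20), (20, 40)]:
        for sigma in (0.1, 1.0):
            for n in (100, 1000):
                cells.append(GenConfig(m=m, k=k, n=n, sigma=sigma, **overrides))
    return cells
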