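"""Classical per-equation baselines: structural-form OLS and 2SLS.

Both estimators are limited-information, equation-by-equation methods.
OLS regresses each endogenous variable directly on its included
regressors (biased under simultaneity but the least-squares minimizer of
the teacher-forced loss).  Two-stage least squares first regresses every
endogenous variable on *all* k exogenous columns (the instrument set) and
then, per equation, regresses the outcome on the fitted endogenous
regressors plus the included exogenous ones.

All solves go through a QR/SVD least-squares factorization rather than
explicit Gram-matrix inversion; uniform-[0, 10] designs are routinely
ill-conditioned enough for the difference to matter.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import EstimationError, IdentificationError
from .sem_core import (
    Dataset,
    StructuralParams,
    StructuralSpec,
    check_identification,
)

__all__ = ["FitResult", "fit_ols", "fit_2sls"]

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    """Estimated coefficients plus method metadata.

    ``trace`` is only populated by iterative methods: a list of
    ``(iteration, training_loss)`` pairs with strictly increasing
    iteration indices.
    """

    params: StructuralParams
    method: str  # "ols" | "2sls" | "sgd"
    trace: Optional[list] = None
    hyper: dict = field(default_factory=dict)
    timing: float = 0.0


def _lstsq_full_rank(A: np.ndarray, b: np.ndarray, what: str, allow_deficient: bool = False):
    """Least-squares solve that raises on rank deficiency unless allowed
    (then the minimum-norm solution is returned and a warning logged)."""
    theta, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < A.shape[1]:
        if not allow_deficient:
            raise EstimationError(
                f"rank-deficient design in {what}: rank {rank} < "
                f"{A.shape[1]} columns"
            )
        logger.warning(
            "rank-deficient design in %s (rank %d < %d); returning the "
            "minimum-norm least-squares solution",
            what,
            rank,
            A.shape[1],
        )
    return theta


def _assemble(spec: StructuralSpec, per_equation: list[np.ndarray]) -> StructuralParams:
    B = np.zeros((spec.m, spec.m))
    G = np.zeros((spec.m, spec.k))
    for i, theta in enumerate(per_equation):
        nb = spec.n_endo_included(i)
        B[i, spec.endo_mask[i]] = theta[:nb]
        G[i, spec.exo_mask[i]] = theta[nb:]
    return StructuralParams(spec=spec, B_tilde=B, Gamma=G)


def fit_ols(spec: StructuralSpec, data: Dataset) -> FitResult:
    """Per-equation ordinary least squares on the structural form.

    Equation ``i`` regresses ``y_i`` on the *observed* included endogenous
    and exogenous columns; excluded coefficients stay exactly zero.
    """
    t0 = time.perf_counter()
    thetas = []
    for i in range(spec.m):
        Z = np.hstack([data.Y[:, spec.endo_mask[i]], data.X[:, spec.exo_mask[i]]])
        thetas.append(_lstsq_full_rank(Z, data.Y[:, i], what=f"OLS equation {i}"))
    params = _assemble(spec, thetas)
    return FitResult(params=params, method="ols", timing=time.perf_counter() - t0)


def fit_2sls(
    spec: StructuralSpec,
    data: Dataset,
    allow_underidentified: bool = False,
) -> FitResult:
    """Two-stage least squares with the full instrument set.

    Stage 1 regresses every endogenous variable on all ``k`` exogenous
    columns, giving fitted values ``Yhat``.  Stage 2 regresses each
    ``y_i`` on the ``Yhat`` columns of its included endogenous regressors
    plus its included exogenous columns.

    Equations failing the order condition are refused with an
    :class:`IdentificationError` unless ``allow_underidentified`` is set,
    in which case the minimum-norm stage-2 solution is returned and a
    warning is logged.
    """
    t0 = time.perf_counter()
    bad = [s for s in check_identification(spec) if s.status == "underidentified"]
    if bad and not allow_underidentified:
        detail = "; ".join(
            f"equation {s.equation}: {s.n_exo_excluded} excluded exogenous < "
            f"{s.n_endo_included} endogenous regressors"
            for s in bad
        )
        raise IdentificationError(f"order condition fails ({detail})")

    # Stage 1: project the endogenous block on the full instrument set.
    coef1 = _lstsq_full_rank(data.X, data.Y, what="2SLS stage 1")
    Yhat = data.X @ coef1

    thetas = []
    for i in range(spec.m):
        Z = np.hstack([Yhat[:, spec.endo_mask[i]], data.X[:, spec.exo_mask[i]]])
        thetas.append(
            _lstsq_full_rank(
                Z,
                data.Y[:, i],
                what=f"2SLS stage 2, equation {i}",
                allow_deficient=allow_underidentified,
            )
        )
    params = _assemble(spec, thetas)
    return FitResult(
        params=params,
        method="2sls",
        hyper={"allow_underidentified": allow_underidentified},
        timing=time.perf_counter() - t0,
    )
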