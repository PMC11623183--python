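"""Core representation of linear simultaneous-equation models (SEMs).

A linear SEM with ``m`` endogenous variables ``y_1..y_m`` and ``k``
exogenous variables ``x_1..x_k`` writes each endogenous variable as a
linear combination of (some of) the other endogenous variables and (some
of) the exogenous variables plus white noise::

    y_i = sum_{j != i} B_{ij} y_j + sum_r G_{ir} x_r + u_i

Some coefficients are known a priori to be zero; that sparsity structure
is the :class:`StructuralSpec` (boolean inclusion masks), while the free
coefficient values live in :class:`StructuralParams`.

Conventions
-----------
* ``B_tilde`` is the m-by-m endogenous coefficient matrix of the equation
  above, with a structurally zero diagonal (a variable never regresses on
  itself).  The implicit-form matrix ``B = B_tilde - I`` — the one
  appearing in ``Y B' + X G' + U = 0`` — is derived on demand via
  :meth:`StructuralParams.implicit_B` and never stored, which removes the
  usual sign/diagonal ambiguity between the two ways of writing the system.
* The reduced form expresses the endogenous block purely in terms of the
  exogenous one, ``Y = X Pi + V`` with ``Pi = G' (I - B_tilde')^{-1}``
  (k-by-m); equivalently ``Pi = -G' (B')^{-1}`` for the implicit form.
* No intercepts anywhere.  Users who want a constant add a constant
  column to ``X`` themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlgebraError, ShapeError, SpecificationError, UsageError

__all__ = [
    "StructuralSpec",
    "StructuralParams",
    "ReducedParams",
    "Dataset",
    "EquationIdentification",
    "build_spec",
    "to_reduced",
    "structural_residuals",
    "check_identification",
    "predict",
    "COND_LIMIT",
]

#: Condition-number threshold above which (I - B~') is declared ill-conditioned.
COND_LIMIT = 1e6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructuralSpec:
    """Sparsity structure of a linear SEM: which coefficients are free.

    Parameters
    ----------
    m
        Number of endogenous variables (equations).
    k
        Number of exogenous variables.
    endo_mask
        Boolean ``(m, m)``; entry ``(i, j)`` is True iff ``y_j`` appears as
        a regressor in equation ``i``.  The diagonal must be False.
    exo_mask
        Boolean ``(m, k)``; entry ``(i, r)`` is True iff ``x_r`` appears in
        equation ``i``.
    names
        Optional variable labels ``(y names..., x names...)``.
    """

    m: int
    k: int
    endo_mask: np.ndarray
    exo_mask: np.ndarray
    names: Optional[tuple] = None

    def __post_init__(self) -> None:
        m, k = int(self.m), int(self.k)
        if m < 1 or k < 1:
            raise SpecificationError(f"need m >= 1 and k >= 1, got m={m}, k={k}")
        endo = np.asarray(self.endo_mask, dtype=bool)
        exo = np.asarray(self.exo_mask, dtype=bool)
        if endo.shape != (m, m):
            raise SpecificationError(
                f"endo_mask must be {(m, m)}, got {endo.shape}"
            )
        if exo.shape != (m, k):
            raise SpecificationError(f"exo_mask must be {(m, k)}, got {exo.shape}")
        if np.any(np.diag(endo)):
            bad = np.flatnonzero(np.diag(endo))
            raise SpecificationError(
                f"endo_mask diagonal must be False (a variable cannot regress "
                f"on itself); offending equation(s): {bad.tolist()}"
            )
        empty = ~(endo.any(axis=1) | exo.any(axis=1))
        if np.any(empty):
            raise SpecificationError(
                f"equation(s) {np.flatnonzero(empty).tolist()} include no "
                f"regressor at all"
            )
        endo.setflags(write=False)
        exo.setflags(write=False)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "endo_mask", endo)
        object.__setattr__(self, "exo_mask", exo)

    # -- convenience -------------------------------------------------------

    def n_endo_included(self, i: int) -> int:
        """Number of endogenous regressors in equation ``i``."""
        return int(self.endo_mask[i].sum())

    def n_exo_included(self, i: int) -> int:
        """Number of exogenous regressors in equation ``i``."""
        return int(self.exo_mask[i].sum())

    def n_free(self) -> int:
        """Total number of free coefficients."""
        return int(self.endo_mask.sum() + self.exo_mask.sum())

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "k": self.k,
            "endo_mask": self.endo_mask.astype(int).tolist(),
            "exo_mask": self.exo_mask.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StructuralSpec":
        return cls(
            m=d["m"],
            k=d["k"],
            endo_mask=np.asarray(d["endo_mask"], dtype=bool),
            exo_mask=np.asarray(d["exo_mask"], dtype=bool),
        )

    def to_json(self, path: "str | Path | None" = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: "str | Path") -> "StructuralSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class StructuralParams:
    """Coefficient values for a :class:`StructuralSpec`.

    ``B_tilde`` is ``(m, m)`` with zero diagonal; ``Gamma`` is ``(m, k)``.
    Entries whose mask is False must be exactly zero.
    """

    spec: StructuralSpec
    B_tilde: np.ndarray
    Gamma: np.ndarray

    def __post_init__(self) -> None:
        m, k = self.spec.m, self.spec.k
        B = np.asarray(self.B_tilde, dtype=float)
        G = np.asarray(self.Gamma, dtype=float)
        if B.shape != (m, m):
            raise ShapeError(f"B_tilde must be {(m, m)}, got {B.shape}")
        if G.shape != (m, k):
            raise ShapeError(f"Gamma must be {(m, k)}, got {G.shape}")
        if not (np.all(np.isfinite(B)) and np.all(np.isfinite(G))):
            raise SpecificationError("coefficients must be finite")
        if np.any(B[~self.spec.endo_mask] != 0.0):
            raise SpecificationError(
                "B_tilde has nonzero entries at a-priori-zero (masked) positions"
            )
        if np.any(G[~self.spec.exo_mask] != 0.0):
            raise SpecificationError(
                "Gamma has nonzero entries at a-priori-zero (masked) positions"
            )
        B.setflags(write=False)
        G.setflags(write=False)
        object.__setattr__(self, "B_tilde", B)
        object.__setattr__(self, "Gamma", G)

    def implicit_B(self) -> np.ndarray:
        """The signed matrix ``B = B_tilde - I`` of the implicit form
        ``Y B' + X G' + U = 0`` (diagonal -1)."""
        return self.B_tilde - np.eye(self.spec.m)

    def free_vector(self) -> np.ndarray:
        """Free coefficients flattened (B entries first, then Gamma)."""
        return np.concatenate(
            [self.B_tilde[self.spec.endo_mask], self.Gamma[self.spec.exo_mask]]
        )

    @classmethod
    def from_free_vector(
        cls, spec: StructuralSpec, theta: np.ndarray
    ) -> "StructuralParams":
        nb = int(spec.endo_mask.sum())
        B = np.zeros((spec.m, spec.m))
        G = np.zeros((spec.m, spec.k))
        B[spec.endo_mask] = theta[:nb]
        G[spec.exo_mask] = theta[nb:]
        return cls(spec=spec, B_tilde=B, Gamma=G)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = self.spec.to_dict()
        d["B_tilde"] = self.B_tilde.tolist()
        d["Gamma"] = self.Gamma.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StructuralParams":
        return cls(
            spec=StructuralSpec.from_dict(d),
            B_tilde=np.asarray(d["B_tilde"], dtype=float),
            Gamma=np.asarray(d["Gamma"], dtype=float),
        )

    def to_json(self, path: "str | Path | None" = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: "str | Path") -> "StructuralParams":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class ReducedParams:
    """Reduced-form coefficients ``Pi`` (k-by-m) of ``Y = X Pi + V``."""

    Pi: np.ndarray

    def __post_init__(self) -> None:
        Pi = np.asarray(self.Pi, dtype=float)
        Pi.setflags(write=False)
        object.__setattr__(self, "Pi", Pi)


@dataclass
class Dataset:
    """Paired observation matrices ``X`` (n-by-k) and ``Y`` (n-by-m).

    ``meta`` carries provenance: noise scale sigma, RNG seed, whether the
    data have been standardized, and anything the producing stage records.
    """

    X: np.ndarray
    Y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if X.shape[0] != Y.shape[0]:
            raise ShapeError(
                f"X and Y must share a row count; got {X.shape[0]} vs {Y.shape[0]}"
            )
        if X.shape[0] < 1:
            raise ShapeError("datasets need at least one observation")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ShapeError("X and Y must be finite")
        self.X, self.Y = X, Y

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @property
    def m(self) -> int:
        return self.Y.shape[1]

    def take(self, rows: np.ndarray, **meta_updates) -> "Dataset":
        """Row-subset copy (used by splitting and subsampling)."""
        meta = {**self.meta, **meta_updates}
        return Dataset(X=self.X[rows].copy(), Y=self.Y[rows].copy(), meta=meta)

    # -- CSV round trip: columns y1..ym then x1..xk, one row per observation

    def to_csv(self, path: "str | Path") -> None:
        cols = [f"y{i + 1}" for i in range(self.m)] + [
            f"x{r + 1}" for r in range(self.k)
        ]
        df = pd.DataFrame(np.hstack([self.Y, self.X]), columns=cols)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: "str | Path", meta: Optional[dict] = None) -> "Dataset":
        df = pd.read_csv(path)
        ycols = [c for c in df.columns if c.startswith("y")]
        xcols = [c for c in df.columns if c.startswith("x")]
        if not ycols or not xcols:
            raise UsageError(
                f"{path}: expected columns named y1..ym and x1..xk, "
                f"got {list(df.columns)}"
            )
        return cls(
            X=df[xcols].to_numpy(float),
            Y=df[ycols].to_numpy(float),
            meta=dict(meta or {}),
        )


@dataclass(frozen=True)
class EquationIdentification:
    """Order-condition bookkeeping for one equation."""

    equation: int
    n_endo_included: int
    n_exo_excluded: int
    status: str  # underidentified | exactly_identified | overidentified


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_spec(
    m: int,
    k: int,
    endo_mask: Sequence,
    exo_mask: Sequence,
    names: Optional[Sequence[str]] = None,
) -> StructuralSpec:
    """Validate and freeze a sparsity structure.

    Raises :class:`SpecificationError` on a self-loop (True diagonal in
    ``endo_mask``), an equation with no regressors, or shape mismatches.
    """
    return StructuralSpec(
        m=m,
        k=k,
        endo_mask=np.asarray(endo_mask, dtype=bool),
        exo_mask=np.asarray(exo_mask, dtype=bool),
        names=tuple(names) if names is not None else None,
    )


def to_reduced(params: StructuralParams, cond_limit: float = COND_LIMIT) -> ReducedParams:
    """Reduced-form coefficients ``Pi = Gamma' (I - B_tilde')^{-1}``.

    Raises :class:`AlgebraError` when ``I - B_tilde'`` is singular or its
    condition number exceeds ``cond_limit``.
    """
    m = params.spec.m
    A = np.eye(m) - params.B_tilde.T
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > cond_limit:
        raise AlgebraError(
            f"(I - B_tilde') is singular or ill-conditioned: "
            f"condition estimate {cond:.3e} exceeds limit {cond_limit:.1e}"
        )
    # Pi' = A^{-1}' Gamma'' => solve A' Pi'... solve on the right: Pi = G' A^{-1}
    Pi = np.linalg.solve(A.T, params.Gamma).T
    return ReducedParams(Pi=Pi)


def structural_residuals(params: StructuralParams, data: Dataset) -> np.ndarray:
    """Structural disturbances ``U = Y - Y B_tilde' - X Gamma'`` (n-by-m)."""
    spec = params.spec
    if data.m != spec.m or data.k != spec.k:
        raise ShapeError(
            f"data has (m={data.m}, k={data.k}) but spec expects "
            f"(m={spec.m}, k={spec.k})"
        )
    return data.Y - data.Y @ params.B_tilde.T - data.X @ params.Gamma.T


def check_identification(spec: StructuralSpec) -> list[EquationIdentification]:
    """Apply the order condition to every equation.

    Equation ``i`` with ``m_i`` included endogenous regressors and ``k_i``
    included exogenous variables is identified only if the number of
    excluded exogenous variables, ``k - k_i``, is at least ``m_i``:
    instruments must be as numerous as the endogenous regressors they
    replace.  Equality gives exact identification, surplus gives
    overidentification.
    """
    out = []
    for i in range(spec.m):
        m_i = spec.n_endo_included(i)
        excl = spec.k - spec.n_exo_included(i)
        if excl < m_i:
            status = "underidentified"
        elif excl == m_i:
            status = "exactly_identified"
        else:
            status = "overidentified"
        out.append(
            EquationIdentification(
                equation=i, n_endo_included=m_i, n_exo_excluded=excl, status=status
            )
        )
    return out


def predict(
    params: StructuralParams,
    X: np.ndarray,
    mode: str = "reduced",
    Y_observed: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Predict the endogenous block.

    mode="reduced"
        Solve the whole system: ``Yhat = X Pi`` using only ``X``.
    mode="structural"
        Teacher-forced one-step predictions: each equation is evaluated
        with the *observed* values of the other endogenous variables,
        ``yhat_i = sum_j B_tilde_{ij} y_j^obs + sum_r Gamma_{ir} x_r``.
        Requires ``Y_observed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.spec.k:
        raise ShapeError(f"X has {X.shape[1]} columns, spec expects {params.spec.k}")
    if mode == "reduced":
        return X @ to_reduced(params).Pi
    if mode == "structural":
        if Y_observed is None:
            raise UsageError("mode='structural' requires Y_observed (teacher forcing)")
        Y = np.atleast_2d(np.asarray(Y_observed, dtype=float))
        if Y.shape != (X.shape[0], params.spec.m):
            raise ShapeError(
                f"Y_observed must be {(X.shape[0], params.spec.m)}, got {Y.shape}"
            )
        return Y @ params.B_tilde.T + X @ params.Gamma.T
    raise UsageError(f"unknown prediction mode {mode!r}")
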