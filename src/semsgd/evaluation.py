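"""MSE metric, train/validation protocol, standardization, and the
Monte-Carlo benchmark harness comparing 2SLS against SGD.

The benchmark sweeps a grid of synthetic-model shapes, repeats each cell
``n_reps`` times with fresh models and data, and reports the average and
standard deviation of the validation MSE per (cell, method, init,
prediction mode).

Two protocols are shipped:

* ``unified`` (default): every method estimates on the same 70% training
  split and is scored on the same 30% validation split — a like-for-like
  comparison.
* ``paper``: replicates an asymmetric historical design in which 2SLS is
  fit on the full dataset and scored on a random size-300 subsample,
  while SGD uses the 70/30 split.

Standardization (per-column z-scoring with training-set statistics) is on
by default: uniform-[0, 10] coefficient systems put the endogenous block
on an enormous and cell-dependent scale, on which SGD at practical
learning rates diverges and MSEs are incomparable across cells.  Scores
are therefore on the standardized scale unless it is disabled.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import SemError, ShapeError, UsageError
from .estimators import fit_2sls
from .rng import derive_seed, substream
from .sem_core import Dataset, predict
from .sgd import SGDConfig, sgd_fit
from .synthetic import GenConfig, generate_instance, paper_grid

__all__ = [
    "mse",
    "split",
    "Scaler",
    "standardize",
    "EvalReport",
    "run_benchmark",
    "plot_report",
]


def mse(Y: np.ndarray, Yhat: np.ndarray) -> float:
    """Mean squared error over all observations and endogenous variables:
    ``(1/(n*m)) * sum_j sum_i (Y_ij - Yhat_ij)^2``."""
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    if Y.shape != Yhat.shape:
        raise ShapeError(f"shape mismatch: {Y.shape} vs {Yhat.shape}")
    if Y.size == 0:
        raise ShapeError("empty arrays")
    return float(np.mean((Y - Yhat) ** 2))


def split(
    data: Dataset,
    train_fraction: float = 0.7,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
):
    """Uniformly random partition into train (floor(n*fraction) rows) and
    validation; both parts must be nonempty."""
    if not 0.0 < train_fraction < 1.0:
        raise UsageError("train_fraction must lie strictly between 0 and 1")
    if rng is None:
        rng = substream(0 if seed is None else seed, "split")
    n = data.n
    n_train = int(np.floor(n * train_fraction))
    if n_train < 1 or n_train >= n:
        raise UsageError(
            f"degenerate split: {n_train} train rows out of {n}"
        )
    perm = rng.permutation(n)
    tr, va = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    return (
        data.take(tr, role="train", train_fraction=train_fraction),
        data.take(va, role="validation", train_fraction=train_fraction),
    )


@dataclass(frozen=True)
class Scaler:
    """Per-column z-scoring statistics computed on a training set."""

    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray

    def transform(self, data: Dataset) -> Dataset:
        meta = {**data.meta, "standardized": True, "scaler": self.to_dict()}
        return Dataset(
            X=(data.X - self.x_mean) / self.x_std,
            Y=(data.Y - self.y_mean) / self.y_std,
            meta=meta,
        )

    def inverse(self, data: Dataset) -> Dataset:
        meta = {**data.meta, "standardized": False}
        meta.pop("scaler", None)
        return Dataset(
            X=data.X * self.x_std + self.x_mean,
            Y=data.Y * self.y_std + self.y_mean,
            meta=meta,
        )

    def to_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_std": self.y_std.tolist(),
        }


def standardize(train: Dataset, others: Sequence[Dataset] = ()):
    """Z-score every column using *training-set* means and standard
    deviations; apply the same affine map to the held-out sets.

    Returns ``(scaled_train, [scaled_others...], scaler)``.  Raises on a
    zero-variance training column (naming it), since its scale is
    undefined.
    """
    x_std = train.X.std(axis=0)
    y_std = train.Y.std(axis=0)
    for label, stds in (("x", x_std), ("y", y_std)):
        dead = np.flatnonzero(stds == 0.0)
        if dead.size:
            raise UsageError(
                f"zero-variance training column(s) {label}"
                f"{(dead + 1).tolist()}: cannot standardize"
            )
    scaler = Scaler(
        x_mean=train.X.mean(axis=0),
        x_std=x_std,
        y_mean=train.Y.mean(axis=0),
        y_std=y_std,
    )
    return scaler.transform(train), [scaler.transform(d) for d in others], scaler


@dataclass
class EvalReport:
    """Benchmark output: one row per (cell, method, init, prediction mode)."""

    rows: list = field(default_factory=list)
    settings: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            "m",
            "k",
            "sigma",
            "n",
            "method",
            "init",
            "learning_rate",
            "prediction_mode",
            "avg_mse",
            "std_mse",
            "n_reps",
        ]
        return pd.DataFrame(self.rows, columns=cols)

    def to_csv(self, path: "str | Path") -> None:
        self.to_dataframe().to_csv(path, index=False)


def _score(params, val: Dataset, modes: Sequence[str]) -> dict:
    out = {}
    for mode in modes:
        yhat = predict(params, val.X, mode=mode, Y_observed=val.Y)
        out[mode] = mse(val.Y, yhat)
    return out


def run_benchmark(
    grid: Optional[Sequence[GenConfig]] = None,
    sgd_cfgs: Optional[Sequence[SGDConfig]] = None,
    n_reps: int = 10,
    protocol: str = "unified",
    master_seed: int = 0,
    standardize_data: bool = True,
    prediction_modes: Sequence[str] = ("reduced", "structural"),
    train_fraction: float = 0.7,
    subsample_size: int = 300,
) -> EvalReport:
    """Run the Monte-Carlo comparison and aggregate MSEs per cell.

    For every cell and repetition a fresh model (sparsity structure +
    coefficients) and dataset are generated from seeds derived from
    ``master_seed``, each method is fit, and validation MSE is recorded
    in each requested prediction mode.  Per-cell failures (e.g. a
    generation budget exhausted) are recorded in ``report.failures`` and
    the affected rows aggregate over the successful repetitions only.
    """
    if protocol not in ("unified", "paper"):
        raise UsageError(f"unknown protocol {protocol!r}")
    if n_reps < 1:
        raise UsageError("n_reps must be >= 1")
    if grid is None:
        grid = paper_grid()
    if sgd_cfgs is None:
        sgd_cfgs = [SGDConfig(init="twostage"), SGDConfig(init="random")]

    raw: dict[tuple, list[float]] = {}
    failures: list[dict] = []

    def record(cell: GenConfig, method: str, init: str, lr, mode: str, value: float):
        key = (cell.m, cell.k, cell.sigma, cell.n, method, init, lr, mode)
        raw.setdefault(key, []).append(value)

    for ci, cell in enumerate(grid):
        for rep in range(n_reps):
            rep_seed = derive_seed(master_seed, f"cell{ci}", f"rep{rep}")
            cfg = replace(cell, seed=rep_seed)
            cell_id = {"m": cell.m, "k": cell.k, "sigma": cell.sigma, "n": cell.n, "rep": rep}
            try:
                spec, params, data = generate_instance(cfg)
            except SemError as exc:
                failures.append({**cell_id, "stage": "generate", "error": str(exc)})
                continue

            try:
                train, val = split(
                    data, train_fraction, rng=substream(rep_seed, "split")
                )
                if standardize_data:
                    train_s, (val_s,), _ = standardize(train, [val])
                else:
                    train_s, val_s = train, val
            except SemError as exc:
                failures.append({**cell_id, "stage": "split", "error": str(exc)})
                continue

            # ---- 2SLS baseline -----------------------------------------
            try:
                if protocol == "unified":
                    fit = fit_2sls(spec, train_s)
                    scores = _score(fit.params, val_s, prediction_modes)
                else:  # paper: fit on the full data, score on a 300-row subsample
                    if standardize_data:
                        full_s, _, _ = standardize(data)
                    else:
                        full_s = data
                    fit = fit_2sls(spec, full_s)
                    size = min(subsample_size, full_s.n)
                    idx = substream(rep_seed, "subsample").choice(
                        full_s.n, size=size, replace=False
                    )
                    scores = _score(fit.params, full_s.take(idx), prediction_modes)
                for mode, v in scores.items():
                    record(cell, "2sls", "", None, mode, v)
            except SemError as exc:
                failures.append({**cell_id, "stage": "2sls", "error": str(exc)})

            # ---- SGD variants ------------------------------------------
            for scfg in sgd_cfgs:
                tag = (scfg.init, str(scfg.learning_rate))
                try:
                    run_cfg = replace(
                        scfg, seed=derive_seed(rep_seed, "sgd", *tag)
                    )
                    fit = sgd_fit(spec, train_s, run_cfg)
                    scores = _score(fit.params, val_s, prediction_modes)
                    for mode, v in scores.items():
                        record(
                            cell, "sgd", scfg.init, scfg.learning_rate, mode, v
                        )
                except SemError as exc:
                    failures.append(
                        {**cell_id, "stage": f"sgd[{scfg.init}]", "error": str(exc)}
                    )

    rows = []
    for (m, k, sigma, n, method, init, lr, mode), values in raw.items():
        arr = np.asarray(values, dtype=float)
        rows.append(
            {
                "m": m,
                "k": k,
                "sigma": sigma,
                "n": n,
                "method": method,
                "init": init,
                "learning_rate": lr,
                "prediction_mode": mode,
                "avg_mse": float(arr.mean()),
                "std_mse": float(arr.std(ddof=0)),  # 0 by convention at n_reps=1
                "n_reps": int(arr.size),
            }
        )
    settings = {
        "protocol": protocol,
        "n_reps": n_reps,
        "master_seed": master_seed,
        "standardize": standardize_data,
        "mse_scale": "standardized (train statistics)" if standardize_data else "raw",
        "train_fraction": train_fraction,
        "subsample_size": subsample_size,
        "grid": [asdict(c) for c in grid],
        "sgd_cfgs": [asdict(c) for c in sgd_cfgs],
    }
    return EvalReport(rows=rows, settings=settings, failures=failures)


def plot_report(report: EvalReport, outdir: "str | Path") -> list[Path]:
    """Bar charts of average MSE by method for each model shape, grouped
    by (sigma, n).  One PNG per (m, k); returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = report.to_dataframe()
    written = []
    for (m, k), sub in df.groupby(["m", "k"]):
        sub = sub.copy()
        sub["variant"] = sub.apply(
            lambda r: (r["method"] + (f"[{r['init']}]" if r["init"] else ""))
            + f"/{r['prediction_mode']}",
            axis=1,
        )
        cells = sorted(sub.groupby(["sigma", "n"]).groups)
        variants = sorted(sub["variant"].unique())
        width = 0.8 / max(1, len(variants))
        fig, ax = plt.subplots(figsize=(1.8 * len(cells) + 3, 4))
        xs = np.arange(len(cells))
        for vi, variant in enumerate(variants):
            heights = []
            for sigma, n in cells:
                sel = sub[
                    (sub["variant"] == variant)
                    & (sub["sigma"] == sigma)
                    & (sub["n"] == n)
                ]
                heights.append(sel["avg_mse"].iloc[0] if len(sel) else np.nan)
            ax.bar(xs + vi * width, heights, width, label=variant)
        ax.set_xticks(xs + 0.4 - width / 2)
        ax.set_xticklabels([f"sigma={s}\nn={n}" for s, n in cells])
        ax.set_yscale("log")
        ax.set_ylabel("average validation MSE")
        ax.set_title(f"m={m}, k={k}")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = outdir / f"mse_m{m}_k{k}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
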