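"""Assembled piecewise-affine model, one-step prediction and error metrics.

A fitted soft-sensor model holds S local affine ARX laws theta_i, the cluster
centers used during identification, and the dividing surfaces that carve
regressor space into polyhedral regions.  Prediction is series-parallel
(one-step-ahead): the regression vector X(k) built from *measured* past
outputs and inputs is routed to its region and evaluated under that region's
affine law, yhat(k) = [X(k)^T, 1] theta_region.

Metrics follow soft-sensor practice: MAPE as a fraction of mean |(y-yhat)/y|
(samples with |y| below a floor are excluded and counted) and RMSE.  Both are
reported on the normalized scale the model operates on and, when the model
carries its scaling transform, on the physical scale as well.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import (
    BatchTimeSeries,
    RegressionDataset,
    ScalingTransform,
    build_regression_vectors,
)
from .region_partition import DividingSurface, assign_region

logger = logging.getLogger("pwasoft")


@dataclass
class PWARXModel:
    """Piecewise-affine ARX soft-sensor model for one target output.

    ``thetas[i]`` has dimension ``n_y + n_u*r + 1`` (affine term last);
    ``centers`` are the identification-time cluster centers in z-space
    (dimension ``n + 1``); ``surfaces`` are the oriented dividing hyperplanes
    in X-space.  ``scaling`` (optional) maps physical units to the [-1, 1]
    modeling scale.
    """

    n_y: int
    n_u: int
    p: int
    r: int
    target: str
    thetas: np.ndarray                    # (S, n + 1)
    centers: np.ndarray                   # (S, n + 1)
    surfaces: list[DividingSurface] = field(default_factory=list)
    scaling: ScalingTransform | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thetas = np.atleast_2d(np.asarray(self.thetas, dtype=float))
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        n = self.n
        if self.thetas.shape[1] != n + 1:
            raise ValueError(
                f"theta dimension {self.thetas.shape[1]} != n + 1 = {n + 1}"
            )
        if self.centers.shape != (len(self.thetas), n + 1):
            raise ValueError("centers shape inconsistent with thetas")
        for s in self.surfaces:
            if len(s.w) != n:
                raise ValueError("surface normal dimension != n")

    @property
    def n(self) -> int:
        return self.n_y + self.n_u * self.r

    @property
    def S(self) -> int:
        return len(self.thetas)

    # -- prediction -------------------------------------------------------

    def regions(self, X: np.ndarray) -> np.ndarray:
        return assign_region(X, self.surfaces, self.centers)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_one_step(self, X)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "pwasoft-model",
            "orders": {"n_y": self.n_y, "n_u": self.n_u, "p": self.p, "r": self.r},
            "target": self.target,
            "S": self.S,
            "thetas": self.thetas.tolist(),
            "centers": self.centers.tolist(),
            "surfaces": [s.to_dict() for s in self.surfaces],
            "scaling": None if self.scaling is None else self.scaling.to_dict(),
            "metadata": self.metadata,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PWARXModel":
        o = d["orders"]
        return cls(
            n_y=o["n_y"], n_u=o["n_u"], p=o["p"], r=o["r"],
            target=d["target"],
            thetas=np.asarray(d["thetas"], dtype=float),
            centers=np.asarray(d["centers"], dtype=float),
            surfaces=[DividingSurface.from_dict(s) for s in d["surfaces"]],
            scaling=None if d.get("scaling") is None
            else ScalingTransform.from_dict(d["scaling"]),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def from_json(cls, path) -> "PWARXModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def predict_one_step(model: PWARXModel, X: np.ndarray) -> np.ndarray:
    """One-step-ahead prediction ``[X^T, 1] theta_region`` for each row of X."""
    X2 = np.atleast_2d(np.asarray(X, dtype=float))
    if X2.shape[1] != model.n:
        raise ValueError(f"X has dimension {X2.shape[1]}, model expects {model.n}")
    reg = model.regions(X2)
    Phi = np.column_stack([X2, np.ones(len(X2))])
    return np.einsum("ij,ij->i", Phi, model.thetas[reg])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """MAPE/RMSE summary of a prediction series on one data split."""

    target: str
    split: str
    mape: float                       # fraction, e.g. 0.0435
    rmse: float
    relative_errors: np.ndarray       # (y - yhat) / y, NaN where |y| < floor
    n_samples: int
    n_excluded_small_y: int = 0
    mape_physical: float | None = None
    rmse_physical: float | None = None
    rmse_by_size: list = field(default_factory=list)  # (size, rmse) rows

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "split": self.split,
            "mape": self.mape,
            "rmse": self.rmse,
            "n_samples": self.n_samples,
            "n_excluded_small_y": self.n_excluded_small_y,
            "mape_physical": self.mape_physical,
            "rmse_physical": self.rmse_physical,
            "rmse_by_size": [[int(a), float(b)] for a, b in self.rmse_by_size],
        }


def error_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    target: str = "",
    split: str = "",
    small_y_floor: float = 1e-8,
) -> EvaluationReport:
    """MAPE (as a fraction) and RMSE of a prediction series.

    Relative errors are undefined where ``|y| < small_y_floor``; such samples
    are excluded from the MAPE (never from the RMSE) and counted.
    """
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if len(yt) != len(yp) or len(yt) == 0:
        raise ValueError("y_true and y_pred must have equal, non-zero length")
    rel = np.full(len(yt), np.nan)
    ok = np.abs(yt) >= small_y_floor
    rel[ok] = (yt[ok] - yp[ok]) / yt[ok]
    n_excl = int((~ok).sum())
    if n_excl:
        logger.info("error_metrics: %d samples below |y| floor excluded from MAPE", n_excl)
    if not ok.any():
        raise ValueError("all samples excluded from MAPE by the |y| floor")
    return EvaluationReport(
        target=target,
        split=split,
        mape=float(np.mean(np.abs(rel[ok]))),
        rmse=float(np.sqrt(np.mean((yt - yp) ** 2))),
        relative_errors=rel,
        n_samples=len(yt),
        n_excluded_small_y=n_excl,
    )


def rmse_by_test_size(
    y_true: np.ndarray, y_pred: np.ndarray, step: int = 20
) -> list[tuple[int, float]]:
    """Cumulative RMSE at growing test-set sizes (step, 2*step, ..., N)."""
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    sizes = list(range(step, len(yt) + 1, step))
    if not sizes or sizes[-1] != len(yt):
        sizes.append(len(yt))
    return [
        (m, float(np.sqrt(np.mean((yt[:m] - yp[:m]) ** 2)))) for m in sizes
    ]


def evaluate_model(
    model: PWARXModel,
    batches: Sequence[BatchTimeSeries],
    split: str = "test",
    size_step: int = 20,
) -> EvaluationReport:
    """Evaluate one-step-ahead prediction on the rows labelled *split*.

    Regressors are built per batch (windows never cross batches), filtered to
    the split, predicted in normalized space, and scored.  When the model
    carries its scaling transform the metrics are also reported on the
    physical scale; a cumulative RMSE-vs-size table is attached.
    """
    ds = build_regression_vectors(batches, model.target, model.n_y, model.n_u, model.p)
    if ds.split_labels is None:
        raise ValueError("batches carry no split labels")
    sub = ds.split(split)
    if len(sub) == 0:
        raise ValueError(f"split {split!r} is empty")
    yhat = predict_one_step(model, sub.X)
    rep = error_metrics(sub.y, yhat, target=model.target, split=split)
    rep.rmse_by_size = rmse_by_test_size(sub.y, yhat, step=size_step)
    if model.scaling is not None:
        ti = model.scaling.channel_names.index(model.target)
        tr = model.scaling
        span = 0.0 if tr.constant[ti] else (tr.hi[ti] - tr.lo[ti])
        y_phys = tr.lo[ti] + (sub.y + 1.0) * span / 2.0
        yhat_phys = tr.lo[ti] + (yhat + 1.0) * span / 2.0
        phys = error_metrics(y_phys, yhat_phys, target=model.target, split=split)
        rep.mape_physical = phys.mape
        rep.rmse_physical = phys.rmse
    return rep


def fit_global_arx(dataset: RegressionDataset) -> np.ndarray:
    """Least-squares global affine ARX parameters (baseline, S = 1).

    Returns theta of dimension n + 1 minimizing ``||y - [X, 1] theta||``.
    """
    Phi = np.column_stack([dataset.X, np.ones(len(dataset))])
    theta, *_ = np.linalg.lstsq(Phi, dataset.y, rcond=None)
    return theta
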