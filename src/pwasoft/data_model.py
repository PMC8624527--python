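"""Batch time-series containers, preprocessing and regressor construction.

A fermentation batch is a uniformly sampled multivariate record: six auxiliary
input channels (broth temperature ``T``, dissolved oxygen ``DO``, ``pH``, air
flow ``q``, stirrer speed ``v``, head pressure ``p``) on a fast grid, and the
hard-to-measure outputs (cell concentration ``X``, protease K concentration
``P``) observed on a slower off-line grid.  This module provides

* :class:`BatchTimeSeries` — one batch with an observation mask on the outputs,
* :func:`interpolate_outputs` — fill the outputs onto the fast grid,
* :func:`minmax_normalize` / :class:`ScalingTransform` — per-channel affine
  scaling of all channels to ``[-1, 1]``,
* :func:`build_regression_vectors` — assemble lagged input/output regression
  vectors ``X(k)`` and modeling vectors ``z(k) = [X(k), y(k)]`` for
  piecewise-ARX identification.

Lag windows never cross batch boundaries: each batch is an independent
realization of the process and stitching batches together would fabricate
dynamics that no batch exhibits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pwasoft")

#: Canonical auxiliary-input channel names, in column order.
U_NAMES: tuple[str, ...] = ("T", "DO", "pH", "q", "v", "p")
#: Canonical output channel names (cell concentration, protease K concentration).
Y_NAMES: tuple[str, ...] = ("X", "P")

#: Column layout of the delimited-text batch tables.
CSV_COLUMNS: tuple[str, ...] = (
    "time_min", *U_NAMES, *Y_NAMES, "batch_id", "observed", "split"
)


@dataclass
class BatchTimeSeries:
    """One fermentation batch on a uniform time grid.

    Parameters
    ----------
    batch_id
        Identifier of the batch.
    u
        Array of shape ``(N, r)`` with the auxiliary inputs.
    y
        Array of shape ``(N, m)`` with the outputs.  Rows where
        ``y_observed_mask`` is False may be NaN until interpolated.
    y_observed_mask
        Boolean array of shape ``(N,)``; True marks genuine (slow-grid)
        observations, False marks rows to be filled by interpolation.
    step_minutes
        Spacing of the uniform grid, in minutes.
    split_labels
        Optional per-row data-split labels (``"train"``/``"val"``/``"test"``).
    """

    batch_id: str
    u: np.ndarray
    y: np.ndarray
    y_observed_mask: np.ndarray
    step_minutes: float = 5.0
    u_names: tuple[str, ...] = U_NAMES
    y_names: tuple[str, ...] = Y_NAMES
    split_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        self.y_observed_mask = np.asarray(self.y_observed_mask, dtype=bool)
        if self.step_minutes <= 0:
            raise ValueError("step_minutes must be positive")
        n = len(self.u)
        if n < 1:
            raise ValueError(f"batch {self.batch_id!r} is empty")
        if len(self.y) != n or len(self.y_observed_mask) != n:
            raise ValueError(
                f"batch {self.batch_id!r}: u, y and mask lengths differ "
                f"({n}, {len(self.y)}, {len(self.y_observed_mask)})"
            )
        if self.u.shape[1] != len(self.u_names):
            raise ValueError(
                f"batch {self.batch_id!r}: u has {self.u.shape[1]} channels, "
                f"expected {len(self.u_names)}"
            )
        if self.y.shape[1] != len(self.y_names):
            raise ValueError(
                f"batch {self.batch_id!r}: y has {self.y.shape[1]} channels, "
                f"expected {len(self.y_names)}"
            )
        bad = self.y_observed_mask & ~np.isfinite(self.y).all(axis=1)
        if bad.any():
            raise ValueError(
                f"batch {self.batch_id!r}: non-finite y at observed rows "
                f"{np.flatnonzero(bad)[:5].tolist()}"
            )
        if self.split_labels is not None:
            self.split_labels = np.asarray(self.split_labels, dtype=object)
            if len(self.split_labels) != n:
                raise ValueError("split_labels length mismatch")

    def __len__(self) -> int:
        return len(self.u)

    @property
    def n_samples(self) -> int:
        return len(self.u)

    @property
    def r(self) -> int:
        return self.u.shape[1]

    @property
    def time_minutes(self) -> np.ndarray:
        return np.arange(len(self.u)) * self.step_minutes

    def copy(self) -> "BatchTimeSeries":
        return BatchTimeSeries(
            batch_id=self.batch_id,
            u=self.u.copy(),
            y=self.y.copy(),
            y_observed_mask=self.y_observed_mask.copy(),
            step_minutes=self.step_minutes,
            u_names=self.u_names,
            y_names=self.y_names,
            split_labels=None if self.split_labels is None else self.split_labels.copy(),
        )


# ---------------------------------------------------------------------------
# Output interpolation (slow grid -> fast grid)
# ---------------------------------------------------------------------------

def interpolate_outputs(
    batch: BatchTimeSeries,
    method: str = "linear",
    allow_extrapolation: bool = False,
) -> BatchTimeSeries:
    """Fill unobserved output rows by interpolating the slow-grid observations.

    Off-line assays (here: hourly) are mapped onto the fast sensor grid so each
    fast-grid input row gains a matching output value.  Observed rows are
    preserved exactly; only masked-False rows are filled.

    Parameters
    ----------
    method
        ``"linear"`` (default, piecewise linear) or ``"cubic"`` (natural cubic
        spline through the observations).
    allow_extrapolation
        If False (default), unobserved rows outside the first/last observation
        raise an error instead of being extrapolated.
    """
    if method not in ("linear", "cubic"):
        raise ValueError(f"unknown interpolation method {method!r}")
    obs = np.flatnonzero(batch.y_observed_mask)
    if batch.y_observed_mask.all():
        return batch.copy()
    if obs.size < 2:
        raise ValueError(
            f"batch {batch.batch_id!r}: need >= 2 observed outputs to "
            f"interpolate, got {obs.size}"
        )
    fill = np.flatnonzero(~batch.y_observed_mask)
    if not allow_extrapolation and ((fill < obs[0]).any() or (fill > obs[-1]).any()):
        raise ValueError(
            f"batch {batch.batch_id!r}: unobserved rows outside the observed "
            f"range [{obs[0]}, {obs[-1]}]; pass allow_extrapolation=True to "
            f"extrapolate"
        )
    out = batch.copy()
    t = batch.time_minutes
    for j in range(batch.y.shape[1]):
        yo = batch.y[obs, j]
        if method == "linear":
            # np.interp clamps outside the range; explicit slope extension when
            # extrapolation was requested.
            vals = np.interp(t[fill], t[obs], yo)
            if allow_extrapolation:
                lo, hi = obs[0], obs[-1]
                left = fill < lo
                right = fill > hi
                if left.any():
                    s = (yo[1] - yo[0]) / (t[obs[1]] - t[obs[0]])
                    vals[left] = yo[0] + s * (t[fill[left]] - t[lo])
                if right.any():
                    s = (yo[-1] - yo[-2]) / (t[obs[-1]] - t[obs[-2]])
                    vals[right] = yo[-1] + s * (t[fill[right]] - t[hi])
        else:
            from scipy.interpolate import CubicSpline

            vals = CubicSpline(t[obs], yo, bc_type="natural")(t[fill])
        out.y[fill, j] = vals
    return out


# ---------------------------------------------------------------------------
# Min-max normalization to [-1, 1]
# ---------------------------------------------------------------------------

@dataclass
class ScalingTransform:
    """Invertible per-channel affine map onto ``[-1, 1]``.

    Channels with zero range in the training data are flagged constant and map
    to 0 (the min-max formula is undefined there); the inverse restores the
    constant value.
    """

    channel_names: tuple[str, ...]
    lo: np.ndarray
    hi: np.ndarray
    constant: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if self.constant is None:
            self.constant = self.hi == self.lo
        self.constant = np.asarray(self.constant, dtype=bool)
        if not (len(self.lo) == len(self.hi) == len(self.constant) == len(self.channel_names)):
            raise ValueError("ScalingTransform field lengths differ")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Map raw channel values (shape ``(..., n_channels)``) into [-1, 1]."""
        v = np.asarray(values, dtype=float)
        span = np.where(self.constant, 1.0, self.hi - self.lo)
        out = -1.0 + 2.0 * (v - self.lo) / span
        return np.where(self.constant, 0.0, out)

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`transform`; constant channels restore ``lo``."""
        s = np.asarray(scaled, dtype=float)
        span = np.where(self.constant, 0.0, self.hi - self.lo)
        return self.lo + (s + 1.0) * span / 2.0

    def to_dict(self) -> dict:
        return {
            "channel_names": list(self.channel_names),
            "lo": self.lo.tolist(),
            "hi": self.hi.tolist(),
            "constant": self.constant.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingTransform":
        return cls(
            channel_names=tuple(d["channel_names"]),
            lo=np.asarray(d["lo"], dtype=float),
            hi=np.asarray(d["hi"], dtype=float),
            constant=np.asarray(d["constant"], dtype=bool),
        )

    # -- batch-level application ------------------------------------------

    def _split_uy(self, batch: BatchTimeSeries) -> tuple[np.ndarray, np.ndarray]:
        names = batch.u_names + batch.y_names
        if names != self.channel_names:
            raise ValueError(
                f"transform channels {self.channel_names} do not match batch "
                f"channels {names}"
            )
        return batch.u, batch.y

    def apply_batches(self, batches: Sequence[BatchTimeSeries]) -> list[BatchTimeSeries]:
        """Return normalized copies of *batches* using this (training) map.

        Values outside the stored training range are mapped by the same affine
        law and may leave ``[-1, 1]``; this is logged, never clipped.
        """
        out = []
        for b in batches:
            u, y = self._split_uy(b)
            full = np.hstack([u, y])
            scaled = self.transform(full)
            finite = np.isfinite(scaled)
            n_out = int(((np.abs(scaled) > 1.0) & finite).sum())
            if n_out:
                logger.info(
                    "batch %s: %d values outside the training range map outside "
                    "[-1, 1] (not clipped)", b.batch_id, n_out
                )
            c = b.copy()
            c.u = scaled[:, : u.shape[1]]
            c.y = scaled[:, u.shape[1]:]
            out.append(c)
        return out

    def invert_outputs(self, scaled_y: np.ndarray, y_names: tuple[str, ...] = Y_NAMES) -> np.ndarray:
        """De-normalize output columns only (shape ``(..., len(y_names))``)."""
        idx = [self.channel_names.index(n) for n in y_names]
        sub = ScalingTransform(
            channel_names=tuple(y_names),
            lo=self.lo[idx], hi=self.hi[idx], constant=self.constant[idx],
        )
        return sub.inverse(scaled_y)


def minmax_normalize(
    batches: Sequence[BatchTimeSeries],
) -> tuple[list[BatchTimeSeries], ScalingTransform]:
    """Fit a per-channel min-max map to [-1, 1] over *batches* and apply it.

    All batches contribute to the per-channel min/max (inputs and outputs
    alike).  Returns the scaled copies and the fitted, invertible transform.
    """
    batches = list(batches)
    if not batches:
        raise ValueError("minmax_normalize: empty batch collection")
    names = batches[0].u_names + batches[0].y_names
    stacked = np.vstack([np.hstack([b.u, b.y]) for b in batches])
    for j, name in enumerate(names):
        col = stacked[:, j]
        if not np.isfinite(col).all():
            k = int(np.flatnonzero(~np.isfinite(col))[0])
            raise ValueError(
                f"channel {name!r} has a non-finite value at stacked row {k}; "
                f"interpolate outputs before normalizing"
            )
    lo = stacked.min(axis=0)
    hi = stacked.max(axis=0)
    tr = ScalingTransform(channel_names=names, lo=lo, hi=hi)
    if tr.constant.any():
        logger.info(
            "constant channels mapped to 0: %s",
            [names[i] for i in np.flatnonzero(tr.constant)],
        )
    return tr.apply_batches(batches), tr


def assign_split_labels(
    batches: Sequence[BatchTimeSeries],
    sizes: tuple[int, int, int] = (576, 204, 180),
    labels: tuple[str, str, str] = ("train", "val", "test"),
) -> None:
    """Label rows train/val/test by global sample index over ordered batches.

    The split sizes need not align with batch boundaries; rows are labelled in
    batch order.  Sizes must sum to the total row count.
    """
    total = sum(len(b) for b in batches)
    if sum(sizes) != total:
        raise ValueError(f"split sizes {sizes} do not sum to {total} samples")
    flat = np.empty(total, dtype=object)
    edges = np.cumsum((0,) + sizes)
    for lab, a, b in zip(labels, edges[:-1], edges[1:]):
        flat[a:b] = lab
    k = 0
    for b in batches:
        b.split_labels = flat[k: k + len(b)].copy()
        k += len(b)


# ---------------------------------------------------------------------------
# Regression / modeling vectors
# ---------------------------------------------------------------------------

@dataclass
class RegressionDataset:
    """Lagged regression pairs for one target output.

    ``X[k] = [y(k-1)..y(k-n_y), u_1(k-p-1)..u_r(k-p-1), ..,
    u_1(k-p-n_u)..u_r(k-p-n_u)]`` and ``z[k] = [X[k], y(k)]`` — the modeling
    vector in which local models are clustered.
    """

    n_y: int
    n_u: int
    p: int
    r: int
    target: str
    X: np.ndarray            # (M, n)
    y: np.ndarray            # (M,)
    batch_ids: np.ndarray    # (M,) object
    time_indices: np.ndarray  # (M,) int, index within the source batch
    split_labels: np.ndarray | None = None

    @property
    def n(self) -> int:
        """Regressor dimension ``n_y + n_u * r``."""
        return self.n_y + self.n_u * self.r

    @property
    def z(self) -> np.ndarray:
        """Modeling vectors ``z(k) = [X(k), y(k)]`` of dimension ``n + 1``."""
        return np.hstack([self.X, self.y[:, None]])

    @property
    def n_pairs(self) -> int:
        return len(self.y)

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, mask: np.ndarray) -> "RegressionDataset":
        mask = np.asarray(mask)
        return RegressionDataset(
            n_y=self.n_y, n_u=self.n_u, p=self.p, r=self.r, target=self.target,
            X=self.X[mask], y=self.y[mask],
            batch_ids=self.batch_ids[mask], time_indices=self.time_indices[mask],
            split_labels=None if self.split_labels is None else self.split_labels[mask],
        )

    def split(self, label: str) -> "RegressionDataset":
        if self.split_labels is None:
            raise ValueError("dataset carries no split labels")
        return self.subset(self.split_labels == label)


def regressor_window(n_y: int, n_u: int, p: int) -> int:
    """Number of leading samples a lag window consumes: ``max(n_y, p + n_u)``."""
    return max(n_y, p + n_u)


def build_regression_vectors(
    batches: Sequence[BatchTimeSeries] | BatchTimeSeries,
    target: str,
    n_y: int,
    n_u: int,
    p: int = 0,
) -> RegressionDataset:
    """Assemble lagged regression vectors for *target* from one or more batches.

    The first ``max(n_y, p + n_u)`` samples of each batch are trimmed (their
    lag windows are incomplete); windows never span two batches.  Batches too
    short to yield a pair are skipped with a warning.
    """
    if isinstance(batches, BatchTimeSeries):
        batches = [batches]
    if n_y < 0 or n_u < 1 or p < 0:
        raise ValueError("require n_y >= 0, n_u >= 1, p >= 0")
    batches = list(batches)
    if not batches:
        raise ValueError("no batches given")
    ti = batches[0].y_names.index(target)
    r = batches[0].r
    w = regressor_window(n_y, n_u, p)
    Xs, ys, bids, tidx, splits = [], [], [], [], []
    have_splits = all(b.split_labels is not None for b in batches)
    for b in batches:
        N = len(b)
        if N <= w:
            logger.warning(
                "batch %s: length %d <= lag window %d, skipped", b.batch_id, N, w
            )
            continue
        yt = b.y[:, ti]
        for k in range(w, N):
            row = [yt[k - i] for i in range(1, n_y + 1)]
            for j in range(1, n_u + 1):
                row.extend(b.u[k - p - j])
            Xs.append(row)
            ys.append(yt[k])
            bids.append(b.batch_id)
            tidx.append(k)
            if have_splits:
                splits.append(b.split_labels[k])
    if not ys:
        raise ValueError("all batches shorter than the lag window; no pairs")
    return RegressionDataset(
        n_y=n_y, n_u=n_u, p=p, r=r, target=target,
        X=np.asarray(Xs, dtype=float),
        y=np.asarray(ys, dtype=float),
        batch_ids=np.asarray(bids, dtype=object),
        time_indices=np.asarray(tidx, dtype=int),
        split_labels=np.asarray(splits, dtype=object) if have_splits else None,
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

#: Column names the reader recognizes as output (target) channels.
_OUTPUT_COLUMN_NAMES = frozenset({"X", "P", "y"})


def write_batches_csv(batches: Iterable[BatchTimeSeries], path) -> None:
    """Write batches as one tidy CSV table.

    Columns: ``time_min``, the batch's input channels, its output channels
    (named from :data:`Y_NAMES` or ``y`` for single-output synthetic systems),
    ``batch_id``, ``observed`` and ``split`` (see :data:`CSV_COLUMNS` for the
    canonical fermentation layout).
    """
    frames = []
    for b in batches:
        d = {"time_min": b.time_minutes}
        for j, name in enumerate(b.u_names):
            d[name] = b.u[:, j]
        for j, name in enumerate(b.y_names):
            d[name] = b.y[:, j]
        d["batch_id"] = b.batch_id
        d["observed"] = b.y_observed_mask.astype(int)
        d["split"] = b.split_labels if b.split_labels is not None else ""
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_batches_csv(path) -> list[BatchTimeSeries]:
    """Read batches written by :func:`write_batches_csv` (order preserved).

    Output channels are the columns named ``X``, ``P`` or ``y``; every other
    non-bookkeeping column is an input channel.
    """
    df = pd.read_csv(path, dtype={"batch_id": str})
    for col in ("time_min", "batch_id", "observed"):
        if col not in df.columns:
            raise ValueError(f"batch CSV missing column {col!r}")
    meta = {"time_min", "batch_id", "observed", "split"}
    y_names = tuple(c for c in df.columns if c in _OUTPUT_COLUMN_NAMES)
    u_names = tuple(c for c in df.columns if c not in meta and c not in y_names)
    if not y_names or not u_names:
        raise ValueError("batch CSV must contain input and output channels")
    out = []
    for bid in df["batch_id"].drop_duplicates():
        g = df[df["batch_id"] == bid]
        t = g["time_min"].to_numpy(dtype=float)
        step = float(np.diff(t)[0]) if len(t) > 1 else 5.0
        splits = None
        if "split" in g.columns and not g["split"].isna().all():
            splits = g["split"].to_numpy(dtype=object)
        out.append(BatchTimeSeries(
            batch_id=str(bid),
            u=g[list(u_names)].to_numpy(dtype=float),
            y=g[list(y_names)].to_numpy(dtype=float),
            y_observed_mask=g["observed"].to_numpy(dtype=bool),
            step_minutes=step,
            u_names=u_names,
            y_names=y_names,
            split_labels=splits,
        ))
    return out
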