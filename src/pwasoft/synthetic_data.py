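"""Synthetic ground-truth data: exact PWARX systems and a fermentation surrogate.

Real fermentation batches of the kind the soft sensor targets are rarely
public, so every pipeline stage is exercised against data whose ground truth
is known exactly:

* :func:`gen_pwarx_dataset` simulates a piecewise-affine ARX system whose
  regime partition (thresholds or nearest-center, on the regression vector)
  and local parameters are specified, returning batches plus the true labels
  for recovery scoring;
* :func:`gen_fermentation_batches` integrates a mechanistic batch-fermentation
  surrogate — logistic biomass growth modulated by bell-shaped deviations of
  temperature/pH/dissolved-oxygen from their setpoints, Luedeking-Piret
  product formation — on a 5-minute sensor grid with hourly off-line output
  assays, then interpolates, thins and normalizes exactly as the modeling
  pipeline expects;
* :func:`make_two_regime_benchmark` and :func:`make_three_phase_fixture` are
  the standard recovery fixtures (S = 2, and an S = 3 lag/growth/stationary
  trajectory with r = 6 input channels).

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    BatchTimeSeries,
    ScalingTransform,
    assign_split_labels,
    interpolate_outputs,
    minmax_normalize,
)

logger = logging.getLogger("pwasoft")

_DIVERGENCE_GUARD = 1e6


# ---------------------------------------------------------------------------
# Exact PWARX systems
# ---------------------------------------------------------------------------

@dataclass
class PWARXSpec:
    """Ground-truth piecewise-affine ARX system.

    The regime of time k is decided on the regression vector X(k): either by
    ascending ``thresholds`` on coordinate ``region_coord`` (regime = number
    of thresholds at or below that coordinate) or by nearest ``centers_x``
    (rows in X-space).  ``thetas[i]`` has dimension ``n_y + n_u*r + 1``.
    """

    thetas: np.ndarray
    n_y: int = 1
    n_u: int = 1
    p: int = 0
    r: int = 1
    thresholds: tuple = ()
    region_coord: int = 0
    centers_x: np.ndarray | None = None
    noise_sd: float = 0.0
    n_samples: int = 200
    n_batches: int = 1
    seed: int = 0
    u_ar_coef: float = 0.9
    u_sd: float = 0.3
    u_kind: str = "ar1"          # "ar1" or "bimodal" (Markov level-switching)
    u_level: float = 0.8         # bimodal: levels +/- u_level
    u_flip_prob: float = 0.05    # bimodal: per-step level flip probability
    u_ramp: tuple = ()           # per-channel linear drift amplitude over a batch
    y0: float = 0.0

    def __post_init__(self) -> None:
        self.thetas = np.atleast_2d(np.asarray(self.thetas, dtype=float))
        n = self.n_y + self.n_u * self.r
        if self.thetas.shape[1] != n + 1:
            raise ValueError(
                f"theta dimension {self.thetas.shape[1]} != n + 1 = {n + 1}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        n_regions = len(self.thresholds) + 1 if self.centers_x is None \
            else len(np.atleast_2d(self.centers_x))
        if n_regions != self.S_true:
            raise ValueError(
                f"region definition yields {n_regions} regimes but "
                f"{self.S_true} theta vectors were given"
            )

    @property
    def S_true(self) -> int:
        return len(self.thetas)

    @property
    def n(self) -> int:
        return self.n_y + self.n_u * self.r

    def region_of(self, X: np.ndarray) -> int:
        if self.centers_x is not None:
            C = np.atleast_2d(self.centers_x)
            return int(np.argmin(np.linalg.norm(C - X, axis=1)))
        c = X[self.region_coord]
        return int(sum(c >= t for t in self.thresholds))


def gen_pwarx_dataset(spec: PWARXSpec) -> tuple[list[BatchTimeSeries], dict]:
    """Simulate a PWARX system; return batches and the ground truth.

    The truth dict carries the per-sample regime ``labels`` (aligned with the
    pairs :func:`~pwasoft.data_model.build_regression_vectors` emits for the
    same orders), the true ``thetas`` and the spec itself.
    """
    rng = np.random.default_rng(spec.seed)
    w = max(spec.n_y, spec.p + spec.n_u)
    u_names = tuple(f"u{j + 1}" for j in range(spec.r))
    batches, labels = [], []
    for b in range(spec.n_batches):
        N = spec.n_samples
        u = np.zeros((N, spec.r))
        if spec.u_kind == "bimodal":
            level = np.where(rng.uniform(size=spec.r) < 0.5, 1.0, -1.0)
            for k in range(N):
                flip = rng.uniform(size=spec.r) < spec.u_flip_prob
                level = np.where(flip, -level, level)
                u[k] = spec.u_level * level + spec.u_sd * rng.normal(size=spec.r)
        elif spec.u_kind == "ar1":
            innov_sd = spec.u_sd * np.sqrt(max(1.0 - spec.u_ar_coef**2, 1e-12))
            for k in range(1, N):
                u[k] = spec.u_ar_coef * u[k - 1] + innov_sd * rng.normal(size=spec.r)
        else:
            raise ValueError(f"unknown u_kind {spec.u_kind!r}")
        if len(spec.u_ramp):
            ramp = np.asarray(spec.u_ramp, dtype=float)
            if len(ramp) != spec.r:
                raise ValueError("u_ramp length must equal r")
            u += (np.arange(N)[:, None] / max(N - 1, 1) - 0.5) * ramp
        y = np.full(N, spec.y0, dtype=float)
        for k in range(w, N):
            X = _regression_vector(y, u, k, spec.n_y, spec.n_u, spec.p)
            reg = spec.region_of(X)
            labels.append(reg)
            y[k] = (
                np.concatenate([X, [1.0]]) @ spec.thetas[reg]
                + spec.noise_sd * rng.normal()
            )
            if abs(y[k]) > _DIVERGENCE_GUARD:
                raise ValueError(
                    f"simulated output diverged (|y| > {_DIVERGENCE_GUARD:g}) "
                    f"under theta_{reg} = {spec.thetas[reg]}"
                )
        batches.append(BatchTimeSeries(
            batch_id=f"pwarx-{b + 1}",
            u=u,
            y=y[:, None],
            y_observed_mask=np.ones(N, dtype=bool),
            u_names=u_names,
            y_names=("y",),
        ))
    truth = {
        "labels": np.asarray(labels, dtype=int),
        "thetas": spec.thetas.copy(),
        "S_true": spec.S_true,
        "spec": spec,
    }
    return batches, truth


def _regression_vector(y, u, k, n_y, n_u, p) -> np.ndarray:
    row = [y[k - i] for i in range(1, n_y + 1)]
    for j in range(1, n_u + 1):
        row.extend(u[k - p - j])
    return np.asarray(row, dtype=float)


# ---------------------------------------------------------------------------
# Standard recovery fixtures
# ---------------------------------------------------------------------------

def make_two_regime_benchmark(
    seed: int, noise_sd: float = 0.0, n_samples: int = 300, n_batches: int = 1
) -> tuple[list[BatchTimeSeries], dict]:
    """S = 2 switched-affine benchmark (r = 1, one lag each, d_theta = 3).

    The regime is decided by the sign of u(k-1); the input holds a level near
    +/-0.8 (small jitter) and flips occasionally, so the two regimes form two
    well-separated clouds in z-space with balanced occupancy in every seed.
    The truth dict additionally carries ``Y_ts``, a threshold at the
    regime-mismatch scale that only the true two-regime structure can reach.
    """
    spec = PWARXSpec(
        thetas=np.array([
            [0.40, 0.20, -0.30],   # u < 0 regime: settles near -0.77
            [0.40, 0.20, +0.30],   # u >= 0 regime: settles near +0.77
        ]),
        n_y=1, n_u=1, r=1,
        thresholds=(0.0,),
        region_coord=1,            # the u(k-1) coordinate of X
        noise_sd=noise_sd,
        n_samples=n_samples,
        n_batches=n_batches,
        seed=seed,
        u_kind="bimodal",
        u_level=0.8,
        u_sd=0.08,
        u_flip_prob=0.06,
        y0=0.0,
    )
    batches, truth = gen_pwarx_dataset(spec)
    truth["Y_ts_per_pair"] = 3.0 * max(noise_sd, 0.01) ** 2
    truth["Y_ts"] = len(truth["labels"]) * truth["Y_ts_per_pair"]
    return batches, truth


def make_three_phase_fixture(
    seed: int, noise_sd: float = 0.002, n_samples: int = 96, n_batches: int = 10
) -> tuple[list[BatchTimeSeries], dict]:
    """Three-regime fermentation-like fixture (r = 6, d_theta = 8).

    Each batch traces a growth trajectory through three contiguous phases
    split by thresholds on y(k-1): a lag phase (slow drift up), a
    growth phase (exponential-like rise) and a stationary phase (fast settle
    near 0.9).  The six auxiliary channels enter each regime with distinctly
    different coefficient patterns, so no single affine law (nor any
    two-regime merge) can reach the noise floor.  Every phase spans at least
    roughly 20% of a batch, keeping all three regimes identifiable.
    """
    # y-lag coefficient and offset set the phase trajectory; the six input
    # coefficients differ strongly across regimes to keep them distinguishable
    u_coefs = 2.0 * np.array([
        [0.060, -0.050, 0.040, -0.060, 0.050, 0.030],     # lag phase
        [-0.060, 0.050, -0.040, 0.060, -0.050, 0.060],    # growth phase
        [0.020, 0.060, 0.050, -0.030, -0.060, -0.040],    # stationary phase
    ])
    # the input channels drift slowly over a batch (as real fermentation
    # variables do), which makes the phases separable in z-space; the
    # coefficient patterns are projected orthogonal to the drift direction so
    # the drift shapes the clusters without perturbing the phase trajectory
    ramp = 0.6 * np.array([1.0, -0.9, 0.8, -0.8, 0.9, -1.0])
    rv = ramp / np.linalg.norm(ramp)
    u_coefs = u_coefs - np.outer(u_coefs @ rv, rv)
    thetas = np.column_stack([
        [0.970, 1.040, 0.700],            # y(k-1) coefficient per phase
        u_coefs,
        [0.0150, 0.0010, 0.2700],         # affine offset per phase
    ])
    spec = PWARXSpec(
        thetas=thetas,
        n_y=1, n_u=1, r=6,
        thresholds=(0.30, 0.65),
        noise_sd=noise_sd,
        n_samples=n_samples,
        n_batches=n_batches,
        seed=seed,
        u_ar_coef=0.9,
        u_sd=0.05,
        u_ramp=tuple(ramp),
        y0=0.05,
    )
    batches, truth = gen_pwarx_dataset(spec)
    # search threshold at 2.5x the per-sample noise floor: loose enough for
    # the true three-regime structure, unreachable for any one- or two-regime
    # partition of this system
    truth["Y_ts_per_pair"] = 2.5 * max(noise_sd, 0.002) ** 2
    truth["Y_ts"] = len(truth["labels"]) * truth["Y_ts_per_pair"]
    return batches, truth


# ---------------------------------------------------------------------------
# Mechanistic fermentation surrogate
# ---------------------------------------------------------------------------

@dataclass
class FermentationSpec:
    """Batch-fermentation surrogate emulating the study's sampling design.

    Kinetics: logistic biomass growth ``dX/dt = mu_max * g(T) * g(pH) * g(DO)
    * X * (1 - X/X_max)`` with bell-shaped modulation ``g`` around the
    setpoints, and Luedeking-Piret product formation ``dP/dt = lp_growth *
    dX/dt + lp_maintenance * X``.  Inputs are AR(1) perturbations around the
    control setpoints (tank pressure 0.04 MPa, stirring 250 rpm, 28 degC,
    air flow ~1100 L/h, DO ~40%, pH 7.3).  Sensors sample every 5 minutes
    for 80 h; outputs are observed hourly, interpolated to the fast grid,
    thinned to ``samples_per_batch`` rows, and normalized to [-1, 1].
    """

    mu_max: float = 0.12                  # 1/h, effective max specific growth
    X_max: float = 30.0                   # g/L carrying capacity
    X0: float = 0.6                       # g/L inoculum
    P0: float = 0.05                      # g/L initial product
    lp_growth: float = 0.30               # growth-associated coefficient a
    lp_maintenance: float = 0.005         # non-growth-associated b, 1/h
    setpoints: dict = field(default_factory=lambda: {
        "T": 28.0, "DO": 40.0, "pH": 7.3, "q": 1100.0, "v": 250.0, "p": 0.04,
    })
    modulation_widths: dict = field(default_factory=lambda: {
        "T": 2.0, "DO": 15.0, "pH": 0.6,
    })
    input_ar_coef: float = 0.9
    input_sd_fraction: float = 0.02       # stationary sd as fraction of setpoint
    duration_h: float = 80.0
    input_step_min: float = 5.0
    output_step_min: float = 60.0
    n_batches: int = 10
    samples_per_batch: int = 96
    split_sizes: tuple[int, int, int] = (576, 204, 180)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mu_max, self.X_max, self.X0) <= 0:
            raise ValueError("kinetic parameters must be positive")
        if self.lp_growth < 0 or self.lp_maintenance < 0:
            raise ValueError("Luedeking-Piret coefficients must be >= 0")
        total = self.n_batches * self.samples_per_batch
        if sum(self.split_sizes) != total:
            raise ValueError(
                f"split sizes {self.split_sizes} must sum to "
                f"{self.n_batches} x {self.samples_per_batch} = {total}"
            )


def gen_fermentation_batches(
    spec: FermentationSpec,
    normalize: bool = True,
    noiseless: bool = False,
) -> tuple[list[BatchTimeSeries], ScalingTransform | None]:
    """Simulate, observe, interpolate, thin, label splits and normalize.

    ``noiseless=True`` pins all inputs at their setpoints (used for checking
    closed-form kinetic properties).  Returns the batches and the fitted
    scaling transform (None when ``normalize=False``).
    """
    rng = np.random.default_rng(spec.seed)
    dt_h = spec.input_step_min / 60.0
    n_fast = int(round(spec.duration_h * 60.0 / spec.input_step_min))  # e.g. 960
    obs_every = int(round(spec.output_step_min / spec.input_step_min))  # e.g. 12
    n_sim = (n_fast // obs_every) * obs_every + 1  # last index observed
    names = ("T", "DO", "pH", "q", "v", "p")
    sp = np.array([spec.setpoints[k] for k in names])
    widths = spec.modulation_widths
    stride = max(n_fast // spec.samples_per_batch, 1)
    batches = []
    for b in range(spec.n_batches):
        if noiseless:
            u = np.tile(sp, (n_sim, 1))
            X = spec.X0
        else:
            sd = spec.input_sd_fraction * sp
            innov = sd * np.sqrt(max(1.0 - spec.input_ar_coef**2, 1e-12))
            dev = np.zeros((n_sim, len(sp)))
            for k in range(1, n_sim):
                dev[k] = spec.input_ar_coef * dev[k - 1] + innov * rng.normal(size=len(sp))
            u = sp + dev
            X = spec.X0 * float(rng.uniform(0.9, 1.1))
        P = spec.P0
        Xs = np.empty(n_sim)
        Ps = np.empty(n_sim)
        for k in range(n_sim):
            Xs[k], Ps[k] = X, P
            g = (
                _bell(u[k, 0], sp[0], widths["T"])
                * _bell(u[k, 2], sp[2], widths["pH"])
                * _bell(u[k, 1], sp[1], widths["DO"])
            )
            dX = spec.mu_max * g * X * (1.0 - X / spec.X_max)
            dP = spec.lp_growth * dX + spec.lp_maintenance * X
            X = X + dt_h * dX
            P = P + dt_h * dP
            if X < 0 or P < 0:
                logger.warning("fermentation state went negative; clipped at 0")
                X, P = max(X, 0.0), max(P, 0.0)
        mask = np.zeros(n_sim, dtype=bool)
        mask[::obs_every] = True
        y = np.column_stack([Xs, Ps])
        y_obs = np.where(mask[:, None], y, np.nan)
        raw = BatchTimeSeries(
            batch_id=f"ferm-{b + 1}",
            u=u, y=y_obs, y_observed_mask=mask,
            step_minutes=spec.input_step_min,
        )
        filled = interpolate_outputs(raw, method="linear")
        keep = np.arange(0, n_fast, stride)[: spec.samples_per_batch]
        thin = BatchTimeSeries(
            batch_id=filled.batch_id,
            u=filled.u[keep],
            y=filled.y[keep],
            y_observed_mask=filled.y_observed_mask[keep],
            step_minutes=spec.input_step_min * stride,
        )
        batches.append(thin)
    assign_split_labels(batches, sizes=spec.split_sizes)
    if not normalize:
        return batches, None
    scaled, transform = minmax_normalize(batches)
    for s, b in zip(scaled, batches):
        s.split_labels = b.split_labels
    return scaled, transform


def _bell(value: float, setpoint: float, width: float) -> float:
    return float(np.exp(-((value - setpoint) ** 2) / (2.0 * width**2)))
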