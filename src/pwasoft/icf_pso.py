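"""Particle swarm optimization with an iteration-dependent compression factor.

The velocity update of a standard PSO,

    v <- w*v + c1*r1*(pbest - p) + c2*r2*(gbest - p),

is multiplied by a compression factor mu that decays with the iteration count
G.  The decaying factor lets particles fly fast early (escaping local optima)
and damps them late (fine local search).  The raw schedule is

    mu(G) = delta * sigma ** (G / (N + G - 1)),

with constants delta > 0, sigma in (0, 1) and schedule horizon N.  With the
recommended delta = 24, sigma = 0.01, N = 300 the raw value starts near 23.6,
so by default the schedule is normalized by mu(1): it then starts at exactly 1
and decays monotonically toward sigma-dependent small values, which is the
behavior the factor is meant to have.  Both variants are available via
``factor_mode`` ("icf_normalized" / "icf_printed"), alongside the classic
constriction factor of Clerc ("clerc") and plain PSO ("none").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger("pwasoft")

FACTOR_MODES = ("icf_printed", "icf_normalized", "clerc", "none")


@dataclass
class SwarmConfig:
    """Configuration of the (ICF-)PSO optimizer.

    Attributes
    ----------
    n_particles
        Swarm size (>= 2).
    w, c1, c2
        Inertia weight and acceleration coefficients.
    icf_delta, icf_sigma
        Constants of the compression-factor schedule (defaults 24 and 0.01).
    n_schedule
        Horizon N of the mu schedule (default 300).
    n_iterations
        Iteration budget; defaults to ``n_schedule``.
    fitness_threshold
        Stop as soon as the global best fitness drops to or below this value.
    factor_mode
        One of "icf_normalized" (default), "icf_printed", "clerc", "none".
    bounds
        ``(lower, upper)`` arrays (or scalars) delimiting the search box.
    velocity_clamp
        Optional per-dimension cap on |velocity|.
    seed
        Seed for the internal random generator.
    """

    n_particles: int = 30
    w: float = 0.729
    c1: float = 1.49
    c2: float = 1.49
    icf_delta: float = 24.0
    icf_sigma: float = 0.01
    n_schedule: int = 300
    n_iterations: int | None = None
    fitness_threshold: float = -math.inf
    factor_mode: str = "icf_normalized"
    bounds: tuple = (-10.0, 10.0)
    velocity_clamp: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("swarm size must be >= 2")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("acceleration coefficients must be positive")
        if self.icf_delta <= 0 or self.icf_sigma <= 0:
            raise ValueError("icf_delta and icf_sigma must be positive")
        if self.n_schedule < 1:
            raise ValueError("n_schedule must be >= 1")
        if self.factor_mode not in FACTOR_MODES:
            raise ValueError(f"factor_mode must be one of {FACTOR_MODES}")
        if self.factor_mode == "clerc":
            clerc_factor(self.c1, self.c2)  # validates c1 + c2 > 4
        if self.n_iterations is None:
            self.n_iterations = self.n_schedule


@dataclass
class SwarmState:
    """Mutable swarm state: positions, velocities, bests and the counter G."""

    positions: np.ndarray          # (n_particles, D)
    velocities: np.ndarray         # (n_particles, D)
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray      # (n_particles,)
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int = 1             # current iteration counter G
    trace: list = field(default_factory=list)

    @classmethod
    def initialize(
        cls,
        fitness_fn: Callable[[np.ndarray], float],
        D: int,
        config: SwarmConfig,
        rng: np.random.Generator,
        init_positions: np.ndarray | None = None,
    ) -> "SwarmState":
        lo, hi = _expand_bounds(config.bounds, D)
        if init_positions is None:
            pos = rng.uniform(lo, hi, size=(config.n_particles, D))
        else:
            pos = np.array(init_positions, dtype=float)
            if pos.shape != (config.n_particles, D):
                raise ValueError("init_positions shape mismatch")
        vel = np.zeros_like(pos)
        fit = _evaluate(fitness_fn, pos)
        g = int(np.argmin(fit))
        return cls(
            positions=pos, velocities=vel,
            pbest_positions=pos.copy(), pbest_fitness=fit.copy(),
            gbest_position=pos[g].copy(), gbest_fitness=float(fit[g]),
        )


def compression_factor(
    G: int,
    icf_delta: float = 24.0,
    icf_sigma: float = 0.01,
    N: int = 300,
    mode: str = "icf_normalized",
) -> float:
    """Iteration-dependent compression factor mu(G).

    ``mode="icf_printed"`` returns the raw schedule
    ``delta * sigma ** (G / (N + G - 1))``; ``mode="icf_normalized"`` divides
    by the raw value at G = 1, so the schedule starts at exactly 1.  Both are
    strictly decreasing in G for sigma < 1, with shrinking decrements.
    """
    if G < 1 or N < 1:
        raise ValueError("require G >= 1 and N >= 1")
    if icf_delta <= 0 or icf_sigma <= 0:
        raise ValueError("icf_delta and icf_sigma must be positive")
    raw = icf_delta * icf_sigma ** (G / (N + G - 1))
    if mode == "icf_printed":
        return raw
    if mode == "icf_normalized":
        return raw / (icf_delta * icf_sigma ** (1.0 / N))
    raise ValueError(f"mode must be 'icf_printed' or 'icf_normalized', got {mode!r}")


def clerc_factor(c1: float, c2: float) -> float:
    """Clerc's constriction factor ``phi = 2 / |2 - rho - sqrt(rho^2 - 4 rho)|``.

    Defined only for ``rho = c1 + c2 > 4``.
    """
    rho = c1 + c2
    if rho <= 4:
        raise ValueError(f"Clerc constriction requires c1 + c2 > 4, got {rho}")
    return 2.0 / abs(2.0 - rho - math.sqrt(rho * rho - 4.0 * rho))


def _factor(config: SwarmConfig, G: int) -> float:
    if config.factor_mode == "none":
        return 1.0
    if config.factor_mode == "clerc":
        return clerc_factor(config.c1, config.c2)
    return compression_factor(
        G, config.icf_delta, config.icf_sigma, config.n_schedule, config.factor_mode
    )


def _expand_bounds(bounds, D: int) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = bounds
    lo = np.broadcast_to(np.asarray(lo, dtype=float), (D,)).copy()
    hi = np.broadcast_to(np.asarray(hi, dtype=float), (D,)).copy()
    if not (np.isfinite(lo).all() and np.isfinite(hi).all()) or (lo >= hi).any():
        raise ValueError("bounds must be finite with lower < upper")
    return lo, hi


def _evaluate(fitness_fn, positions: np.ndarray) -> np.ndarray:
    out = np.empty(len(positions))
    for i, p in enumerate(positions):
        v = float(fitness_fn(p))
        if not math.isfinite(v):
            logger.warning("fitness returned non-finite value; set to +inf")
            v = math.inf
        out[i] = v
    return out


def update_swarm(
    state: SwarmState,
    config: SwarmConfig,
    fitness_fn: Callable[[np.ndarray], float],
    rng: np.random.Generator,
    repair_fn: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
) -> SwarmState:
    """Advance the swarm one generation in place (returns the same state).

    Velocities follow the compressed update; positions leaving the search box
    are clipped with the violated velocity component zeroed.  ``repair_fn``,
    when given, may adjust each position before evaluation (used by the
    identification layer to re-seat cluster centers of empty clusters).
    """
    D = state.positions.shape[1]
    lo, hi = _expand_bounds(config.bounds, D)
    mu = _factor(config, state.iteration)
    shape = state.positions.shape
    r1 = rng.uniform(size=shape)
    r2 = rng.uniform(size=shape)
    vel = mu * (
        config.w * state.velocities
        + config.c1 * r1 * (state.pbest_positions - state.positions)
        + config.c2 * r2 * (state.gbest_position[None, :] - state.positions)
    )
    if config.velocity_clamp is not None:
        np.clip(vel, -config.velocity_clamp, config.velocity_clamp, out=vel)
    pos = state.positions + vel
    below, above = pos < lo, pos > hi
    vel[below | above] = 0.0
    np.clip(pos, lo, hi, out=pos)
    if repair_fn is not None:
        for i in range(len(pos)):
            pos[i] = np.clip(repair_fn(pos[i], rng), lo, hi)
    fit = _evaluate(fitness_fn, pos)
    state.positions = pos
    state.velocities = vel
    improved = fit < state.pbest_fitness
    state.pbest_positions[improved] = pos[improved]
    state.pbest_fitness[improved] = fit[improved]
    g = int(np.argmin(state.pbest_fitness))
    if state.pbest_fitness[g] < state.gbest_fitness:
        state.gbest_fitness = float(state.pbest_fitness[g])
        state.gbest_position = state.pbest_positions[g].copy()
    state.iteration += 1
    return state


def optimize(
    fitness_fn: Callable[[np.ndarray], float],
    D: int,
    config: SwarmConfig,
    init_positions: np.ndarray | None = None,
    repair_fn: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float, dict]:
    """Minimize ``fitness_fn`` over a ``D``-dimensional box.

    Runs until the global best fitness reaches ``config.fitness_threshold`` or
    ``config.n_iterations`` generations have elapsed.  Fully reproducible for
    a fixed seed.  Returns ``(best_position, best_fitness, info)`` where
    ``info`` carries the per-iteration best-fitness trace and the stop reason.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = SwarmState.initialize(fitness_fn, D, config, rng, init_positions)
    state.trace.append(state.gbest_fitness)
    reason = "iteration_budget"
    if state.gbest_fitness <= config.fitness_threshold:
        reason = "threshold_met"
    else:
        while state.iteration < config.n_iterations + 1:
            update_swarm(state, config, fitness_fn, rng, repair_fn)
            state.trace.append(state.gbest_fitness)
            if state.gbest_fitness <= config.fitness_threshold:
                reason = "threshold_met"
                break
    info = {
        "trace": np.asarray(state.trace),
        "iterations": state.iteration,
        "reason": reason,
        "state": state,
    }
    return state.gbest_position.copy(), state.gbest_fitness, info


def plot_factor_regimes(ax=None, N: int = 300):
    """Plot mu(G) schedules for representative (delta, sigma) regimes.

    Illustrates the two admissible constant regimes — delta in (0,1) with
    sigma > 1, and delta > 1 with sigma in (0,1) — including the recommended
    (24, 0.01) pair.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    G = np.arange(1, N + 1)
    regimes = [
        (0.5, math.pi), (0.5, 2 * math.pi), (0.1, 2 * math.pi),
        (2 * math.pi, 0.5), (12.0, 0.1), (24.0, 0.01),
    ]
    for d, s in regimes:
        mu = [compression_factor(g, d, s, N, "icf_printed") for g in G]
        ax.plot(G, mu, label=f"delta={d:g}, sigma={s:g}")
    ax.set_xlabel("iteration G")
    ax.set_ylabel("mu(G)")
    ax.legend(fontsize=7)
    return ax
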