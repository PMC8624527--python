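"""Joint identification of the local-model count S and parameters theta_i.

The mixed-integer problem — assign every modeling vector z(k) = [X(k), y(k)]
to one of S affine local models while estimating each model's parameters — is
approached with a cluster-coupled particle swarm.  A particle encodes all S
local models at once,

    position = [theta_1, Z_1, theta_2, Z_2, ..., theta_S, Z_S],

where theta_i (dimension n+1, affine term last) are the local ARX parameters
and Z_i (dimension n+1) the cluster centers in z-space.  Fitness is the sum of
squared one-step residuals J1 under the nearest-center assignment of the
modeling vectors.  S itself is found by an incremental outer loop: starting at
S = 1, the swarm minimizes J1; if the best J1 stays above a threshold Y_ts the
loop restarts with S + 1, so the lexicographic reading of the two-objective
problem (smallest S whose fit reaches the threshold) is solved exactly.

The swarm explores theta jointly with the centers; an optional per-cluster
least-squares polish (off by default) replaces each theta_i by the ordinary
least-squares fit of its cluster after the swarm finishes, which can only
lower J1 for fixed labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import RegressionDataset
from .icf_pso import SwarmConfig, optimize
from .prediction_eval import PWARXModel

logger = logging.getLogger("pwasoft")


# ---------------------------------------------------------------------------
# Particle encoding
# ---------------------------------------------------------------------------

@dataclass
class ParticleEncoding:
    """S local models (theta_i, center Z_i) packed into one position vector.

    Flattening layout: ``[theta_1, Z_1, ..., theta_S, Z_S]`` with
    ``dim(theta_i) = dim(Z_i) = n + 1``, so the position dimension is
    ``2 * S * (n + 1)``.
    """

    S: int
    n: int                       # regressor dimension n_y + n_u * r
    thetas: np.ndarray           # (S, n + 1)
    centers: np.ndarray          # (S, n + 1)

    def __post_init__(self) -> None:
        self.thetas = np.atleast_2d(np.asarray(self.thetas, dtype=float))
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        d = self.n + 1
        if self.thetas.shape != (self.S, d) or self.centers.shape != (self.S, d):
            raise ValueError(
                f"encoding shapes {self.thetas.shape}/{self.centers.shape} "
                f"inconsistent with S={self.S}, n={self.n}"
            )

    @property
    def position_dim(self) -> int:
        return 2 * self.S * (self.n + 1)

    def encode(self) -> np.ndarray:
        blocks = []
        for i in range(self.S):
            blocks.append(self.thetas[i])
            blocks.append(self.centers[i])
        return np.concatenate(blocks)

    @classmethod
    def decode(cls, position: np.ndarray, S: int, n: int) -> "ParticleEncoding":
        d = n + 1
        pos = np.asarray(position, dtype=float).ravel()
        if len(pos) != 2 * S * d:
            raise ValueError(f"position length {len(pos)} != 2*S*(n+1) = {2 * S * d}")
        blocks = pos.reshape(S, 2 * d)
        return cls(S=S, n=n, thetas=blocks[:, :d].copy(), centers=blocks[:, d:].copy())


# ---------------------------------------------------------------------------
# Clustering and the J1 objective
# ---------------------------------------------------------------------------

def assign_clusters(z_vectors: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign each modeling vector to its nearest center (Euclidean norm).

    Ties break to the lowest center index.  Returns (labels, per-cluster
    counts M_i); the counts always sum to the number of vectors.
    """
    Z = np.atleast_2d(np.asarray(z_vectors, dtype=float))
    C = np.atleast_2d(np.asarray(centers, dtype=float))
    if Z.shape[1] != C.shape[1]:
        raise ValueError(
            f"z dimension {Z.shape[1]} != center dimension {C.shape[1]}"
        )
    labels = np.argmin(cdist(Z, C), axis=1)
    counts = np.bincount(labels, minlength=len(C))
    return labels, counts


def _residuals(thetas: np.ndarray, labels: np.ndarray, dataset: RegressionDataset) -> np.ndarray:
    Phi = np.column_stack([dataset.X, np.ones(len(dataset))])
    return dataset.y - np.einsum("ij,ij->i", Phi, thetas[labels])


EMPTY_CLUSTER_PENALTY = 10.0


def fitness_J1(encoding: ParticleEncoding, dataset: RegressionDataset) -> float:
    """Sum of squared one-step residuals under nearest-center assignment.

    Each empty cluster adds ``10 x`` the J1 of the non-empty part as a
    penalty, discouraging degenerate solutions that inflate S without using
    every local model.
    """
    if encoding.n != dataset.n:
        raise ValueError(
            f"encoding regressor dimension {encoding.n} != dataset {dataset.n}"
        )
    labels, counts = assign_clusters(dataset.z, encoding.centers)
    res = _residuals(encoding.thetas, labels, dataset)
    J1 = float(res @ res)
    n_empty = int((counts == 0).sum())
    if n_empty:
        J1 *= 1.0 + EMPTY_CLUSTER_PENALTY * n_empty
    return J1


def refine_local_parameters(
    labels: np.ndarray, dataset: RegressionDataset, S: int | None = None
) -> np.ndarray:
    """Per-cluster ordinary least squares of y on [X, 1].

    Rank-deficient (e.g. single-point) clusters get the minimum-norm solution
    with a warning; empty clusters raise.  Serves both as an opt-in polish of
    the swarm's thetas and as the oracle defining attainable parameters in
    recovery experiments.
    """
    labels = np.asarray(labels)
    if S is None:
        S = int(labels.max()) + 1
    Phi = np.column_stack([dataset.X, np.ones(len(dataset))])
    thetas = np.zeros((S, dataset.n + 1))
    for i in range(S):
        m = labels == i
        if not m.any():
            raise ValueError(f"cluster {i} is empty; cannot refine")
        if m.sum() < Phi.shape[1]:
            logger.warning(
                "cluster %d has %d points for %d parameters; minimum-norm "
                "solution used", i, int(m.sum()), Phi.shape[1]
            )
        thetas[i], *_ = np.linalg.lstsq(Phi[m], dataset.y[m], rcond=None)
    return thetas


# ---------------------------------------------------------------------------
# Incremental-S identification loop
# ---------------------------------------------------------------------------

@dataclass
class IdentificationResult:
    """Outcome of the incremental-S swarm identification."""

    model: PWARXModel                 # surfaces not yet attached
    labels: np.ndarray                # cluster label per modeling vector
    cluster_sizes: np.ndarray         # M_i, sums to len(dataset)
    J1: float                         # best objective at the returned S
    Y_ts: float                       # threshold used
    termination: str                  # "threshold_met" or "s_cap_reached"
    traces: dict = field(default_factory=dict)   # per-S best-J1 PSO traces
    best_J1_per_S: dict = field(default_factory=dict)


def default_threshold(dataset: RegressionDataset, fraction: float = 0.01) -> float:
    """Default J1 search threshold: *fraction* of the total output variance."""
    y = dataset.y
    return float(fraction * np.sum((y - y.mean()) ** 2))


def _farthest_point_centers(
    z: np.ndarray, S: int, rng: np.random.Generator
) -> np.ndarray:
    """Greedy farthest-point sample of S rows of z (random first pick)."""
    idx = [int(rng.integers(len(z)))]
    while len(idx) < S:
        d = cdist(z, z[idx]).min(axis=1)
        d[idx] = -1.0
        idx.append(int(np.argmax(d)))
    return z[idx].copy()


def _initial_positions(
    dataset: RegressionDataset,
    S: int,
    config: SwarmConfig,
    rng: np.random.Generator,
    theta_bound: float,
) -> np.ndarray:
    z = dataset.z
    d = dataset.n + 1
    pos = np.empty((config.n_particles, 2 * S * d))
    for i in range(config.n_particles):
        enc = ParticleEncoding(
            S=S, n=dataset.n,
            thetas=rng.uniform(-1.0, 1.0, size=(S, d)),
            centers=_farthest_point_centers(z, S, rng),
        )
        pos[i] = enc.encode()
    return np.clip(pos, -theta_bound, theta_bound)


def _make_bounds(dataset: RegressionDataset, S: int, theta_bound: float):
    z = dataset.z
    d = dataset.n + 1
    zlo, zhi = z.min(axis=0), z.max(axis=0)
    span = np.where(zhi > zlo, zhi - zlo, 1.0)
    zlo = zlo - 0.05 * span
    zhi = zhi + 0.05 * span
    lo = np.concatenate([np.concatenate([np.full(d, -theta_bound), zlo]) for _ in range(S)])
    hi = np.concatenate([np.concatenate([np.full(d, theta_bound), zhi]) for _ in range(S)])
    return lo, hi


def _make_repair(dataset: RegressionDataset, S: int, polish: bool):
    """Particle repair hook.

    Always re-seats the centers of empty clusters onto the worst-fit points.
    With ``polish=True`` (the refine mode) it additionally replaces each
    particle's theta block by the per-cluster least-squares solution for its
    current labels — a memetic local step that reduces the search to the
    cluster centers, which is what makes the incremental-S loop reliable.
    """
    Phi = np.column_stack([dataset.X, np.ones(len(dataset))])

    def repair(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        enc = ParticleEncoding.decode(position, S, dataset.n)
        labels, counts = assign_clusters(dataset.z, enc.centers)
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            res = np.abs(_residuals(enc.thetas, labels, dataset))
            order = np.argsort(res)[::-1]
            for rank, i in enumerate(empty):
                enc.centers[i] = dataset.z[order[rank % len(order)]]
            labels, counts = assign_clusters(dataset.z, enc.centers)
        if polish:
            for i in np.flatnonzero(counts > 0):
                m = labels == i
                enc.thetas[i], *_ = np.linalg.lstsq(Phi[m], dataset.y[m], rcond=None)
        return enc.encode()

    return repair


def identify_pwarx(
    dataset: RegressionDataset,
    swarm_config: SwarmConfig | None = None,
    S_max: int = 6,
    Y_ts: float | None = None,
    refine: bool = False,
    theta_bound: float = 10.0,
    n_restarts: int = 1,
) -> IdentificationResult:
    """Find the smallest S whose swarm-optimized J1 meets the threshold Y_ts.

    For S = 1, 2, ... the swarm minimizes :func:`fitness_J1` over the
    concatenated (theta_i, Z_i) encoding; theta coordinates are bounded by
    ``[-theta_bound, theta_bound]`` (data are expected on the [-1, 1]
    normalized scale) and centers by the z-space bounding box.  If no S up to
    ``S_max`` meets the threshold, the S with the smallest J1 is returned,
    flagged ``"s_cap_reached"``.  ``refine=True`` applies the per-cluster
    least-squares polish to the swarm's best encoding before the threshold
    test (it can only lower J1 for fixed labels).

    Fully deterministic for a fixed ``swarm_config.seed``.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if S_max < 1:
        raise ValueError("S_max must be >= 1")
    config = swarm_config if swarm_config is not None else SwarmConfig()
    if Y_ts is None:
        Y_ts = default_threshold(dataset)
        logger.info("identify_pwarx: default Y_ts = %.6g (1%% of output variance)", Y_ts)
    traces: dict[int, np.ndarray] = {}
    best_per_S: dict[int, float] = {}
    best_overall: tuple[float, int, ParticleEncoding] | None = None
    termination = "s_cap_reached"
    for S in range(1, S_max + 1):
        D = 2 * S * (dataset.n + 1)
        lo, hi = _make_bounds(dataset, S, theta_bound)
        fitness = lambda pos, S=S: fitness_J1(
            ParticleEncoding.decode(pos, S, dataset.n), dataset
        )
        best_J1, enc, trace = np.inf, None, None
        for attempt in range(max(n_restarts, 1)):
            sub_seed = config.seed + 7919 * S + 104729 * attempt
            rng = np.random.default_rng(sub_seed)
            # the raw-J1 threshold is kept active even when refining: the
            # polish can only lower J1 further for the labels the swarm
            # settled on
            cfg = replace(
                config, bounds=(lo, hi), fitness_threshold=Y_ts, seed=sub_seed,
            )
            init = _initial_positions(dataset, S, cfg, rng, theta_bound)
            init = np.clip(init, lo, hi)
            best_pos, J1_a, info = optimize(
                fitness, D, cfg,
                init_positions=init,
                repair_fn=_make_repair(dataset, S, polish=refine),
            )
            enc_a = ParticleEncoding.decode(best_pos, S, dataset.n)
            labels_a, counts_a = assign_clusters(dataset.z, enc_a.centers)
            if refine and (counts_a > 0).all():
                polished = refine_local_parameters(labels_a, dataset, S)
                enc_a = ParticleEncoding(
                    S=S, n=dataset.n, thetas=polished, centers=enc_a.centers
                )
                J1_a = fitness_J1(enc_a, dataset)
            if J1_a < best_J1:
                best_J1, enc, trace = J1_a, enc_a, info["trace"]
            if best_J1 <= Y_ts:
                break
        traces[S] = trace
        best_per_S[S] = best_J1
        logger.info(
            "identify_pwarx: S=%d best J1=%.6g (threshold %.6g, %s)",
            S, best_J1, Y_ts, info["reason"],
        )
        if best_overall is None or best_J1 < best_overall[0]:
            best_overall = (best_J1, S, enc)
        if best_J1 <= Y_ts:
            termination = "threshold_met"
            best_overall = (best_J1, S, enc)
            break
    assert best_overall is not None
    J1, S, enc = best_overall
    labels, counts = assign_clusters(dataset.z, enc.centers)
    if termination == "s_cap_reached":
        logger.warning(
            "identify_pwarx: threshold %.6g not met up to S_max=%d; returning "
            "S=%d with J1=%.6g", Y_ts, S_max, S, J1
        )
    model = PWARXModel(
        n_y=dataset.n_y, n_u=dataset.n_u, p=dataset.p, r=dataset.r,
        target=dataset.target,
        thetas=enc.thetas, centers=enc.centers,
        metadata={
            "seed": int(config.seed),
            "Y_ts": float(Y_ts),
            "refined": bool(refine),
            "termination": termination,
        },
    )
    return IdentificationResult(
        model=model,
        labels=labels,
        cluster_sizes=counts,
        J1=float(J1),
        Y_ts=float(Y_ts),
        termination=termination,
        traces=traces,
        best_J1_per_S=best_per_S,
    )
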