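"""Model-order selection by false nearest neighbors and Cao's statistics.

For an ARX-type model the regressor dimension is n = n_y + n_u * r (n_y output
lags, n_u input lags over r input channels).  Choosing (n_y, n_u) is an
embedding-dimension problem: if the embedding is too small, points that are far
apart on the true trajectory collapse onto neighbors ("false neighbors") that
separate again when a coordinate is added.

Two diagnostics are computed over a nested schedule of candidate lag
structures (output lag added first: (1,1), (2,1), (2,2), (3,2), ...):

* the false-nearest-neighbor (FNN) fraction at threshold R_T — a neighbor is
  false when appending the next coordinate grows its L-infinity distance by
  more than a factor R_T relative to the current distance (Kennel's
  criterion; a variant dividing by the *grown* distance is kept behind a flag
  but can never fire for R_T >= 10 because L-infinity distances only grow
  under coordinate nesting, making that ratio < 1),
* Cao's E(n) — the mean distance-growth factor alpha(p, n) of each point's
  nearest neighbor — and E0(n) = E(n+1)/E(n), whose stabilization near 1
  marks the minimum embedding dimension.

Because exogenous input lags carry innovations that no embedding can predict,
E0 on input/output data proposes a total-lag budget rather than a unique
split; the final (n_y, n_u) is disambiguated by one-step least-squares ARX
residual on a held-out slice, with a parsimony rule (smallest split whose
residual is within 5% of the best).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger("pwasoft")


# ---------------------------------------------------------------------------
# Lag-structure schedule and embedding vectors
# ---------------------------------------------------------------------------

def embedding_schedule(max_steps: int, with_input: bool = True) -> list[tuple[int, int]]:
    """Nested (n_y, n_u) schedule, output lag first.

    With input: (1,1), (2,1), (2,2), (3,2), (3,3), ...  Step s has
    n_y + n_u = s + 1 total lags.  Without input (scalar series embedding):
    (1,0), (2,0), (3,0), ...
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if not with_input:
        return [(s, 0) for s in range(1, max_steps + 1)]
    out = []
    n_y, n_u = 1, 1
    for s in range(max_steps):
        out.append((n_y, n_u))
        if n_y == n_u:
            n_y += 1
        else:
            n_u += 1
    return out


def embedding_vectors(
    y: np.ndarray, u: np.ndarray | None, n_y: int, n_u: int, trim: int
) -> np.ndarray:
    """Lag vectors [y(k-1)..y(k-n_y), u(k-1)..u(k-n_u)] for k = trim..N-1.

    ``trim`` fixes the first usable index so vector sets of different lag
    structures share time indices (required for nesting comparisons).
    """
    y = np.asarray(y, dtype=float).ravel()
    N = len(y)
    if trim < max(n_y, n_u):
        raise ValueError("trim smaller than the lag window")
    if N <= trim:
        raise ValueError("series shorter than the lag window")
    cols = [y[trim - i: N - i] for i in range(1, n_y + 1)]
    if n_u:
        if u is None:
            raise ValueError("n_u > 0 but no input series given")
        u2 = np.asarray(u, dtype=float)
        if u2.ndim == 1:
            u2 = u2[:, None]
        for j in range(1, n_u + 1):
            cols.append(u2[trim - j: N - j])
    return np.column_stack([np.atleast_2d(c).reshape(N - trim, -1) for c in cols])


# ---------------------------------------------------------------------------
# Nearest neighbors and FNN
# ---------------------------------------------------------------------------

def linf_nearest_neighbor(vectors: np.ndarray, p_index: int) -> tuple[int, float]:
    """Index and distance of the L-infinity nearest neighbor of one point.

    Self-matches are excluded; ties break to the smallest index.
    """
    V = np.asarray(vectors, dtype=float)
    if V.ndim != 2 or len(V) < 2:
        raise ValueError("need >= 2 vectors of equal dimension")
    d = np.max(np.abs(V - V[p_index]), axis=1)
    d[p_index] = np.inf
    j = int(np.argmin(d))
    return j, float(d[j])


def _all_nearest(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized L-infinity nearest neighbor for every point (ties: lowest index)."""
    D = cdist(vectors, vectors, metric="chebyshev")
    np.fill_diagonal(D, np.inf)
    idx = np.argmin(D, axis=1)
    return idx, D[np.arange(len(vectors)), idx]


def false_neighbor_ratio(
    vectors_n: np.ndarray,
    vectors_n1: np.ndarray,
    R_T: float = 10.0,
    printed_variant: bool = False,
) -> float:
    """Fraction of points whose nearest neighbor is false at threshold R_T.

    The neighbor found at dimension n is re-measured after appending the next
    coordinate(s); it is false when the relative distance growth
    ``|d_(n+1) - d_n| / d_n`` reaches R_T.  ``printed_variant=True`` divides
    by ``d_(n+1)`` instead (that ratio is bounded below 1 under nesting, so no
    neighbor can be flagged at R_T >= 10; retained for comparison only).
    Points with zero dimension-n distance are skipped.
    """
    Vn = np.asarray(vectors_n, dtype=float)
    V1 = np.asarray(vectors_n1, dtype=float)
    if len(Vn) != len(V1):
        raise ValueError("vector sets must have equal length")
    idx, dn = _all_nearest(Vn)
    d1 = np.max(np.abs(V1 - V1[idx]), axis=1)
    keep = dn > 0
    skipped = int((~keep).sum())
    if skipped:
        logger.debug("false_neighbor_ratio: skipped %d zero-distance points", skipped)
    if not keep.any():
        return 0.0
    if printed_variant:
        ratio = np.abs(d1[keep] - dn[keep]) / d1[keep]
    else:
        ratio = np.abs(d1[keep] - dn[keep]) / dn[keep]
    return float(np.mean(ratio >= R_T))


# ---------------------------------------------------------------------------
# Cao's statistics
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingDiagnostics:
    """Per-step FNN and Cao statistics over the lag-structure schedule.

    ``E``/``E0`` are Cao's mean distance-growth statistics; ``E_star``/``E2``
    are the companion statistics on the appended coordinate alone, whose
    flatness at 1 across all steps is Cao's signature of a series with no
    finite embedding dimension (``random_like``).
    """

    schedule: list[tuple[int, int]]
    dims: np.ndarray                    # regressor dimension at each step
    fnn_ratio: np.ndarray               # false-neighbor fraction per step
    E: np.ndarray                       # Cao E at each step
    E0: np.ndarray                      # E(s+1)/E(s), length len(E) - 1
    E_star: np.ndarray                  # mean appended-coordinate distance
    E2: np.ndarray                      # E*(s+1)/E*(s), length len(E) - 1
    R_T: float
    tol: float = 0.05
    delta_0: float = 0.02               # FNN-fraction stabilization threshold
    n_skipped_zero_distance: int = 0
    degenerate: bool = False            # all-identical vectors at some step
    random_like: bool = False           # E2 ~ 1 everywhere: no finite dimension
    selected_step: int | None = None    # 1-based index into schedule
    selected_orders: tuple[int, int] | None = None

    def summary(self) -> str:
        rows = ["step  (n_y,n_u)  dim   FNN      E        E0      E2"]
        for s, (o, d, f, e) in enumerate(
            zip(self.schedule, self.dims, self.fnn_ratio, self.E), start=1
        ):
            e0 = f"{self.E0[s - 1]:.4f}" if s - 1 < len(self.E0) else "  -  "
            e2 = f"{self.E2[s - 1]:.4f}" if s - 1 < len(self.E2) else "  -  "
            rows.append(f"{s:>4}  {o!s:>9}  {d:>3}  {f:6.3f}  {e:7.3f}  {e0}  {e2}")
        return "\n".join(rows)


def cao_statistics(
    y: np.ndarray,
    u: np.ndarray | None = None,
    n_max: int = 8,
    R_T: float = 10.0,
    schedule: list[tuple[int, int]] | None = None,
    tol: float = 0.05,
) -> EmbeddingDiagnostics:
    """Compute FNN fractions and Cao's E(n), E0(n) over the lag schedule.

    For each step s the nearest neighbor of every point is found at the step-s
    embedding; alpha(p, s) is the factor by which that pair's L-infinity
    distance grows at step s+1, E(s) is the mean over points, and
    E0(s) = E(s+1)/E(s).  Zero-distance pairs are excluded from the mean
    (counted in the diagnostics).  E0 staying within ``1 +/- tol`` for every
    step marks a series with no finite embedding dimension (e.g. white noise).
    """
    y = np.asarray(y, dtype=float).ravel()
    if schedule is None:
        schedule = embedding_schedule(n_max, with_input=u is not None)
    n_steps = len(schedule)
    # one extra structure to measure growth out of the last step
    extended = schedule + [_next_step(schedule)]
    trim = max(max(ny, nu) for ny, nu in extended)
    if len(y) - trim < 2:
        raise ValueError(
            f"series of length {len(y)} too short for the schedule "
            f"(needs > {trim + 1} samples)"
        )
    vecs = _accretion_vectors(y, u, extended, trim)
    E = np.full(n_steps, np.nan)
    E_star = np.full(n_steps, np.nan)
    fnn = np.full(n_steps, np.nan)
    skipped_total = 0
    degenerate = False
    for s in range(n_steps):
        Vn, V1 = vecs[s], vecs[s + 1]
        idx, dn = _all_nearest(Vn)
        d1 = np.max(np.abs(V1 - V1[idx]), axis=1)
        # appended-coordinate distance: the new columns of step s+1 only
        new = V1[:, Vn.shape[1]:]
        E_star[s] = float(np.mean(np.max(np.abs(new - new[idx]), axis=1)))
        keep = dn > 0
        skipped_total += int((~keep).sum())
        if not keep.any():
            degenerate = True
            logger.warning(
                "cao_statistics: all dimension-%d distances are zero "
                "(identical vectors); step flagged degenerate", s + 1
            )
            E[s] = np.nan
            fnn[s] = 0.0
            continue
        alpha = d1[keep] / dn[keep]
        E[s] = float(np.mean(alpha))
        growth = np.abs(d1[keep] - dn[keep]) / dn[keep]
        fnn[s] = float(np.mean(growth >= R_T))
    with np.errstate(invalid="ignore"):
        E0 = E[1:] / E[:-1]
        E2 = E_star[1:] / E_star[:-1]
    finite = np.isfinite(E2)
    random_like = bool(finite.any() and np.all(np.abs(E2[finite] - 1.0) < tol))
    if random_like:
        logger.warning(
            "cao_statistics: E2 within 1 +/- %.3g at every step — the series "
            "behaves like noise (no finite embedding dimension)", tol
        )
    return EmbeddingDiagnostics(
        schedule=schedule,
        dims=np.array([v.shape[1] for v in vecs[:n_steps]]),
        fnn_ratio=fnn,
        E=E,
        E0=E0,
        E_star=E_star,
        E2=E2,
        R_T=R_T,
        tol=tol,
        n_skipped_zero_distance=skipped_total,
        degenerate=degenerate,
        random_like=random_like,
    )


def _accretion_vectors(
    y: np.ndarray,
    u: np.ndarray | None,
    schedule: list[tuple[int, int]],
    trim: int,
) -> list[np.ndarray]:
    """Prefix-nested embedding matrices along the schedule.

    Columns are appended in schedule order (new lag blocks go last), so the
    step-s matrix is a literal prefix of the step-(s+1) matrix; L-infinity
    distances are permutation-invariant, so this matches the canonical
    y-lags-then-u-lags layout.
    """
    y = np.asarray(y, dtype=float).ravel()
    N = len(y)
    if u is not None:
        u2 = np.asarray(u, dtype=float)
        if u2.ndim == 1:
            u2 = u2[:, None]
    cols: list[np.ndarray] = []
    out = []
    prev_ny = prev_nu = 0
    for ny, nu in schedule:
        for lag in range(prev_ny + 1, ny + 1):
            cols.append(y[trim - lag: N - lag][:, None])
        for lag in range(prev_nu + 1, nu + 1):
            if u is None:
                raise ValueError("schedule requests input lags but u is None")
            cols.append(u2[trim - lag: N - lag])
        prev_ny, prev_nu = ny, nu
        out.append(np.hstack(cols))
    return out


def _next_step(schedule: list[tuple[int, int]]) -> tuple[int, int]:
    ny, nu = schedule[-1]
    if nu == 0:
        return (ny + 1, 0)
    return (ny + 1, nu) if ny == nu else (ny, nu + 1)


# ---------------------------------------------------------------------------
# Order selection
# ---------------------------------------------------------------------------

def _arx_holdout_rss(
    y: np.ndarray, u: np.ndarray | None, n_y: int, n_u: int, holdout: float = 0.3
) -> float:
    """One-step least-squares ARX residual on a trailing held-out slice."""
    trim = max(n_y, n_u)
    X = embedding_vectors(y, u, n_y, n_u, trim)
    t = np.asarray(y, dtype=float).ravel()[trim:]
    Phi = np.column_stack([X, np.ones(len(X))])
    split = max(len(t) - int(round(holdout * len(t))), Phi.shape[1])
    if split >= len(t):
        raise ValueError("series too short for a held-out slice")
    theta, *_ = np.linalg.lstsq(Phi[:split], t[:split], rcond=None)
    resid = t[split:] - Phi[split:] @ theta
    return float(resid @ resid)


def select_orders(
    y: np.ndarray,
    u: np.ndarray | None = None,
    n_max: int = 8,
    R_T: float = 10.0,
    tol: float = 0.05,
    holdout: float = 0.3,
    delta_0: float = 0.02,
) -> tuple[int, int, EmbeddingDiagnostics]:
    """Select (n_y, n_u) by FNN/Cao stabilization plus held-out ARX ranking.

    Two stabilization signals are scanned along the schedule: the FNN fraction
    dropping below ``delta_0`` (the false-neighbor count reaching ~zero marks
    the minimum embedding directly), and ``|E0(s) - 1| < tol`` (Cao
    stabilization, pointing at step s+1 by the n+1 rule).  The earlier of the
    two proposals fixes a total-lag budget L.  All splits with
    ``n_y + n_u <= L + 1`` (n_y, n_u >= 1) are then ranked by one-step ARX
    residual on a held-out slice and the smallest split within 5% of the best
    residual wins (ties at equal size: more output lags first, matching the
    output-first schedule).
    """
    diag = cao_statistics(y, u, n_max=n_max, R_T=R_T, tol=tol)
    diag.delta_0 = delta_0
    proposals = []
    fnn_ok = np.flatnonzero(
        np.isfinite(diag.fnn_ratio) & (diag.fnn_ratio < delta_0)
    )
    if fnn_ok.size:
        proposals.append(int(fnn_ok[0]) + 1)       # FNN marks the step directly
    e0_ok = [
        s for s in np.flatnonzero(np.isfinite(diag.E0))
        if abs(diag.E0[s] - 1.0) < tol
    ]
    if e0_ok:
        # E0 settles at step s (1-based s+1); min embedding is the next step
        proposals.append(min(int(e0_ok[0]) + 2, len(diag.schedule)))
    if not proposals:
        raise ValueError(
            f"neither the FNN fraction (< {delta_0}) nor E0 (within {tol} of 1) "
            f"stabilizes over {n_max} schedule steps; increase n_max"
        )
    s_min = min(proposals)
    diag.selected_step = s_min
    if u is None:
        n_y = diag.schedule[s_min - 1][0]
        diag.selected_orders = (n_y, 0)
        return n_y, 0, diag
    L = sum(diag.schedule[s_min - 1])             # total-lag budget
    candidates = [
        (ny, nu)
        for total in range(2, L + 2)
        for ny in range(1, total)
        for nu in (total - ny,)
    ]
    scored = []
    for ny, nu in candidates:
        try:
            scored.append(((ny, nu), _arx_holdout_rss(y, u, ny, nu, holdout)))
        except (ValueError, np.linalg.LinAlgError):
            continue
    if not scored:
        raise ValueError("no candidate split could be scored; series too short")
    scale = float(np.sum(np.square(np.asarray(y, dtype=float))))
    best = min(rss for _, rss in scored)
    admissible = [
        (ny + nu, -ny, (ny, nu))
        for (ny, nu), rss in scored
        if rss <= 1.05 * best + 1e-12 * scale
    ]
    _, _, (n_y, n_u) = min(admissible)
    diag.selected_orders = (n_y, n_u)
    logger.info(
        "select_orders: stabilization at step %d -> budget %d lags; chose "
        "(n_y, n_u) = (%d, %d)\n%s", s_min, L, n_y, n_u, diag.summary()
    )
    return n_y, n_u, diag
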