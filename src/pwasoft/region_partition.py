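"""Dividing surfaces between local-model regions via least-squares SVM.

After clustering has split the modeling vectors into S groups, each pair of
*adjacent* groups (adjacency by the nearest-cluster-center rule) is separated
by an oriented hyperplane w^T X + v = 0 in regressor space, trained as a
two-class least-squares support vector machine: instead of the standard SVM
quadratic program, equality constraints with squared slacks reduce training to
one symmetric linear system

    [[0, y^T], [y, Omega + I/gamma]] [b; alpha] = [0; 1],

with Omega_kl = y_k y_l K(x_k, x_l).  For the linear kernel the primal weight
vector is recovered as w = sum_k alpha_k y_k x_k, which is what yields explicit
hyperplane parameters; an RBF kernel is supported for the sign classifier but
cannot emit a hyperplane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger("pwasoft")


# ---------------------------------------------------------------------------
# Adjacency of cluster regions
# ---------------------------------------------------------------------------

def adjacent_subspaces(centers: np.ndarray) -> list[tuple[int, int]]:
    """Adjacent region pairs by the nearest-other-center rule.

    Each cluster is adjacent to the cluster whose center is nearest to its
    own; the deduplicated, sorted pair list is returned (0-based indices).
    Non-mutually-nearest pairs are absent by construction, which is why a
    model can have fewer surfaces than ``S*(S-1)/2``.
    """
    C = np.atleast_2d(np.asarray(centers, dtype=float))
    S = len(C)
    if S < 2:
        logger.info("adjacent_subspaces: fewer than 2 centers, no surfaces needed")
        return []
    D = cdist(C, C)
    np.fill_diagonal(D, np.inf)
    pairs = set()
    for i in range(S):
        dmin = D[i].min()
        # exact ties (e.g. symmetric center layouts) make every tied
        # neighbor adjacent
        for j in np.flatnonzero(D[i] <= dmin * (1.0 + 1e-12)):
            pairs.add((min(i, j), max(i, j)))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# LS-SVM training
# ---------------------------------------------------------------------------

@dataclass
class LSSVMModel:
    """Trained least-squares SVM classifier.

    ``alpha`` (one multiplier per training point) and bias ``b`` solve the
    KKT linear system; ``gamma`` is the slack penalty weight (the larger, the
    harder the margin).
    """

    alpha: np.ndarray
    b: float
    kernel: str                 # "linear" or "rbf"
    gamma: float
    rbf_width: float
    X: np.ndarray               # training inputs, (N, n)
    labels: np.ndarray          # training labels in {-1, +1}
    kkt_residual: float = 0.0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        K = _kernel_matrix(np.atleast_2d(X), self.X, self.kernel, self.rbf_width)
        return K @ (self.alpha * self.labels) + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0.0, 1, -1)


def _kernel_matrix(A: np.ndarray, B: np.ndarray, kernel: str, rbf_width: float) -> np.ndarray:
    if kernel == "linear":
        return A @ B.T
    if kernel == "rbf":
        return np.exp(-cdist(A, B, "sqeuclidean") / rbf_width**2)
    raise ValueError(f"unknown kernel {kernel!r}")


def lssvm_solve(
    points: np.ndarray,
    labels: np.ndarray,
    kernel: str = "linear",
    lssvm_gamma: float = 10.0,
    rbf_width: float = 0.2,
) -> LSSVMModel:
    """Train an LS-SVM by solving its (N+1)x(N+1) KKT linear system.

    Raises if one class is absent or the system is numerically singular.
    The solution is checked against the assembled system (relative residual)
    and satisfies ``sum_k alpha_k y_k = 0`` (first block row).
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    y = np.asarray(labels, dtype=float).ravel()
    if len(X) != len(y):
        raise ValueError("points and labels lengths differ")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be -1 or +1")
    if (y > 0).sum() == 0 or (y < 0).sum() == 0:
        raise ValueError("both classes must be present")
    if lssvm_gamma <= 0:
        raise ValueError("lssvm_gamma must be positive")
    N = len(X)
    K = _kernel_matrix(X, X, kernel, rbf_width)
    Omega = np.outer(y, y) * K
    A = np.zeros((N + 1, N + 1))
    A[0, 1:] = y
    A[1:, 0] = y
    A[1:, 1:] = Omega + np.eye(N) / lssvm_gamma
    rhs = np.concatenate([[0.0], np.ones(N)])
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            f"LS-SVM system is numerically singular (condition number {cond:.3g})"
        )
    sol = np.linalg.solve(A, rhs)
    b, alpha = float(sol[0]), sol[1:]
    res = float(np.linalg.norm(A @ sol - rhs) / max(np.linalg.norm(rhs), 1.0))
    return LSSVMModel(
        alpha=alpha, b=b, kernel=kernel, gamma=lssvm_gamma,
        rbf_width=rbf_width, X=X, labels=y, kkt_residual=res,
    )


# ---------------------------------------------------------------------------
# Hyperplane extraction and the region map
# ---------------------------------------------------------------------------

@dataclass
class DividingSurface:
    """Oriented hyperplane separating two adjacent local-model regions.

    Convention: ``w^T X + v >= 0`` is the side of region ``i`` (the
    lower-indexed region of the pair); points exactly on the surface belong
    to region ``i`` (closed polyhedra).
    """

    region_i: int
    region_j: int
    w: np.ndarray
    v: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        if not np.linalg.norm(self.w) > 0:
            raise ValueError("dividing surface has zero normal vector")

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.w + self.v

    def to_dict(self) -> dict:
        return {
            "region_i": int(self.region_i), "region_j": int(self.region_j),
            "w": self.w.tolist(), "v": float(self.v),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DividingSurface":
        return cls(d["region_i"], d["region_j"], np.asarray(d["w"]), float(d["v"]))


def extract_hyperplane(model: LSSVMModel) -> tuple[np.ndarray, float]:
    """Primal hyperplane (w, v) of a linear-kernel LS-SVM.

    ``w = sum_k alpha_k y_k x_k``; the offset is averaged over all training
    points, ``v = mean(y_k - w^T x_k)``, the numerically stable version of
    reading it off a single support vector.
    """
    if model.kernel != "linear":
        raise ValueError(
            "hyperplane parameters require a linear kernel; RBF models only "
            "provide the sign classifier"
        )
    w = model.X.T @ (model.alpha * model.labels)
    v = float(np.mean(model.labels - model.X @ w))
    return w, v


def fit_dividing_surfaces(
    X: np.ndarray,
    labels: np.ndarray,
    centers: np.ndarray,
    lssvm_gamma: float = 10.0,
) -> list[DividingSurface]:
    """Train one linear LS-SVM per adjacent cluster pair and extract surfaces.

    ``X`` are regression vectors, ``labels`` their cluster indices, and
    ``centers`` the cluster centers in z-space (the leading n coordinates are
    used for adjacency in X-space terms).  The lower-indexed region of each
    pair is the +1 class, so its side is ``w^T X + v >= 0``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    pairs = adjacent_subspaces(centers)
    surfaces = []
    for i, j in pairs:
        mask = (labels == i) | (labels == j)
        if (labels == i).sum() == 0 or (labels == j).sum() == 0:
            logger.warning("surface (%d,%d): one cluster empty, skipped", i, j)
            continue
        y = np.where(labels[mask] == i, 1.0, -1.0)
        svm = lssvm_solve(X[mask], y, kernel="linear", lssvm_gamma=lssvm_gamma)
        w, v = extract_hyperplane(svm)
        surf = DividingSurface(i, j, w, v)
        agree = float(np.mean(np.sign(surf.evaluate(X[mask])) == np.sign(y)))
        if agree < 0.95:
            logger.warning(
                "surface (%d,%d): only %.1f%% of its training points on the "
                "stored side — clusters may not be linearly separable",
                i, j, 100 * agree,
            )
        surfaces.append(surf)
    logger.info("adjacency pairs: %s", pairs)
    return surfaces


def assign_region(
    X: np.ndarray,
    surfaces: list[DividingSurface],
    centers: np.ndarray,
) -> np.ndarray:
    """Map regression vectors to region indices (total, deterministic).

    A point belongs to the first region (in index order) whose sign
    constraints against all its surfaces are satisfied; the boundary value 0
    satisfies both sides, so boundary points land in the lower-indexed region.
    Points with an inconsistent sign pattern (possible with pairwise-trained
    surfaces) fall back to the nearest center in X-space; the count is logged.
    """
    X2 = np.atleast_2d(np.asarray(X, dtype=float))
    C = np.atleast_2d(np.asarray(centers, dtype=float))
    S = len(C)
    out = np.zeros(len(X2), dtype=int)
    if S == 1 or not surfaces:
        return out
    n = X2.shape[1]
    Cx = C[:, :n]  # centers live in z-space; drop the output coordinate
    vals = {(s.region_i, s.region_j): s.evaluate(X2) for s in surfaces}
    ok = np.ones((len(X2), S), dtype=bool)
    for (i, j), g in vals.items():
        ok[:, i] &= g >= 0.0
        ok[:, j] &= g <= 0.0
    has_region = ok.any(axis=1)
    out[has_region] = np.argmax(ok[has_region], axis=1)
    n_fallback = int((~has_region).sum())
    if n_fallback:
        logger.info(
            "assign_region: %d/%d points had inconsistent sign patterns; "
            "fell back to nearest center", n_fallback, len(X2)
        )
        d = cdist(X2[~has_region], Cx)
        out[~has_region] = np.argmin(d, axis=1)
    return out
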