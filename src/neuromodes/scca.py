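"""Sparse canonical correlation analysis via penalized rank-1 matrix decomposition.

The solver maximizes ``u' X'Y v`` subject to ``||u||_2 <= 1``, ``||v||_2 <= 1``
and L1 bounds on both weight vectors, by alternating soft-thresholded updates
on the cross-product matrix (the diagonal-covariance surrogate of CCA that is
the standard sparse-CCA algorithm).  Successive modes are obtained by rank-1
deflation of the cross-product matrix.

L1 penalties are expressed as *fractions* in (0, 1]: a fraction ``c`` maps to
the absolute bound ``clip(c * sqrt(p), 1, sqrt(p))`` on that side's weight
vector, so fraction 1 imposes no sparsity and fractions near 0 force a single
nonzero weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SccaPenalties",
    "CanonicalMode",
    "CanonicalVariates",
    "soft_threshold",
    "l1_constrained_unit_vector",
    "scca_fit",
    "canonical_variates",
]


@dataclass(frozen=True)
class SccaPenalties:
    """L1 penalty fractions for the two data domains.

    ``c_x`` penalizes the first (connectivity) side, ``c_y`` the second
    (task) side.  Both must lie in (0, 1].
    """

    c_x: float = 1.0
    c_y: float = 1.0

    def __post_init__(self) -> None:
        for name, value in (("c_x", self.c_x), ("c_y", self.c_y)):
            if not 0.0 < value <= 1.0:
                raise ValueError(f"penalty fraction {name}={value} outside (0, 1]")

    def absolute_bound(self, fraction: float, p: int) -> float:
        root_p = np.sqrt(p)
        return float(np.clip(fraction * root_p, 1.0, root_p))


@dataclass
class CanonicalMode:
    """One sparse canonical vector pair with its sample canonical correlation."""

    index: int
    u: np.ndarray
    v: np.ndarray
    canonical_r: float
    n_nonzero_u: int
    n_nonzero_v: int
    converged: bool
    iterations: int
    objective_path: np.ndarray = field(repr=False, default=None)


@dataclass
class CanonicalVariates:
    """Per-subject projections onto one canonical mode."""

    xu: np.ndarray
    yv: np.ndarray
    index: int


def soft_threshold(a: np.ndarray, delta: float) -> np.ndarray:
    """Elementwise ``sign(a) * max(|a| - delta, 0)``."""
    if delta < 0:
        raise ValueError("soft-threshold parameter must be nonnegative")
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def _threshold_bisect(abs_a: np.ndarray, c: float, tol: float) -> float:
    lo, hi = 0.0, float(abs_a.max())
    for _ in range(200):
        if hi - lo <= tol * max(1.0, hi):
            break
        mid = 0.5 * (lo + hi)
        s = np.maximum(abs_a - mid, 0.0)
        n2 = np.sqrt(s @ s)
        if n2 == 0 or s.sum() / n2 > c:
            lo = mid
        else:
            hi = mid
    return hi


def _threshold_exact(abs_a: np.ndarray, c: float) -> float:
    """Smallest delta with ``L1/L2 <= c`` after soft-thresholding, in closed
    form.

    On the segment where the top ``k`` magnitudes stay active the squared
    ratio is a rational quadratic in delta, so the crossing solves
    ``(S_k - k d)^2 = c^2 (Q_k - 2 d S_k + k d^2)`` inside that segment.
    """
    b = np.sort(abs_a)[::-1]
    S = np.cumsum(b)
    Q = np.cumsum(b * b)
    ks = np.arange(1, b.size + 1, dtype=float)
    # segment lower delta endpoints b_{k+1} (0 for the last segment)
    lower = np.empty_like(b)
    lower[:-1] = b[1:]
    lower[-1] = 0.0
    l1 = S - ks * lower
    l2sq = Q - 2.0 * lower * S + ks * lower * lower
    # ratio > c  <=>  l1^2 > c^2 * l2sq   (l1 >= 0, avoids sqrt/divide)
    exceeds = l1 * l1 > (c * c) * l2sq
    if not exceeds.any():  # feasible at delta = 0
        return 0.0
    k = int(np.argmax(exceeds)) + 1  # active count on the crossing segment
    Sk, Qk = S[k - 1], Q[k - 1]
    A = k * (k - c * c)
    B = 2.0 * Sk * (c * c - k)
    Cq = Sk * Sk - c * c * Qk
    hi_end = b[k - 1]
    lo_end = lower[k - 1]
    if abs(A) < 1e-300:
        # c^2 == k: the ratio is constant on the segment; any delta there is
        # feasible, so take the segment's lower end (B vanishes with A)
        delta = lo_end if abs(B) < 1e-300 else -Cq / B
    else:
        disc = max(B * B - 4.0 * A * Cq, 0.0)
        root = disc**0.5
        candidates = [(-B - root) / (2 * A), (-B + root) / (2 * A)]
        inside = [d for d in candidates if lo_end - 1e-12 <= d <= hi_end + 1e-12]
        delta = min(inside) if inside else lo_end
    return float(min(max(delta, lo_end), hi_end))


def l1_constrained_unit_vector(
    a: np.ndarray, c: float, tol: float = 1e-8, method: str = "exact"
) -> np.ndarray:
    """Soft-threshold ``a`` and renormalize so the L2 norm is 1 and the L1
    norm is at most ``c``.

    The threshold is the smallest ``delta >= 0`` for which the normalized
    thresholded vector satisfies the L1 bound; ``delta = 0`` whenever
    ``a / ||a||_2`` already does.  ``method="exact"`` solves the piecewise
    quadratic crossing in closed form; ``method="bisect"`` locates it by
    bisection to ``tol`` (the slower reference route, kept for
    cross-checking).
    """
    a = np.asarray(a, dtype=float)
    abs_a = np.abs(a)
    norm = np.sqrt(abs_a @ abs_a)
    if norm == 0 or not np.isfinite(norm):
        raise ValueError("cannot project an all-zero (or non-finite) vector")
    if abs_a.sum() / norm <= c + tol:
        return a / norm
    if method == "bisect":
        delta = _threshold_bisect(abs_a, c, tol)
    else:
        delta = _threshold_exact(abs_a, c)
    s = np.sign(a) * np.maximum(abs_a - delta, 0.0)
    n2 = np.sqrt(s @ s)
    if n2 == 0:  # only possible with ties at the max; fall back to hard max
        s = np.where(abs_a == abs_a.max(), a, 0.0)
        n2 = np.sqrt(s @ s)
    return s / n2


def _leading_right_singular_vector(M: np.ndarray) -> np.ndarray:
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    return vt[0]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def scca_fit(
    X: np.ndarray,
    Y: np.ndarray,
    penalties: SccaPenalties | None = None,
    K: int = 1,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> list[CanonicalMode]:
    """Fit ``K`` sparse canonical modes to row-aligned matrices ``X`` (n x p)
    and ``Y`` (n x q).

    Columns are expected to be standardized by the caller.  Each mode is a
    rank-1 penalized decomposition of the running cross-product matrix
    ``M = X'Y``: ``v`` is initialized from the leading right singular vector
    of ``M``, then ``u`` and ``v`` alternate through L1-constrained unit
    projections until the largest weight change drops below ``tol``.  After
    convergence, ``M`` is deflated by ``(u'Mv) u v'`` and the next mode is
    fit.  Modes are oriented so the largest-magnitude entry of ``v`` is
    positive (``u`` and ``v`` flip jointly, leaving the correlation intact).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"X and Y must be 2-d with aligned rows, got {X.shape} and {Y.shape}"
        )
    if K < 1:
        raise ValueError("K must be >= 1")
    penalties = penalties or SccaPenalties()
    n, p = X.shape
    q = Y.shape[1]
    cx = penalties.absolute_bound(penalties.c_x, p)
    cy = penalties.absolute_bound(penalties.c_y, q)

    M = X.T @ Y
    m0_norm = np.linalg.norm(M)
    modes: list[CanonicalMode] = []
    for k in range(1, min(K, p, q) + 1):
        if np.linalg.norm(M) <= 1e-10 * max(m0_norm, 1e-12):
            # deflated to numerical zero: no further structure to extract
            break
        v = _leading_right_singular_vector(M)
        u = np.zeros(p)
        objective = []
        converged = False
        it = 0
        Mv = M @ v
        for it in range(1, max_iter + 1):
            u_new = l1_constrained_unit_vector(Mv, cx)
            v_new = l1_constrained_unit_vector(M.T @ u_new, cy)
            Mv_new = M @ v_new
            objective.append(float(u_new @ Mv_new))
            delta = max(
                np.abs(u_new - u).max() if u.any() else np.inf,
                np.abs(v_new - v).max(),
            )
            u, v, Mv = u_new, v_new, Mv_new
            if delta < tol:
                converged = True
                break
        # drop numerical dust so reported supports are meaningful
        for w in (u, v):
            scale = np.abs(w).max()
            if scale > 0:
                w[np.abs(w) < 1e-12 * scale] = 0.0
        u /= np.linalg.norm(u) if np.linalg.norm(u) else 1.0
        v /= np.linalg.norm(v) if np.linalg.norm(v) else 1.0
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            u, v = -u, -v
        r = _pearson(X @ u, Y @ v)
        modes.append(
            CanonicalMode(
                index=k,
                u=u,
                v=v,
                canonical_r=r,
                n_nonzero_u=int(np.count_nonzero(u)),
                n_nonzero_v=int(np.count_nonzero(v)),
                converged=converged,
                iterations=it,
                objective_path=np.asarray(objective),
            )
        )
        M = M - (u @ M @ v) * np.outer(u, v)
    return modes


def canonical_variates(
    X: np.ndarray, Y: np.ndarray, mode: CanonicalMode
) -> CanonicalVariates:
    """Project subjects onto a fitted mode: ``xu = X u``, ``yv = Y v``."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != mode.u.shape[0] or Y.shape[1] != mode.v.shape[0]:
        raise ValueError(
            "dimension mismatch between data matrices and canonical vectors"
        )
    return CanonicalVariates(xu=X @ mode.u, yv=Y @ mode.v, index=mode.index)
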