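"""Hyperparameter and mode selection for the sparse CCA.

Two-part procedure: (1) the L1 penalty pair is chosen by grid search with
k-fold cross-validation, maximizing the mean out-of-sample rank-1 canonical
correlation; (2) fitted modes are tested by permutation — the rows of the
behavioural matrix are shuffled, the model refit, and every observed mode's
correlation is compared against the permutation distribution of the *first*
canonical correlation, which yields family-wise-error-controlled p-values
(the strongest null mode bounds all weaker ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .connectome import scale_columns_safe
from .scca import CanonicalMode, SccaPenalties, scca_fit

__all__ = [
    "PenaltyGrid",
    "PermutationResult",
    "cv_penalty_search",
    "permutation_mode_test",
]

_DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


@dataclass
class PenaltyGrid:
    """Candidate penalty fractions (Cartesian product) and the CV layout."""

    c_x_candidates: tuple[float, ...] = _DEFAULT_FRACTIONS
    c_y_candidates: tuple[float, ...] = _DEFAULT_FRACTIONS
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for cand in (*self.c_x_candidates, *self.c_y_candidates):
            if not 0.0 < cand <= 1.0:
                raise ValueError(f"penalty fraction {cand} outside (0, 1]")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class PermutationResult:
    """Permutation null distribution and per-mode FWE-corrected p-values."""

    n_perm: int
    null_first_r: np.ndarray
    observed_r: np.ndarray
    p_fwe: np.ndarray
    accepted: np.ndarray
    alpha: float = 0.05
    modes: list[CanonicalMode] = field(default_factory=list, repr=False)


def _heldout_correlation(
    X_train, Y_train, X_test, Y_test, penalties, tol, max_iter
) -> tuple[float, bool]:
    mu_x, sd_x = X_train.mean(0), X_train.std(0, ddof=1)
    mu_y, sd_y = Y_train.mean(0), Y_train.std(0, ddof=1)
    sd_x = np.where(sd_x == 0, 1.0, sd_x)
    sd_y = np.where(sd_y == 0, 1.0, sd_y)
    modes = scca_fit(
        (X_train - mu_x) / sd_x,
        (Y_train - mu_y) / sd_y,
        penalties,
        K=1,
        tol=tol,
        max_iter=max_iter,
    )
    if not modes:
        return 0.0, True
    u, v = modes[0].u, modes[0].v
    xu = ((X_test - mu_x) / sd_x) @ u
    yv = ((Y_test - mu_y) / sd_y) @ v
    if np.std(xu) == 0 or np.std(yv) == 0:
        return 0.0, True
    return float(np.corrcoef(xu, yv)[0, 1]), False


def cv_penalty_search(
    X: np.ndarray,
    Y: np.ndarray,
    grid: PenaltyGrid | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[SccaPenalties, pd.DataFrame]:
    """Choose the penalty pair maximizing the mean out-of-sample rank-1
    canonical correlation over k folds.

    Folds are subject-wise, shuffled once with ``grid.seed``.  Training
    folds are standardized and their column statistics are applied to the
    held-out fold before projecting.  A degenerate fold (zero-variance
    projection) contributes a correlation of 0 and increments the returned
    table's warning counter.  Ties prefer the weaker penalty (larger
    ``c_x + c_y``, then larger ``c_x``).  Returns the winning pair and the
    full audit table.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have aligned rows")
    grid = grid or PenaltyGrid()
    if grid.k_folds > X.shape[0]:
        raise ValueError("more folds than subjects")
    kf = KFold(n_splits=grid.k_folds, shuffle=True, random_state=grid.seed)
    splits = list(kf.split(X))
    rows = []
    for cx in grid.c_x_candidates:
        for cy in grid.c_y_candidates:
            penalties = SccaPenalties(cx, cy)
            fold_rs, n_degenerate = [], 0
            for train, test in splits:
                r, degenerate = _heldout_correlation(
                    X[train], Y[train], X[test], Y[test], penalties, tol, max_iter
                )
                fold_rs.append(r)
                n_degenerate += degenerate
            rows.append(
                {
                    "c_x": cx,
                    "c_y": cy,
                    "cv_score": float(np.mean(fold_rs)),
                    "n_degenerate_folds": n_degenerate,
                    **{f"fold_{i}_r": r for i, r in enumerate(fold_rs)},
                }
            )
    table = pd.DataFrame(rows)
    # tie-break: max cv_score, then larger c_x + c_y, then larger c_x
    top = table[np.isclose(table["cv_score"], table["cv_score"].max())]
    top = top.assign(_total=top["c_x"] + top["c_y"]).sort_values(
        ["_total", "c_x"], ascending=False
    )
    best_row = top.iloc[0]
    return SccaPenalties(float(best_row["c_x"]), float(best_row["c_y"])), table


def permutation_mode_test(
    X: np.ndarray,
    Y: np.ndarray,
    penalties: SccaPenalties,
    K: int = 2,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> PermutationResult:
    """Permutation FWE test of the fitted canonical modes.

    The observed modes are fit on the intact (standardized) data.  For each
    permutation the rows of ``Y`` are shuffled, the rank-1 model refit, and
    its first canonical correlation recorded.  Every observed mode is
    compared to this null distribution of *first* correlations:
    ``p_fwe(k) = (1 + #{null >= r_k}) / (1 + n_perm)``; modes with
    ``p_fwe < alpha`` are accepted.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives coarse p-value resolution", stacklevel=2
        )
    X = scale_columns_safe(np.asarray(X, dtype=float))
    Y = scale_columns_safe(np.asarray(Y, dtype=float))
    modes = scca_fit(X, Y, penalties, K=K, tol=tol, max_iter=max_iter)
    observed_r = np.array([m.canonical_r for m in modes])
    rng = np.random.default_rng(seed)
    null_first_r = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(Y.shape[0])
        null_modes = scca_fit(X, Y[perm], penalties, K=1, tol=tol, max_iter=max_iter)
        null_first_r[b] = null_modes[0].canonical_r if null_modes else 0.0
    exceed = (null_first_r[None, :] >= observed_r[:, None]).sum(axis=1)
    p_fwe = (1.0 + exceed) / (1.0 + n_perm)
    return PermutationResult(
        n_perm=n_perm,
        null_first_r=null_first_r,
        observed_r=observed_r,
        p_fwe=p_fwe,
        accepted=p_fwe < alpha,
        alpha=alpha,
        modes=modes,
    )
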