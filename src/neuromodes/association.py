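"""Linking neurocognitive mode scores to experience-sampling reports.

A subject's *mode score* is the mean of their two z-scored canonical
variates (connectivity and task side).  Mode scores, together with age, sex
and head-motion covariates, enter a multivariate linear model whose
responses are the 13 z-scored thought-probe item means.  Each predictor is
tested with a Type III hypothesis and Pillai's trace
``V = tr(H (H + E)^{-1})`` with the standard F approximation; the per-item
standardized coefficients form the predictor's *thought pattern*.  Stratum
re-fits (per task condition, per day) and Pearson similarity between
coefficient patterns quantify the stability of a mode's experience profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scca import CanonicalVariates

__all__ = [
    "ModeScores",
    "ThoughtPattern",
    "mode_score",
    "manova_pillai",
    "stratified_patterns",
    "pattern_similarity",
]


@dataclass
class ModeScores:
    """Per-subject neurocognitive score for one mode, plus its components."""

    index: int
    score: np.ndarray
    variate_fc: np.ndarray
    variate_task: np.ndarray


@dataclass
class ThoughtPattern:
    """One predictor's multivariate association with the thought items."""

    predictor: str
    coefficients: pd.Series
    pillai: float
    f_stat: float
    df_num: float
    df_den: float
    p_value: float
    eta_sq: float
    n: int


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - np.mean(x)) / sd


def mode_score(variates: CanonicalVariates) -> ModeScores:
    """Average the z-scored connectivity and task variates of one mode.

    (The sum differs from the mean only by a factor of 2, so every
    downstream correlation or regression statistic is identical either way.)
    """
    zx = _zscore(np.asarray(variates.xu, dtype=float))
    zy = _zscore(np.asarray(variates.yv, dtype=float))
    return ModeScores(
        index=variates.index,
        score=(zx + zy) / 2.0,
        variate_fc=zx,
        variate_task=zy,
    )


def manova_pillai(
    items: pd.DataFrame,
    predictors: pd.DataFrame,
    zscore_items: bool = True,
) -> list[ThoughtPattern]:
    """Type III multivariate regression of the thought items on the
    predictors, one Pillai's trace test per predictor.

    ``items`` is the n x 13 table of item means; ``predictors`` holds the
    mode scores and nuisance covariates (no intercept column — one is added).
    For predictor ``j`` the Type III hypothesis SSCP is
    ``H = b_j' (L G L')^{-1} b_j`` with ``G = (X'X)^{-1}`` and ``L`` the row
    selector of ``j``; ``E`` is the residual SSCP.  Pillai's trace
    ``V = tr(H (H + E)^{-1})`` is converted to an F statistic with the usual
    ``(s, m, n)`` parameters, and the multivariate effect size is
    ``eta_sq = V / s``.  Coefficients are standardized (per SD of the
    predictor, items z-scored).
    """
    Y = items.to_numpy(dtype=float)
    n, p_items = Y.shape
    if len(predictors) != n:
        raise ValueError("items and predictors must have aligned rows")
    names = list(predictors.columns)
    if n <= len(names) + p_items:
        raise ValueError(
            f"need n > n_predictors + n_items ({len(names)} + {p_items}), got n={n}"
        )
    if zscore_items:
        Y = np.column_stack([_zscore(Y[:, j]) for j in range(p_items)])
    Xp = predictors.to_numpy(dtype=float)
    design = np.column_stack([np.ones(n), Xp])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = [
            names[j - 1]
            for j in range(1, design.shape[1])
            if np.linalg.matrix_rank(design[:, : j + 1]) < j + 1
        ]
        raise ValueError(f"collinear predictor column(s): {bad}")
    G = np.linalg.inv(design.T @ design)
    B = G @ design.T @ Y
    resid = Y - design @ B
    E = resid.T @ resid
    df_error = n - rank

    patterns = []
    pred_sd = Xp.std(axis=0, ddof=1)
    for j, name in enumerate(names, start=1):
        b_j = B[j][None, :]  # 1 x p_items
        H = b_j.T @ b_j / G[j, j]
        HE = H + E
        try:
            V = float(np.trace(np.linalg.solve(HE, H)))
        except np.linalg.LinAlgError as err:
            raise ValueError("singular H + E matrix in Pillai's trace") from err
        df_h = 1
        s = min(df_h, p_items)
        m = (abs(df_h - p_items) - 1) / 2.0
        nn = (df_error - p_items - 1) / 2.0
        df_num = s * (2 * m + s + 1)
        df_den = s * (2 * nn + s + 1)
        if V >= s:
            f_stat = np.inf
            p_value = 0.0
        else:
            f_stat = (df_den / df_num) * (V / (s - V))
            p_value = float(stats.f.sf(f_stat, df_num, df_den))
        coef = pd.Series(B[j] * pred_sd[j - 1], index=items.columns, name=name)
        patterns.append(
            ThoughtPattern(
                predictor=name,
                coefficients=coef,
                pillai=V,
                f_stat=float(f_stat),
                df_num=float(df_num),
                df_den=float(df_den),
                p_value=p_value,
                eta_sq=V / s,
                n=n,
            )
        )
    return patterns


def stratified_patterns(
    mdes_strata: pd.DataFrame,
    predictors: pd.DataFrame,
    by: str,
    item_columns: list[str] | None = None,
    min_margin: int = 1,
) -> dict[object, list[ThoughtPattern]]:
    """Re-run the multivariate regression separately per stratum.

    ``mdes_strata`` is the long table (subject_id, condition, day, items);
    ``by`` is ``"condition"`` or ``"day"``.  Within a stratum, each present
    subject's item means are averaged over that stratum's rows, z-scored
    within stratum, and regressed on the same predictors (subset to present
    subjects).  Subjects missing a stratum are dropped from that stratum
    only.  A stratum too small for the model is an error naming it.
    """
    if by not in mdes_strata.columns:
        raise ValueError(f"no stratum column {by!r} in the table")
    if item_columns is None:
        item_columns = [
            c for c in mdes_strata.columns
            if c not in ("subject_id", "condition", "day")
        ]
    results: dict[object, list[ThoughtPattern]] = {}
    for level, chunk in mdes_strata.groupby(by, sort=True):
        means = chunk.groupby("subject_id", sort=False)[item_columns].mean()
        present = [s for s in predictors.index if s in means.index]
        needed = predictors.shape[1] + len(item_columns) + min_margin
        if len(present) < needed:
            raise ValueError(
                f"stratum {by}={level!r} has n={len(present)} < {needed} subjects"
            )
        results[level] = manova_pillai(
            means.loc[present], predictors.loc[present], zscore_items=True
        )
    return results


def pattern_similarity(a, b) -> tuple[float, float]:
    """Pearson correlation (and two-sided p) between two coefficient
    patterns over the same items."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("patterns must share a length of at least 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("cannot correlate a constant pattern")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
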