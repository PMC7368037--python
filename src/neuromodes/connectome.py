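"""Connectivity feature engineering.

Turns per-subject ROI time series into the feature matrix fed to the sparse
CCA: pairwise Pearson correlations, Fisher r-to-z, upper-triangle
vectorization (row-major, i < j), robust feature filtering by median absolute
deviation, and nuisance-covariate residualization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeries",
    "ConnectivityVector",
    "FeatureSelection",
    "upper_triangle_pairs",
    "compute_connectome",
    "mad_filter",
    "residualize_confounds",
    "standardize_columns",
]


@dataclass
class RoiTimeSeries:
    """One subject's ROI-averaged signal: a (timepoints x n_rois) matrix."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-d (timepoints x rois) array")
        t, r = self.values.shape
        if t < 3:
            raise ValueError(f"subject {self.subject_id}: need >= 3 timepoints, got {t}")
        if r < 2:
            raise ValueError(f"subject {self.subject_id}: need >= 2 ROIs, got {r}")
        if not np.isfinite(self.values).all():
            raise ValueError(f"subject {self.subject_id}: non-finite values in series")


@dataclass
class ConnectivityVector:
    """Fisher-z upper-triangle connectome with its ROI-pair index map."""

    subject_id: str
    z_values: np.ndarray
    pair_index: list[tuple[int, int]]


@dataclass
class FeatureSelection:
    """Result of MAD-based feature filtering."""

    selected_indices: np.ndarray
    mad_values: np.ndarray
    fraction: float


def upper_triangle_pairs(n_rois: int) -> list[tuple[int, int]]:
    """Row-major (i, j) ROI pairs with i < j; 0-based indices."""
    return [(i, j) for i in range(n_rois) for j in range(i + 1, n_rois)]


def compute_connectome(ts: RoiTimeSeries, clip: float = 1e-7) -> ConnectivityVector:
    """Fisher-z connectivity vector from one subject's ROI time series.

    Pearson correlations between every ROI pair are clipped to
    ``+/- (1 - clip)`` before ``atanh`` so perfectly correlated pairs stay
    finite; the upper triangle is flattened row-major.  A zero-variance ROI
    column is an error (its correlations are undefined).
    """
    values = ts.values
    sds = values.std(axis=0)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        raise ValueError(
            f"subject {ts.subject_id}: zero-variance ROI column(s) {dead.tolist()}"
        )
    r = np.corrcoef(values, rowvar=False)
    n_rois = values.shape[1]
    iu = np.triu_indices(n_rois, k=1)
    r_vec = np.clip(r[iu], -(1.0 - clip), 1.0 - clip)
    return ConnectivityVector(
        subject_id=ts.subject_id,
        z_values=np.arctanh(r_vec),
        pair_index=upper_triangle_pairs(n_rois),
    )


def mad_filter(X: np.ndarray, fraction: float = 0.05) -> FeatureSelection:
    """Retain the ``floor(fraction * p)`` columns with the largest median
    absolute deviation.

    Ties break toward the lower column index, and the returned indices keep
    the original column order.  Only across-subject variability can carry
    individual differences, so low-MAD (near-constant) connections are
    dropped before model fitting.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-d matrix with at least one column")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    p = X.shape[1]
    n_keep = int(np.floor(fraction * p))
    if n_keep == 0:
        raise ValueError(
            f"fraction {fraction} of {p} columns keeps zero features"
        )
    mad = np.median(np.abs(X - np.median(X, axis=0)), axis=0)
    # stable sort on negated MADs -> ties resolve to the lower column index
    ranked = np.argsort(-mad, kind="stable")[:n_keep]
    return FeatureSelection(
        selected_indices=np.sort(ranked),
        mad_values=mad,
        fraction=fraction,
    )


def residualize_confounds(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Replace each column of ``X`` by its least-squares residual on
    ``[intercept, C]``.

    Output columns are mean-zero and orthogonal to every covariate column.
    Rank-deficient covariates are rejected with the offending columns named.
    """
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if X.shape[0] != C.shape[0]:
        raise ValueError("X and C must have aligned rows")
    design = np.column_stack([np.ones(C.shape[0]), C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name covariate columns that add no rank beyond their predecessors
        bad = [
            j
            for j in range(C.shape[1])
            if np.linalg.matrix_rank(design[:, : j + 2]) < j + 2
        ]
        raise ValueError(f"covariate matrix is rank-deficient; collinear columns {bad}")
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    return X - design @ beta


def standardize_columns(X, ddof: int = 1, allow_constant: bool = False):
    """Scale every column to mean 0 and sample standard deviation 1
    (``n - 1`` denominator).

    Accepts an array or DataFrame and returns the same kind.  Zero-variance
    columns are an error, named in the message, unless ``allow_constant`` is
    set, in which case they are mapped to all-zero columns.
    """
    is_frame = isinstance(X, pd.DataFrame)
    values = np.asarray(X, dtype=float)
    if values.ndim != 2:
        raise ValueError("X must be 2-d")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    dead = np.flatnonzero(sd == 0)
    if dead.size and not allow_constant:
        names = (
            [X.columns[j] for j in dead] if is_frame else dead.tolist()
        )
        raise ValueError(f"zero-variance column(s): {names}")
    sd = np.where(sd == 0, 1.0, sd)
    out = (values - mean) / sd
    if is_frame:
        return pd.DataFrame(out, index=X.index, columns=X.columns)
    return out


def scale_columns_safe(X: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Like :func:`standardize_columns` but maps zero-variance columns to all
    zeros instead of raising.  Used inside cross-validation folds and on
    degenerate (noise-free) feature matrices where constant columns carry no
    information by construction."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (X - mean) / sd_safe
    out[:, sd == 0] = 0.0
    return out
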