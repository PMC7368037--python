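"""Synthetic cohorts with planted sparse canonical structure.

The generator emulates a resting-state + cognitive-battery + experience-
sampling study: per-subject functional connectomes (Fisher-z upper-triangle
vectors over 100 ROIs by default), 13 cognitive task scores, 13 thought-probe
item means collected under two task conditions (0-back / 1-back) over three
days, and age / sex / head-motion covariates.

The planted statistical structure is a sparse low-rank cross-covariance:
latent subject scores ``z_k ~ N(0, 1)`` (independent across modes) load onto
sparse unit vectors ``u_k`` (connectivity space) and ``v_k`` (task space),

    X = sum_k c_k z_k u_k' + noise,     Y = sum_k c_k z_k v_k' + noise,

with the signal scale ``c_k = noise_sd * sqrt(rho_k / (1 - rho_k))`` chosen
so the population canonical correlation of ``(X u_k, Y v_k)`` equals the
configured ``rho_k``.  Thought-probe items couple linearly to the latent
scores through a (K x 13) loading matrix, and age / sex / motion add linear
nuisance effects to every feature block.  Mode supports are sampled disjoint
so planted modes do not interfere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cognition
from .connectome import upper_triangle_pairs

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_null_cohort",
    "MDES_ITEMS",
    "CONDITIONS",
    "DAYS",
]

MDES_ITEMS: tuple[str, ...] = (
    "task", "future", "past", "self", "people", "emotion", "images",
    "words", "vivid", "detailed", "habit", "evolving", "deliberate",
)
CONDITIONS: tuple[str, ...] = ("0-back", "1-back")
DAYS: tuple[int, ...] = (1, 2, 3)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated study: 178 subjects, 100-ROI connectomes
    (4,950 Fisher-z features), 177 retained volumes, 13 task scores, 13
    experience-sampling items, and two planted modes with canonical
    correlations 0.57 and 0.59.
    """

    n_subjects: int = 178
    n_rois: int = 100
    n_timepoints: int = 177
    n_tasks: int = 13
    n_mdes: int = 13
    n_modes: int = 2
    mode_strengths: tuple[float, ...] = (0.57, 0.59)
    u_sparsity: float = 0.025
    v_sparsity: float = 0.4
    weight_values: str = "normal"  # or "equal": +/- 1/sqrt(m) support weights
    mdes_loadings: np.ndarray | None = None
    mdes_coupling_sd: float = 0.14
    mdes_trait_sd: float = 0.65  # stable per-subject item style, shared across strata
    confound_effect_sd: float = 0.1
    noise_sd: float = 1.0
    mdes_noise_sd: float = 1.0
    # connectivity noise dispersion: a small pool of connections (holding the
    # planted supports) varies at full noise_sd, the rest at a reduced sd --
    # the across-subject variability profile the MAD filter exploits
    dispersion: str = "heterogeneous"  # or "homogeneous"
    high_dispersion_fraction: float = 0.05
    low_dispersion_range: tuple[float, float] = (0.2, 0.8)
    day_participation: tuple[float, ...] = (1.0, 0.97, 0.85)
    mdes_item_corr: np.ndarray | None = None
    seed: int = 0
    generation_mode: str = "direct_features"  # or "timeseries"
    n_features: int | None = None  # override R(R-1)/2 for low-dim experiments

    def __post_init__(self) -> None:
        if self.n_modes < 0:
            raise ValueError("n_modes must be >= 0")
        rhos = tuple(self.mode_strengths)[: self.n_modes]
        if len(rhos) < self.n_modes:
            raise ValueError("need one mode strength per planted mode")
        if any(not 0.0 < r < 1.0 for r in rhos):
            raise ValueError("all mode strengths must lie in (0, 1)")
        for name, frac in (("u_sparsity", self.u_sparsity), ("v_sparsity", self.v_sparsity)):
            if not 0.0 < frac <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {frac}")
        if self.generation_mode not in ("direct_features", "timeseries"):
            raise ValueError(f"unknown generation_mode {self.generation_mode!r}")
        if self.weight_values not in ("normal", "equal"):
            raise ValueError(f"unknown weight_values {self.weight_values!r}")
        if self.noise_sd < 0 or self.mdes_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.dispersion not in ("heterogeneous", "homogeneous"):
            raise ValueError(f"unknown dispersion {self.dispersion!r}")

    @property
    def n_connectivity(self) -> int:
        if self.n_features is not None:
            return self.n_features
        return self.n_rois * (self.n_rois - 1) // 2


@dataclass
class GroundTruth:
    """The planted structure, for recovery tests."""

    u_true: list[np.ndarray]
    v_true: list[np.ndarray]
    z_true: np.ndarray
    mdes_loadings: np.ndarray
    confound_betas: dict[str, np.ndarray] = field(default_factory=dict)
    y_raw: np.ndarray | None = None  # planted task block before standardization


@dataclass
class SyntheticCohort:
    """One generated cohort plus its ground truth."""

    config: SimulationConfig
    subject_ids: list[str]
    connectivity: pd.DataFrame  # subjects x p Fisher-z features
    pair_index: list[tuple[int, int]]
    raw_task_table: pd.DataFrame
    task_scores: pd.DataFrame  # standardized planted 13 scores (convenience)
    mdes_table: pd.DataFrame  # overall item means, one row per subject
    mdes_strata: pd.DataFrame  # long: subject_id, condition, day, 13 items
    covariates: pd.DataFrame  # age, sex, mean_fd
    ground_truth: GroundTruth
    roi_timeseries: dict[str, np.ndarray] | None = None

    def write(self, outdir) -> dict:
        """Write every table as TSV plus a ground-truth sidecar and manifest;
        returns the manifest dict."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "connectivity.tsv": self.connectivity,
            "raw_task_measures.tsv": self.raw_task_table,
            "task_scores.tsv": self.task_scores,
            "mdes_overall.tsv": self.mdes_table,
            "mdes_strata.tsv": self.mdes_strata,
            "covariates.tsv": self.covariates,
        }
        for name, df in tables.items():
            path = outdir / name
            df.to_csv(path, sep="\t", index=name != "mdes_strata.tsv")
            paths[name] = str(path)
        gt = {
            "u_true": [u.tolist() for u in self.ground_truth.u_true],
            "v_true": [v.tolist() for v in self.ground_truth.v_true],
            "z_true": self.ground_truth.z_true.tolist(),
            "mdes_loadings": self.ground_truth.mdes_loadings.tolist(),
        }
        gt_path = outdir / "ground_truth.json"
        gt_path.write_text(json.dumps(gt))
        paths["ground_truth.json"] = str(gt_path)
        manifest = {
            "seed": self.config.seed,
            "config": _config_dict(self.config),
            "paths": paths,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    for key, value in d.items():
        if isinstance(value, np.ndarray):
            d[key] = value.tolist()
    return d


def _sparse_unit_vectors(
    rng: np.random.Generator,
    dim: int,
    k: int,
    fraction: float,
    style: str,
    perm: np.ndarray | None = None,
) -> list[np.ndarray]:
    """K sparse unit vectors with disjoint supports and exact nonzero counts."""
    m = max(1, int(np.floor(fraction * dim)))
    if k * m > dim:
        raise ValueError(
            f"cannot plant {k} disjoint supports of size {m} in {dim} features"
        )
    if perm is None:
        perm = rng.permutation(dim)
    vectors = []
    for i in range(k):
        support = perm[i * m : (i + 1) * m]
        w = np.zeros(dim)
        if style == "equal":
            w[support] = rng.choice([-1.0, 1.0], size=m)
        else:
            vals = rng.standard_normal(m)
            vals[vals == 0] = 1.0
            w[support] = vals
        vectors.append(w / np.linalg.norm(w))
    return vectors


def _covariates(rng: np.random.Generator, n: int, ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.uniform(18, 31, n),
            "sex": rng.binomial(1, 0.64, n).astype(float),
            "mean_fd": rng.lognormal(np.log(0.15), 0.4, n),
        },
        index=pd.Index(ids, name="subject_id"),
    )


def _standardized(values: np.ndarray) -> np.ndarray:
    # constant columns (possible in noise-free configurations) map to zero
    sd = values.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (values - values.mean(axis=0)) / sd


def _nearest_correlation(R: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Nearest positive-definite correlation matrix by eigenvalue clipping and
    diagonal renormalization."""
    R = 0.5 * (R + R.T)
    w, V = np.linalg.eigh(R)
    w = np.maximum(w, eig_floor)
    R_pd = (V * w) @ V.T
    d = np.sqrt(np.diag(R_pd))
    R_pd = R_pd / np.outer(d, d)
    np.fill_diagonal(R_pd, 1.0)
    return R_pd


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one cohort under ``config``.  Identical config + seed yields
    an identical cohort."""
    rng = np.random.default_rng(config.seed)
    n, K = config.n_subjects, config.n_modes
    p, q = config.n_connectivity, config.n_tasks
    ids = [f"sub-{i:04d}" for i in range(1, n + 1)]

    rhos = np.asarray(config.mode_strengths[:K], dtype=float)
    feature_perm = rng.permutation(p)
    u_true = _sparse_unit_vectors(
        rng, p, K, config.u_sparsity, config.weight_values, perm=feature_perm
    )
    v_true = _sparse_unit_vectors(rng, q, K, config.v_sparsity, config.weight_values)
    Z = rng.standard_normal((n, K))
    if config.noise_sd > 0:
        scales = config.noise_sd * np.sqrt(rhos / (1.0 - rhos))
    else:
        scales = np.ones(K)

    # per-feature connectivity noise sd: the planted supports sit inside the
    # small high-dispersion pool so that individual-difference signal lives in
    # the most variable connections
    sigma_x = np.full(p, config.noise_sd)
    if config.dispersion == "heterogeneous" and config.noise_sd > 0:
        n_support = sum(np.count_nonzero(u) for u in u_true)
        n_high = max(int(np.ceil(config.high_dispersion_fraction * p)), n_support)
        low = feature_perm[n_high:]
        lo, hi = config.low_dispersion_range
        sigma_x[low] = config.noise_sd * rng.uniform(lo, hi, low.size)

    # connectivity block: baseline pattern + planted signal + feature noise
    baseline = rng.normal(0.25, 0.15, p)
    X = np.tile(baseline, (n, 1))
    Y = np.zeros((n, q))
    for k in range(K):
        X += scales[k] * np.outer(Z[:, k], u_true[k])
        Y += scales[k] * np.outer(Z[:, k], v_true[k])
    if config.noise_sd > 0 and config.generation_mode == "direct_features":
        X += sigma_x * rng.standard_normal((n, p))
    if config.noise_sd > 0:
        Y += config.noise_sd * rng.standard_normal((n, q))

    covariates = _covariates(rng, n, ids)
    C_std = _standardized(covariates.to_numpy())
    betas = {}
    if config.confound_effect_sd > 0:
        for name, width in (("connectivity", p), ("tasks", q), ("mdes", config.n_mdes)):
            betas[name] = config.confound_effect_sd * rng.standard_normal((3, width))
        X += C_std @ betas["connectivity"]
        Y += C_std @ betas["tasks"]

    # thought-report block: items couple to the latent scores
    if config.mdes_loadings is not None:
        L = np.asarray(config.mdes_loadings, dtype=float)
        if L.shape != (K, config.n_mdes):
            raise ValueError(
                f"mdes_loadings must be ({K}, {config.n_mdes}), got {L.shape}"
            )
    else:
        L = config.mdes_coupling_sd * rng.standard_normal((K, config.n_mdes))
    mdes_mean = Z @ L
    if "mdes" in betas:
        mdes_mean = mdes_mean + C_std @ betas["mdes"]
    if config.mdes_trait_sd > 0:
        # stable response styles: per-subject item deviations that persist
        # across conditions and days (independent of the planted modes)
        mdes_mean = mdes_mean + config.mdes_trait_sd * rng.standard_normal(
            (n, config.n_mdes)
        )

    noise_transform = None
    if config.mdes_item_corr is not None:
        R_items = _nearest_correlation(np.asarray(config.mdes_item_corr, dtype=float))
        noise_transform = np.linalg.cholesky(R_items)

    strata_frames = []
    present_by_day = {
        day: rng.random(n) < prob
        for day, prob in zip(DAYS, config.day_participation)
    }
    for day in DAYS:
        mask = present_by_day[day]
        for condition in CONDITIONS:
            eps = rng.standard_normal((n, config.n_mdes))
            if noise_transform is not None:
                eps = eps @ noise_transform.T
            items = mdes_mean + config.mdes_noise_sd * eps
            frame = pd.DataFrame(items[mask], columns=list(MDES_ITEMS))
            frame.insert(0, "day", day)
            frame.insert(0, "condition", condition)
            frame.insert(0, "subject_id", np.asarray(ids)[mask])
            strata_frames.append(frame)
    mdes_strata = pd.concat(strata_frames, ignore_index=True)
    mdes_overall = (
        mdes_strata.drop(columns=["condition", "day"])
        .groupby("subject_id", sort=False)
        .mean()
        .loc[ids]
    )

    # task block rendered back into raw measures invertible by the schedule
    task_scores = pd.DataFrame(
        _standardized(Y), columns=list(cognition.SCORE_NAMES),
        index=pd.Index(ids, name="subject_id"),
    )
    raw_task = cognition.synthesize_raw_measures(task_scores, rng)

    pair_index = (
        upper_triangle_pairs(config.n_rois)
        if config.n_features is None
        else [(0, j + 1) for j in range(p)]
    )
    feature_names = [f"roi{i:03d}-roi{j:03d}" for i, j in pair_index]
    connectivity = pd.DataFrame(
        X, columns=feature_names, index=pd.Index(ids, name="subject_id")
    )

    roi_timeseries = None
    if config.generation_mode == "timeseries":
        if config.n_features is not None:
            raise ValueError("timeseries mode requires a full ROI grid")
        roi_timeseries = {}
        iu = np.triu_indices(config.n_rois, k=1)
        for s, sid in enumerate(ids):
            R = np.eye(config.n_rois)
            R[iu] = np.tanh(X[s])
            R.T[iu] = np.tanh(X[s])
            R_pd = _nearest_correlation(R)
            if np.abs(R_pd - R)[iu].max() > 0.5:
                raise ValueError(
                    f"subject {sid}: planted correlation matrix could not be "
                    "repaired to positive definite within tolerance"
                )
            chol = np.linalg.cholesky(R_pd)
            series = rng.standard_normal((config.n_timepoints, config.n_rois)) @ chol.T
            roi_timeseries[sid] = series

    ground_truth = GroundTruth(
        u_true=u_true, v_true=v_true, z_true=Z, mdes_loadings=L,
        confound_betas=betas, y_raw=Y,
    )
    return SyntheticCohort(
        config=config,
        subject_ids=ids,
        connectivity=connectivity,
        pair_index=pair_index,
        raw_task_table=raw_task,
        task_scores=task_scores,
        mdes_table=mdes_overall,
        mdes_strata=mdes_strata,
        covariates=covariates,
        ground_truth=ground_truth,
        roi_timeseries=roi_timeseries,
    )


def generate_null_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a cohort with the same marginal structure but no planted
    association between connectivity and tasks (and none with the thought
    reports): the null model for error-control experiments."""
    null_config = SimulationConfig(**{**_config_dict(config), "n_modes": 0,
                                      "mode_strengths": (), "mdes_loadings": None})
    cohort = generate_cohort(null_config)
    return cohort
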