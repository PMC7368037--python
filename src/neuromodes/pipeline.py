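"""End-to-end orchestration of the brain-behavior association analysis.

Stages: connectivity feature engineering -> cognitive score assembly ->
MAD feature filtering -> confound residualization -> cross-validated penalty
search -> sparse CCA fit -> permutation mode test -> mode scoring ->
multivariate regression on the thought reports -> stratified stability
analysis.  Every intermediate is written as a tab-separated table and the
run manifest records the config, derived per-stage seeds, and output paths,
so any stage can be re-run in isolation and identical configs reproduce
identical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, cognition, connectome, selection, simulate
from .scca import SccaPenalties, scca_fit, canonical_variates

__all__ = ["PipelineConfig", "run_pipeline", "derive_stage_seeds"]

_STAGE_NAMES = ("generator", "cv_shuffle", "permutation")


def derive_stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministically derive one sub-seed (< 2^31) per stochastic stage."""
    state = np.random.SeedSequence(master_seed).generate_state(len(_STAGE_NAMES))
    return {name: int(s % (2**31)) for name, s in zip(_STAGE_NAMES, state)}


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    output_dir: str = "neuromodes_run"
    seed: int = 0
    # input tables (None -> generate a synthetic cohort instead)
    connectivity_path: str | None = None
    raw_task_path: str | None = None
    mdes_path: str | None = None
    covariates_path: str | None = None
    simulation: dict = field(default_factory=dict)
    # feature options
    mad_fraction: float = 0.05
    clip: float = 1e-7
    filter_before_residualize: bool = True
    # SCCA / selection options
    c_x_candidates: tuple[float, ...] = selection._DEFAULT_FRACTIONS
    c_y_candidates: tuple[float, ...] = selection._DEFAULT_FRACTIONS
    k_folds: int = 5
    n_modes: int = 2
    n_perm: int = 1000
    alpha: float = 0.05
    tol: float = 1e-6
    max_iter: int = 200
    skip_cv: bool = False
    fixed_penalties: tuple[float, float] | None = None

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0.0 < self.mad_fraction <= 1.0:
            raise ValueError("mad_fraction must be in (0, 1]")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if self.skip_cv and self.fixed_penalties is None:
            raise ValueError("skip_cv requires fixed_penalties")


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> str:
    df.to_csv(path, sep="\t", index=index)
    return str(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to
    ``output_dir/manifest.json``)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.seed)
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages": [],
        "paths": {},
        "warnings": [],
    }
    timings: dict[str, float] = {}

    def stage(name):
        manifest["stages"].append(name)
        timings[name] = time.time()
        return name

    # ---- inputs -----------------------------------------------------------
    stage("load_inputs")
    if config.connectivity_path is None:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", seeds["generator"])
        cohort = simulate.generate_cohort(simulate.SimulationConfig(**sim_kwargs))
        features = cohort.connectivity
        raw_task = cohort.raw_task_table
        mdes_overall = cohort.mdes_table
        mdes_strata = cohort.mdes_strata
        covariates = cohort.covariates
        manifest["paths"]["cohort"] = cohort.write(outdir / "cohort")["paths"]
    else:
        features = pd.read_csv(config.connectivity_path, sep="\t", index_col=0)
        raw_task = pd.read_csv(config.raw_task_path, sep="\t", index_col=0)
        mdes = pd.read_csv(config.mdes_path, sep="\t")
        covariates = pd.read_csv(config.covariates_path, sep="\t", index_col=0)
        if {"condition", "day"}.issubset(mdes.columns):
            mdes_strata = mdes
            items = [c for c in mdes.columns if c not in ("subject_id", "condition", "day")]
            mdes_overall = mdes.groupby("subject_id", sort=False)[items].mean()
            mdes_overall = mdes_overall.loc[features.index]
        else:
            mdes_overall = mdes.set_index("subject_id").loc[features.index]
            mdes_strata = None
        cohort = None

    subject_ids = list(features.index)
    item_columns = list(mdes_overall.columns)

    # ---- cognitive scores -------------------------------------------------
    stage("assemble_scores")
    scores = cognition.assemble_scores(raw_task, allow_constant=True)
    manifest["paths"]["task_scores"] = _write(scores, outdir / "task_scores.tsv")

    # ---- connectivity features: filter + residualize ----------------------
    stage("feature_engineering")
    X_full = features.to_numpy(dtype=float)
    C = covariates.loc[subject_ids, ["age", "sex", "mean_fd"]].to_numpy(dtype=float)
    if config.filter_before_residualize:
        fs = connectome.mad_filter(X_full, config.mad_fraction)
        X = connectome.residualize_confounds(X_full[:, fs.selected_indices], C)
    else:
        X_resid = connectome.residualize_confounds(X_full, C)
        fs = connectome.mad_filter(X_resid, config.mad_fraction)
        X = X_resid[:, fs.selected_indices]
    selected_names = [features.columns[j] for j in fs.selected_indices]
    manifest["paths"]["selected_features"] = _write(
        pd.DataFrame(
            {"feature": selected_names,
             "mad": fs.mad_values[fs.selected_indices]}
        ),
        outdir / "selected_features.tsv",
        index=False,
    )
    Y = connectome.residualize_confounds(
        scores.loc[subject_ids].to_numpy(dtype=float), C
    )
    X = connectome.scale_columns_safe(X)
    Y = connectome.scale_columns_safe(Y)

    # ---- penalty selection ------------------------------------------------
    stage("penalty_selection")
    if config.skip_cv:
        penalties = SccaPenalties(*config.fixed_penalties)
        cv_table = None
    else:
        grid = selection.PenaltyGrid(
            c_x_candidates=tuple(config.c_x_candidates),
            c_y_candidates=tuple(config.c_y_candidates),
            k_folds=config.k_folds,
            seed=seeds["cv_shuffle"],
        )
        penalties, cv_table = selection.cv_penalty_search(
            X, Y, grid, tol=config.tol, max_iter=config.max_iter
        )
        manifest["paths"]["cv_grid"] = _write(
            cv_table, outdir / "cv_grid.tsv", index=False
        )
    manifest["penalties"] = {"c_x": penalties.c_x, "c_y": penalties.c_y}

    # ---- fit + permutation test -------------------------------------------
    stage("permutation_mode_test")
    perm = selection.permutation_mode_test(
        X, Y, penalties,
        K=config.n_modes,
        n_perm=config.n_perm,
        seed=seeds["permutation"],
        alpha=config.alpha,
        tol=config.tol,
        max_iter=config.max_iter,
    )
    manifest["paths"]["permutation_null"] = _write(
        pd.DataFrame({"null_first_r": perm.null_first_r}),
        outdir / "permutation_null.tsv",
        index=False,
    )
    mode_table = pd.DataFrame(
        {
            "mode": [m.index for m in perm.modes],
            "canonical_r": perm.observed_r,
            "p_fwe": perm.p_fwe,
            "accepted": perm.accepted,
            "n_nonzero_u": [m.n_nonzero_u for m in perm.modes],
            "n_nonzero_v": [m.n_nonzero_v for m in perm.modes],
        }
    )
    manifest["paths"]["modes"] = _write(mode_table, outdir / "modes.tsv", index=False)
    manifest["paths"]["loadings_u"] = _write(
        pd.DataFrame(
            {f"mode_{m.index}": m.u for m in perm.modes}, index=selected_names
        ),
        outdir / "loadings_connectivity.tsv",
    )
    manifest["paths"]["loadings_v"] = _write(
        pd.DataFrame(
            {f"mode_{m.index}": m.v for m in perm.modes}, index=list(scores.columns)
        ),
        outdir / "loadings_tasks.tsv",
    )
    manifest["accepted_modes"] = [int(m.index) for m, a in zip(perm.modes, perm.accepted) if a]
    manifest["mode_p_fwe"] = [float(p) for p in perm.p_fwe]

    # ---- mode scores + association ---------------------------------------
    stage("association")
    analysed = perm.modes if not any(perm.accepted) else [
        m for m, a in zip(perm.modes, perm.accepted) if a
    ]
    if not any(perm.accepted):
        manifest["warnings"].append(
            "no mode passed the permutation test; association run on all fitted modes"
        )
    score_frame = pd.DataFrame(index=pd.Index(subject_ids, name="subject_id"))
    for m in analysed:
        ms = association.mode_score(canonical_variates(X, Y, m))
        score_frame[f"mode_{m.index}"] = ms.score
    manifest["paths"]["mode_scores"] = _write(
        score_frame, outdir / "mode_scores.tsv"
    )
    predictors = score_frame.join(covariates.loc[subject_ids, ["age", "sex", "mean_fd"]])
    patterns = association.manova_pillai(
        mdes_overall.loc[subject_ids], predictors, zscore_items=True
    )
    pattern_table = _patterns_frame(patterns)
    manifest["paths"]["thought_patterns"] = _write(
        pattern_table, outdir / "thought_patterns.tsv", index=False
    )
    manifest["association"] = {
        tp.predictor: {"pillai": tp.pillai, "F": tp.f_stat, "p": tp.p_value,
                       "eta_sq": tp.eta_sq}
        for tp in patterns
    }

    # ---- stability across strata ------------------------------------------
    if mdes_strata is not None:
        stage("stability")
        similarity_rows = []
        for by in ("condition", "day"):
            strata = association.stratified_patterns(
                mdes_strata, predictors, by=by, item_columns=item_columns
            )
            for level, pats in strata.items():
                manifest["paths"][f"patterns_{by}_{level}"] = _write(
                    _patterns_frame(pats),
                    outdir / f"thought_patterns_{by}_{level}.tsv",
                    index=False,
                )
            for mode_name in score_frame.columns:
                overall = next(
                    tp for tp in patterns if tp.predictor == mode_name
                ).coefficients
                for level, pats in strata.items():
                    coef = next(
                        tp for tp in pats if tp.predictor == mode_name
                    ).coefficients
                    r, p = association.pattern_similarity(overall, coef)
                    similarity_rows.append(
                        {"predictor": mode_name, "stratum": f"{by}={level}",
                         "r_with_overall": r, "p": p}
                    )
        manifest["paths"]["pattern_similarity"] = _write(
            pd.DataFrame(similarity_rows),
            outdir / "pattern_similarity.tsv",
            index=False,
        )

    now = time.time()
    manifest["timings"] = {
        name: round(
            (list(timings.values()) + [now])[i + 1] - t, 3
        )
        for i, (name, t) in enumerate(timings.items())
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _patterns_frame(patterns) -> pd.DataFrame:
    rows = []
    for tp in patterns:
        row = {
            "predictor": tp.predictor,
            "pillai": tp.pillai,
            "F": tp.f_stat,
            "df_num": tp.df_num,
            "df_den": tp.df_den,
            "p_value": tp.p_value,
            "eta_sq": tp.eta_sq,
            "n": tp.n,
        }
        row.update({f"coef_{item}": c for item, c in tp.coefficients.items()})
        rows.append(row)
    return pd.DataFrame(rows)
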