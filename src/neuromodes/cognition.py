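"""Derivation of the 13 cognitive scores from raw task measures.

The battery spans executive control (digit span, task switching), generation
(verbal fluency, unusual uses), semantic memory (picture-word matching,
feature matching, picture naming), episodic memory (paired associates, four
mountains) and fluid intelligence (matrix reasoning).  Raw measures are
summarized into 13 named scores through a small declarative *schedule* built
from five operators:

``mean``        arithmetic mean of the named measures
``contrast``    difference ``a - b`` of two measures or intermediate scores
``efficiency``  ``-(reaction_time / accuracy)``, sign-flipped so higher is
                better
``accuracy``    pass a measure through unchanged
``negate``      sign-flip a cost measure (e.g. switch cost -> "flexibility")

Entries whose name starts with ``_`` are intermediates and are not emitted.
After assembly every emitted column is standardized (mean 0, sample sd 1)
across the cohort.  The default schedule is one consistent reading of the
battery; alternative groupings are expressible by passing a different
schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import standardize_columns

__all__ = [
    "ScoreDef",
    "DEFAULT_SCHEDULE",
    "SCORE_NAMES",
    "efficiency_score",
    "contrast_score",
    "assemble_scores",
    "synthesize_raw_measures",
    "read_raw_table",
]


@dataclass(frozen=True)
class ScoreDef:
    """One entry of a score schedule: ``name = op(*args)``."""

    name: str
    op: str
    args: tuple[str, ...]

    _OPS = ("mean", "contrast", "efficiency", "accuracy", "negate")

    def __post_init__(self) -> None:
        if self.op not in self._OPS:
            raise ValueError(f"unknown operator {self.op!r}; allowed: {self._OPS}")


def efficiency_score(rt: float, acc: float):
    """Reversed efficiency: ``-(rt / acc)``.  Higher is better."""
    rt = np.asarray(rt, dtype=float)
    acc = np.asarray(acc, dtype=float)
    if np.any(acc <= 0):
        raise ValueError("accuracy must be > 0 for an efficiency score")
    if np.any(rt <= 0):
        raise ValueError("reaction time must be > 0")
    out = -(rt / acc)
    return float(out) if out.ndim == 0 else out


def contrast_score(a, b):
    """Condition contrast ``a - b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("contrast inputs must be finite")
    out = a - b
    return float(out) if out.ndim == 0 else out


DEFAULT_SCHEDULE: tuple[ScoreDef, ...] = (
    # intermediates: efficiency per picture-word matching condition
    ScoreDef("_eff_strong", "efficiency", ("reaction_time_strong", "accuracy_strong")),
    ScoreDef("_eff_weak", "efficiency", ("reaction_time_weak", "accuracy_weak")),
    ScoreDef("_eff_picture", "efficiency", ("reaction_time_picture", "accuracy_picture")),
    ScoreDef("_eff_word", "efficiency", ("reaction_time_word", "accuracy_word")),
    ScoreDef("_eff_specific", "efficiency", ("reaction_time_specific", "accuracy_specific")),
    ScoreDef("_eff_general", "efficiency", ("reaction_time_general", "accuracy_general")),
    # the 13 emitted scores
    ScoreDef("digit_span", "mean", ("digit_span_forward", "digit_span_backward")),
    ScoreDef("verbal_fluency", "contrast", ("fluency_category", "fluency_letter")),
    ScoreDef("picture_naming", "accuracy", ("naming_accuracy",)),
    ScoreDef("four_mountains", "accuracy", ("four_mountains_accuracy",)),
    ScoreDef("rapm", "accuracy", ("rapm_accuracy",)),
    ScoreDef("flexibility", "negate", ("switch_cost",)),
    ScoreDef("inhibition", "negate", ("inhibition_cost",)),
    ScoreDef(
        "feature_matching",
        "efficiency",
        ("reaction_time_feature_matching", "accuracy_feature_matching"),
    ),
    ScoreDef(
        "paired_associate",
        "efficiency",
        ("reaction_time_paired_associate", "accuracy_paired_associate"),
    ),
    ScoreDef("strength", "contrast", ("_eff_strong", "_eff_weak")),
    ScoreDef("modality", "contrast", ("_eff_picture", "_eff_word")),
    ScoreDef("specificity", "contrast", ("_eff_specific", "_eff_general")),
    ScoreDef("unusual_uses", "accuracy", ("unusual_uses_score",)),
)

SCORE_NAMES: tuple[str, ...] = tuple(
    d.name for d in DEFAULT_SCHEDULE if not d.name.startswith("_")
)


def _resolve(name: str, raw: pd.DataFrame, computed: dict, score_name: str) -> np.ndarray:
    if name in computed:
        return computed[name]
    if name in raw.columns:
        return raw[name].to_numpy(dtype=float)
    raise KeyError(f"score {score_name!r} needs measure {name!r}, absent from table")


def assemble_scores(
    raw: pd.DataFrame,
    schedule: tuple[ScoreDef, ...] = DEFAULT_SCHEDULE,
    standardize: bool = True,
    allow_constant: bool = False,
) -> pd.DataFrame:
    """Apply a score schedule to a wide raw-measures table (one row per
    subject) and return the standardized score table."""
    computed: dict[str, np.ndarray] = {}
    emitted: list[str] = []
    for d in schedule:
        args = [_resolve(a, raw, computed, d.name) for a in d.args]
        if d.op == "mean":
            value = np.mean(np.column_stack(args), axis=1)
        elif d.op == "contrast":
            value = contrast_score(args[0], args[1])
        elif d.op == "efficiency":
            value = efficiency_score(args[0], args[1])
        elif d.op == "accuracy":
            value = np.asarray(args[0], dtype=float)
        elif d.op == "negate":
            value = -np.asarray(args[0], dtype=float)
        computed[d.name] = np.atleast_1d(value)
        if not d.name.startswith("_"):
            emitted.append(d.name)
    out = pd.DataFrame({name: computed[name] for name in emitted}, index=raw.index)
    if standardize:
        out = standardize_columns(out, allow_constant=allow_constant)
    return out


def read_raw_table(path) -> pd.DataFrame:
    """Read a long-format raw measures table (columns: subject, measure,
    condition, value; tab-separated) and pivot it to the wide layout the
    schedule consumes (column ``measure`` or ``measure_condition``)."""
    long = pd.read_csv(path, sep="\t")
    required = {"subject", "measure", "value"}
    if not required.issubset(long.columns):
        raise ValueError(f"raw table needs columns {sorted(required)}")
    cond = long.get("condition")
    name = long["measure"].astype(str)
    if cond is not None:
        cond = cond.fillna("").astype(str)
        name = np.where(cond == "", name, name + "_" + cond)
    wide = (
        long.assign(_col=name)
        .pivot_table(index="subject", columns="_col", values="value", aggfunc="first")
    )
    wide.columns.name = None
    return wide


def _fit_scale(target: np.ndarray, half_range: float, slack: float = 1.25) -> float:
    """Largest per-unit scale keeping ``scale * target`` inside
    ``+/- half_range`` with headroom."""
    peak = float(np.max(np.abs(target))) if len(target) else 1.0
    peak = max(peak, 1e-12)
    return half_range / (slack * peak)


def synthesize_raw_measures(
    scores: pd.DataFrame, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Build a plausible raw-measures table whose assembled, standardized
    scores reproduce ``scores`` (after its own standardization) exactly.

    Every raw measure is an affine image of the corresponding target score
    with cohort-constant offset and scale, chosen so ranges stay physical
    (accuracies in (0, 1), reaction times positive, spans nonnegative);
    standardization removes the affine map, so assembly inverts exactly.
    The optional ``rng`` only jitters the nuisance (constant-free) measures
    such as the letter-fluency baseline.
    """
    missing = [c for c in SCORE_NAMES if c not in scores.columns]
    if missing:
        raise ValueError(f"score table missing columns {missing}")
    rng = rng or np.random.default_rng(0)
    n = len(scores)
    raw = pd.DataFrame(index=scores.index)

    def col(name):
        return scores[name].to_numpy(dtype=float)

    # digit span: forward/backward straddle the target symmetrically, so the
    # mean is an exact affine image of it
    span = 6.0 + _fit_scale(col("digit_span"), 3.0) * col("digit_span")
    gap = rng.uniform(0.3, 0.7, n)
    raw["digit_span_forward"] = span + gap
    raw["digit_span_backward"] = span - gap
    # fluency: the category-letter contrast carries the target, so the letter
    # baseline can vary freely per subject
    letter = rng.normal(15.0, 2.0, n)
    raw["fluency_letter"] = letter
    raw["fluency_category"] = (
        letter + 4.0 + _fit_scale(col("verbal_fluency"), 3.5) * col("verbal_fluency")
    )
    # plain accuracy scores, kept inside (0.05, 0.95)
    for score_name, measure in (
        ("picture_naming", "naming_accuracy"),
        ("four_mountains", "four_mountains_accuracy"),
        ("rapm", "rapm_accuracy"),
    ):
        raw[measure] = 0.5 + _fit_scale(col(score_name), 0.4) * col(score_name)
    # switching costs in ms; the assembled score is the negated cost
    raw["switch_cost"] = 100.0 - _fit_scale(col("flexibility"), 60.0) * col("flexibility")
    raw["inhibition_cost"] = 80.0 - _fit_scale(col("inhibition"), 50.0) * col("inhibition")
    # efficiency tasks: fixed accuracy, reaction time affine in the target
    for score_name, stem in (
        ("feature_matching", "feature_matching"),
        ("paired_associate", "paired_associate"),
    ):
        acc = 0.85
        rt = acc * (2.0 - _fit_scale(col(score_name), 1.2) * col(score_name))
        raw[f"reaction_time_{stem}"] = rt
        raw[f"accuracy_{stem}"] = np.full(n, acc)
    # picture-word matching: one condition carries the contrast, the paired
    # reference condition is a constant-efficiency baseline
    for score_name, varying, reference in (
        ("strength", "strong", "weak"),
        ("modality", "picture", "word"),
        ("specificity", "specific", "general"),
    ):
        acc = 0.85
        rt_ref = acc * 1.5
        rt_var = acc * (1.5 - _fit_scale(col(score_name), 1.0) * col(score_name))
        raw[f"reaction_time_{varying}"] = rt_var
        raw[f"accuracy_{varying}"] = np.full(n, acc)
        raw[f"reaction_time_{reference}"] = np.full(n, rt_ref)
        raw[f"accuracy_{reference}"] = np.full(n, acc)
    # unusual uses: an open-ended generation count
    raw["unusual_uses_score"] = (
        12.0 + _fit_scale(col("unusual_uses"), 6.0) * col("unusual_uses")
    )
    return raw
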