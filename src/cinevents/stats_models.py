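"""Segmentation-rate, agreement, and predictor-regression statistics.

These operations quantify how consistently a viewer panel segments a movie
at different classes of shot boundary, how much the viewers agree with each
other, and how low-level per-boundary covariates (music, shot duration,
scale, motion, luminance, clutter) predict segmentation consistency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from cinevents.annotations import ViewerResponseTable

__all__ = [
    "BOUNDARY_CLASSES",
    "BoundaryClass",
    "StatResult",
    "segmentation_rate",
    "pooled_segmentation_rate",
    "agreement_kappa",
    "welch_cohen",
    "fit_segmentation_predictors",
]

logger = logging.getLogger(__name__)

#: The boundary classes a coded+detected movie partitions its junctures into.
BOUNDARY_CLASSES = ("scene_boundary", "subscene_boundary", "montage_internal",
                    "within_scene")

#: Alias used in type hints; classes are plain strings from BOUNDARY_CLASSES.
BoundaryClass = str


@dataclass(frozen=True)
class StatResult:
    """One inferential result: estimate, uncertainty, test, effect size."""

    estimate: float
    se: float
    statistic: float
    df: float | tuple
    p: float
    effect_size_d: float | None = None


def segmentation_rate(responses: ViewerResponseTable,
                      classes: Mapping[int, str]) -> dict[str, float | None]:
    """Viewer-averaged segmentation proportion per boundary class.

    ``rate(class) = sum(responses at class boundaries) /
    (n_viewers * n_boundaries in class)``; a class with no boundaries in
    the table is reported as ``None``.
    """
    missing = [b for b in responses.responses if b not in classes]
    if missing:
        raise ValueError(f"boundaries without a class assignment: {missing[:5]}")
    totals: dict[str, int] = {}
    counts: dict[str, int] = {}
    for b, votes in responses.responses.items():
        cls = classes[b]
        totals[cls] = totals.get(cls, 0) + int(sum(votes))
        counts[cls] = counts.get(cls, 0) + 1
    out: dict[str, float | None] = {}
    for cls in BOUNDARY_CLASSES:
        if counts.get(cls):
            out[cls] = totals[cls] / (responses.n_viewers * counts[cls])
        else:
            out[cls] = None
    return out


def pooled_segmentation_rate(tables: Sequence[ViewerResponseTable],
                             classes_per_movie: Sequence[Mapping[int, str]],
                             ) -> dict[str, float | None]:
    """Corpus-level rates: pool response counts across movies before dividing."""
    totals: dict[str, int] = {}
    denoms: dict[str, int] = {}
    for table, classes in zip(tables, classes_per_movie):
        for b, votes in table.responses.items():
            cls = classes[b]
            totals[cls] = totals.get(cls, 0) + int(sum(votes))
            denoms[cls] = denoms.get(cls, 0) + table.n_viewers
    return {cls: (totals[cls] / denoms[cls] if denoms.get(cls) else None)
            for cls in BOUNDARY_CLASSES}


def agreement_kappa(responses: ViewerResponseTable) -> float:
    """Mean pairwise Cohen's kappa over the viewers' 0/1 boundary vectors.

    Pairs in which a viewer has zero variance (all 0 or all 1) have an
    undefined kappa and are excluded (logged).
    """
    if responses.n_viewers < 2:
        raise ValueError("kappa needs at least 2 viewers")
    bounds = sorted(responses.responses)
    vectors = np.array([[responses.responses[b][v] for b in bounds]
                        for v in range(responses.n_viewers)])
    kappas = []
    for i, j in combinations(range(responses.n_viewers), 2):
        a, b = vectors[i], vectors[j]
        if a.std() == 0.0 or b.std() == 0.0:
            if np.array_equal(a, b):
                kappas.append(1.0)  # identical constant vectors: full agreement
            else:
                logger.info("kappa undefined for viewer pair (%d, %d); excluded",
                            i + 1, j + 1)
            continue
        kappas.append(float(cohen_kappa_score(a, b)))
    if not kappas:
        raise ValueError("kappa undefined for every viewer pair")
    return float(np.mean(kappas))


def welch_cohen(group_a: Sequence[float], group_b: Sequence[float]) -> StatResult:
    """Welch two-sample t test with Satterthwaite df, plus Cohen's d.

    ``d`` uses the pooled standard deviation.  The estimate is
    ``mean(A) - mean(B)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = float(a.mean() - b.mean())
    se = float(np.sqrt(va / a.size + vb / b.size))
    if se == 0.0:
        # both groups constant; equal means give t = 0 by convention
        t_stat, df, p = (0.0, float(a.size + b.size - 2), 1.0) if diff == 0.0 else \
            (np.inf * np.sign(diff), float(a.size + b.size - 2), 0.0)
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
        t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    s_pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    d = diff / s_pooled if s_pooled > 0 else 0.0
    return StatResult(estimate=diff, se=se, statistic=t_stat, df=df, p=p,
                      effect_size_d=float(d))


PREDICTORS = ("music01", "log_duration", "scale", "motion", "luminance", "clutter")

#: Only effects below this alpha are flagged (large-sample screen).
STRICT_ALPHA = 1e-4


def fit_segmentation_predictors(table: pd.DataFrame,
                                alpha: float = STRICT_ALPHA) -> dict:
    """Regress per-boundary segmentation consistency on six covariates.

    ``table`` has one row per boundary with columns ``mean_response`` (the
    per-boundary viewer mean, treated as continuous), the six predictors
    ``music01, log_duration, scale, motion, luminance, clutter``, and
    ``movie_id``.  The movie enters as a nominal factor (dropped, with a
    warning, when only one movie is present).  Returns per-predictor
    :class:`StatResult` (with a ``significant`` flag at ``alpha``), the
    model R^2, and ``r2_retained``: the R^2 of a reduced model with only
    music, log duration and scale (no movie factor).
    """
    required = ("mean_response",) + PREDICTORS + ("movie_id",)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    X = table[list(PREDICTORS)].astype(float).copy()
    constant = [c for c in PREDICTORS if X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant predictor(s) after centering: {constant}")
    n_movies = table["movie_id"].nunique()
    if n_movies > 1:
        dummies = pd.get_dummies(table["movie_id"], prefix="movie",
                                 drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    else:
        warnings.warn("single movie: nominal movie factor dropped", stacklevel=2)
    X = sm.add_constant(X)
    y = table["mean_response"].astype(float)
    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    names = list(X.columns)
    coefficients = {}
    for name in PREDICTORS:
        k = names.index(name)
        coefficients[name] = StatResult(
            estimate=float(fit.params[k]), se=float(fit.bse[k]),
            statistic=float(fit.tvalues[k]), df=float(fit.df_resid),
            p=float(fit.pvalues[k]))
    reduced = sm.OLS(
        y.to_numpy(),
        sm.add_constant(table[["music01", "log_duration", "scale"]].astype(float)
                        .to_numpy())).fit()
    return {
        "coefficients": coefficients,
        "significant": {name: res.p < alpha for name, res in coefficients.items()},
        "r2": float(fit.rsquared),
        "r2_retained": float(reduced.rsquared),
        "n": int(len(table)),
        "alpha": alpha,
    }
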