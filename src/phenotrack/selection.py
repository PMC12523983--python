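"""Multiclass separation scores and elbow-point feature selection.

For one feature measured over G labelled classes with class sizes n_g,
class means x̄_g and class sample variances s_g², the separation score is
the ratio of between- to within-class variance,

    x̄̄  = (1/N) Σ n_g x̄_g,           N = Σ n_g
    VB = (1/(N−G)) Σ n_g (x̄_g − x̄̄)²
    VW = (1/(N−G)) Σ (n_g − 1) s_g²
    Separation = VB / VW

(both variances share the N−G normaliser, so the score is the ratio of the
between- and within-class sums of squares). A higher score means the
feature separates the classes more cleanly. Features are ranked by score
and thresholded at the elbow of the descending score profile: the score
with the largest vertical drop below the chord joining the largest and
smallest scores. Selection keeps every feature scoring at or above the
threshold.

Conventions for edge cases: VB = 0 gives score 0; VW = 0 with VB > 0 gives
+inf — infinite scores rank first, are always selected, and are excluded
from the chord fit so they cannot flatten it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class ClassStats:
    """Per-class moments of one feature plus the pooled variances."""

    n: np.ndarray  # class sizes
    means: np.ndarray
    variances: np.ndarray  # sample variances (n-1 denominator)
    grand_mean: float
    vb: float
    vw: float


@dataclass
class SeparationResult:
    """Scores, threshold and selection for one labelled feature table."""

    scores: pd.Series  # feature -> score, original column order
    order: list[str]  # feature names sorted by descending score
    threshold: float
    elbow_index: int  # position of the threshold in `order`
    selected: list[str]  # selected features, original column order
    flagged: list[str]  # features scored on a finite subset of cells


def compute_class_stats(groups: list[np.ndarray]) -> ClassStats:
    """Class moments and pooled between/within variances for one feature."""
    G = len(groups)
    if G < 2:
        raise ParameterError("separation needs at least 2 classes")
    n = np.array([len(g) for g in groups])
    if (n < 1).any():
        raise ParameterError("every class must contain at least one sample")
    N = int(n.sum())
    if N <= G:
        raise ParameterError(f"need more samples ({N}) than classes ({G})")
    means = np.array([np.mean(g) for g in groups])
    variances = np.array([np.var(g, ddof=1) if len(g) > 1 else 0.0 for g in groups])
    grand_mean = float((n * means).sum() / N)
    vb = float((n * (means - grand_mean) ** 2).sum() / (N - G))
    vw = float(((n - 1) * variances).sum() / (N - G))
    return ClassStats(n, means, variances, grand_mean, vb, vw)


def separation_score(groups: list[np.ndarray]) -> float:
    """VB/VW for one feature split by class; see module docstring."""
    stats = compute_class_stats(groups)
    if stats.vb == 0.0:
        return 0.0
    if stats.vw == 0.0:
        return float("inf")
    return stats.vb / stats.vw


def separation_scores(X: pd.DataFrame, labels: pd.Series | np.ndarray) -> SeparationResult:
    """Score every feature column of a labelled table.

    Columns containing non-finite values are scored on the finite subset of
    cells and flagged. The returned result carries scores only; combine with
    :func:`elbow_threshold` / :func:`select_features` or use
    :func:`select` for the full procedure.
    """
    labels = np.asarray(labels)
    classes = pd.unique(labels[~pd.isna(labels)])
    if len(classes) < 2:
        raise ParameterError("feature scoring needs at least 2 classes")
    scores = {}
    flagged = []
    class_masks = [(labels == c) for c in classes]
    for col in X.columns:
        values = X[col].to_numpy(dtype=float)
        finite = np.isfinite(values)
        if not finite.all():
            flagged.append(col)
        groups = [values[m & finite] for m in class_masks]
        try:
            scores[col] = separation_score(groups)
        except ParameterError:
            scores[col] = float("nan")  # a class lost all its finite values
            logger.warning("feature %s unscorable on the finite subset", col)
    series = pd.Series(scores, dtype=float)
    return SeparationResult(
        scores=series,
        order=list(series.sort_values(ascending=False, kind="stable").index),
        threshold=float("nan"),
        elbow_index=-1,
        selected=[],
        flagged=flagged,
    )


def elbow_threshold(scores: np.ndarray | pd.Series) -> tuple[float, int]:
    """Optimal score threshold by the elbow method.

    Scores are sorted descending; a chord is drawn from the largest to the
    smallest finite score; the elbow is the score with the maximum vertical
    distance *below* the chord (ties resolved toward fewer features).
    Infinite scores sort first and are excluded from the chord. With two or
    fewer finite scores the threshold is the minimum score (all selected).
    Returns (threshold, index of the elbow in the descending order).
    """
    values = np.asarray(pd.Series(scores).to_numpy(), dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ParameterError("elbow needs at least one score")
    desc = np.sort(values)[::-1]
    finite = desc[np.isfinite(desc)]
    n_inf = desc.size - finite.size
    K = finite.size
    if K == 0:
        return float("inf"), 0
    if K <= 2:
        return float(finite[-1]), n_inf + K - 1
    s_max, s_min = finite[0], finite[-1]
    i = np.arange(K)
    chord = s_max + (s_min - s_max) * i / (K - 1)
    distance = chord - finite  # positive below the chord
    elbow = int(np.argmax(distance))  # argmax takes the smallest index on ties
    return float(finite[elbow]), n_inf + elbow


def select_features(result: SeparationResult, X: pd.DataFrame) -> pd.DataFrame:
    """Column subset with score >= threshold, original order preserved."""
    if np.isnan(result.threshold):
        raise ParameterError("threshold not computed; run elbow_threshold first")
    keep = [
        c
        for c in X.columns
        if not np.isnan(result.scores[c]) and result.scores[c] >= result.threshold
    ]
    return X[keep]


def select(X: pd.DataFrame, labels: pd.Series | np.ndarray) -> tuple[SeparationResult, pd.DataFrame]:
    """Full procedure: score, threshold at the elbow, select."""
    result = separation_scores(X, labels)
    threshold, elbow = elbow_threshold(result.scores)
    selected = [
        c
        for c in X.columns
        if not np.isnan(result.scores[c]) and result.scores[c] >= threshold
    ]
    result = SeparationResult(
        scores=result.scores,
        order=result.order,
        threshold=threshold,
        elbow_index=elbow,
        selected=selected,
        flagged=result.flagged,
    )
    return result, X[selected]


def score_table(result: SeparationResult, categories: dict[str, str] | None = None) -> pd.DataFrame:
    """Score report: feature, category, score, selected — descending order."""
    rows = []
    selected = set(result.selected)
    for name in result.order:
        rows.append(
            {
                "feature": name,
                "category": categories.get(name, "") if categories else "",
                "score": result.scores[name],
                "selected": name in selected,
            }
        )
    return pd.DataFrame(rows)
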