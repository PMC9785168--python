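"""Score derivation: rank-based AUC, Brunner–Munzel intervals, grid search.

The discriminative performance of a candidate score is measured by the
nonparametric rank-based AUC estimator

    AUC = P(score_pos > score_neg) + 1/2 P(score_pos = score_neg),

computed with midranks so ties count one half.  Confidence intervals come
from inverting the Brunner–Munzel test: the interval is the point estimate
plus/minus a Student-t quantile (Satterthwaite degrees of freedom) times the
standard error built from the within-group variances of (overall midrank −
within-group midrank), clamped to [0, 1].

Weights of the score equation are derived by exhaustive grid search over a
Cartesian grid of integer coefficients, maximizing the rank-based AUC, with
a deterministic tie-break (minimal coefficient sum, then lexicographic).
The dichotomization cut-off is the candidate value maximizing Youden's
J = sensitivity + specificity − 1 under the rule "positive iff score >=
cut-off", candidates being the distinct observed score values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError
from .lesion import ScoreComponents
from .scoring import WeightVector

__all__ = [
    "LabeledScores",
    "AucEstimate",
    "CutoffResult",
    "GridSearchResult",
    "auc_rank",
    "bm_confint",
    "roc_points",
    "youden_optimal_cutoff",
    "grid_search_weights",
    "components_matrix",
]


@dataclass(frozen=True)
class LabeledScores:
    """Scores with parallel binary labels (True = positive / CMI)."""

    scores: np.ndarray
    labels: np.ndarray

    @classmethod
    def from_arrays(cls, scores, labels) -> "LabeledScores":
        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels, dtype=bool)
        if s.ndim != 1 or y.shape != s.shape:
            raise DegenerateDataError(
                f"scores and labels must be parallel 1-d sequences, "
                f"got shapes {s.shape} and {y.shape}"
            )
        return cls(s, y)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.labels).sum())


def _labeled(scores, labels, min_per_class: int = 1) -> LabeledScores:
    data = LabeledScores.from_arrays(scores, labels)
    if data.n_pos < min_per_class or data.n_neg < min_per_class:
        raise DegenerateDataError(
            f"need at least {min_per_class} observation(s) per class, "
            f"got {data.n_pos} positive and {data.n_neg} negative"
        )
    return data


@dataclass(frozen=True)
class AucEstimate:
    """Rank-based AUC with a Brunner–Munzel confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    level: float
    n_pos: int
    n_neg: int
    std_error: float
    df: float


@dataclass(frozen=True)
class CutoffResult:
    """A dichotomization cut-off with its operating characteristics."""

    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class GridSearchResult:
    """Outcome of the exhaustive weight search."""

    best_weights: WeightVector
    best_auc: float
    n_candidates: int
    ties: tuple[WeightVector, ...]


def auc_rank(scores, labels) -> float:
    """Tie-aware rank-based AUC, ``P(pos > neg) + 1/2 P(pos = neg)``.

    Computed from midranks; identical to brute-force pairwise counting with
    tied pairs worth one half.
    """
    data = _labeled(scores, labels)
    ranks = stats.rankdata(data.scores)
    n_pos, n_neg = data.n_pos, data.n_neg
    pos_rank_sum = ranks[data.labels].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _bm_variance_parts(data: LabeledScores) -> tuple[float, float]:
    """Within-group rank variances (v_neg, v_pos) of the Brunner–Munzel construction.

    v_k is the sample variance of (overall midrank − within-group midrank)
    within group k.
    """
    ranks = stats.rankdata(data.scores)
    out = []
    for mask in (~data.labels, data.labels):
        r = ranks[mask]
        r_within = stats.rankdata(data.scores[mask])
        n_k = mask.sum()
        dev = r - r_within - r.mean() + (n_k + 1) / 2.0
        out.append(float((dev**2).sum() / (n_k - 1)))
    return out[0], out[1]


def bm_confint(scores, labels, level: float = 0.95) -> AucEstimate:
    """AUC point estimate with the inverted Brunner–Munzel interval.

    The point estimate is :func:`auc_rank`; the interval is
    ``auc ± t_{f, (1+level)/2} * se`` with the Satterthwaite–Welch degrees of
    freedom ``f`` and ``se = sqrt(n_neg*v_neg + n_pos*v_pos) / (n_neg*n_pos)``,
    clamped to [0, 1].  No transformation of the AUC scale is applied.
    """
    if not 0.0 < level < 1.0:
        raise DegenerateDataError(f"confidence level must lie in (0, 1), got {level!r}")
    data = _labeled(scores, labels, min_per_class=2)
    point = auc_rank(data.scores, data.labels)
    n_neg, n_pos = data.n_neg, data.n_pos
    v_neg, v_pos = _bm_variance_parts(data)
    pooled = n_neg * v_neg + n_pos * v_pos
    if pooled == 0.0:
        if np.ptp(data.scores) == 0.0:
            raise DegenerateDataError(
                "zero rank variance: all scores are identical, the Brunner-Munzel "
                "interval is undefined — collect more varied scores"
            )
        # fully concordant groups (e.g. perfect separation): the rank-variance
        # estimator vanishes and the inverted interval degenerates to the point
        se, df, half = 0.0, float("nan"), 0.0
    else:
        se = float(np.sqrt(pooled) / (n_neg * n_pos))
        df = float(
            pooled**2
            / ((n_neg * v_neg) ** 2 / (n_neg - 1) + (n_pos * v_pos) ** 2 / (n_pos - 1))
        )
        half = float(stats.t.ppf((1.0 + level) / 2.0, df) * se)
    return AucEstimate(
        auc=point,
        ci_low=max(0.0, point - half),
        ci_high=min(1.0, point + half),
        level=level,
        n_pos=n_pos,
        n_neg=n_neg,
        std_error=se,
        df=df,
    )


def roc_points(scores, labels) -> pd.DataFrame:
    """Operating characteristics at every candidate cut-off.

    Candidates are the distinct observed score values under the decision
    rule "positive iff score >= cutoff". Returns a DataFrame with columns
    ``cutoff``, ``sensitivity``, ``specificity``, ``youden_j`` sorted by
    cutoff ascending.
    """
    data = _labeled(scores, labels)
    cutoffs = np.unique(data.scores)
    pos = data.scores[data.labels]
    neg = data.scores[~data.labels]
    sens = (pos[None, :] >= cutoffs[:, None]).mean(axis=1)
    spec = (neg[None, :] < cutoffs[:, None]).mean(axis=1)
    return pd.DataFrame(
        {
            "cutoff": cutoffs,
            "sensitivity": sens,
            "specificity": spec,
            "youden_j": sens + spec - 1.0,
        }
    )


def youden_optimal_cutoff(scores, labels, atol: float = 1e-9) -> CutoffResult:
    """Cut-off maximizing Youden's J; ties broken toward the smallest cut-off.

    J values within ``atol`` of the maximum count as tied, so rational ties
    are not broken by floating-point summation order.
    """
    table = roc_points(scores, labels)
    j = table["youden_j"].to_numpy()
    best = int(np.flatnonzero(j >= j.max() - atol)[0])
    row = table.iloc[best]
    return CutoffResult(
        cutoff=float(row["cutoff"]),
        sensitivity=float(row["sensitivity"]),
        specificity=float(row["specificity"]),
    )


def components_matrix(components: Iterable[ScoreComponents]) -> np.ndarray:
    """Stack component profiles into an integer (n, 6) array."""
    arr = np.asarray(
        [c.as_tuple() if isinstance(c, ScoreComponents) else tuple(c) for c in components],
        dtype=np.int64,
    )
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise DegenerateDataError(f"expected an (n, 6) component table, got shape {arr.shape}")
    return arr


def grid_search_weights(
    components: Iterable[ScoreComponents],
    labels,
    grid: "Sequence[int] | Sequence[Sequence[int]]" = range(4),
    atol: float = 1e-12,
) -> GridSearchResult:
    """Exhaustive search of the weight grid for the maximal rank-based AUC.

    Parameters
    ----------
    components :
        Per-patient component profiles (or 6-tuples).
    labels :
        Parallel binary labels (True = CMI).
    grid :
        Admissible integer values, either one sequence applied to every
        coefficient (default ``0..3``) or six per-coefficient sequences.
    atol :
        Absolute tolerance when collecting AUC ties.

    Returns
    -------
    GridSearchResult
        ``best_weights`` is the tie member with minimal coefficient sum,
        then lexicographically smallest; ``ties`` lists every maximizer.
    """
    x = components_matrix(components)
    y = np.asarray(labels, dtype=bool)
    data = _labeled(np.zeros(len(y)), y)  # class-balance check only
    if len(x) != len(y):
        raise DegenerateDataError(
            f"component table ({len(x)} rows) and labels ({len(y)}) differ in length"
        )
    axes = _grid_axes(grid)
    candidates = np.array(list(itertools.product(*axes)), dtype=np.int64)
    if candidates.size == 0:
        raise DegenerateDataError("empty weight grid")

    scores = x @ candidates.T  # (n_patients, n_candidates)
    ranks = stats.rankdata(scores, axis=0)
    n_pos, n_neg = data.n_pos, data.n_neg
    aucs = (ranks[y].sum(axis=0) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    best_auc = float(aucs.max())
    tie_idx = np.flatnonzero(aucs >= best_auc - atol)
    tie_tuples = sorted(
        (tuple(int(w) for w in candidates[i]) for i in tie_idx),
        key=lambda t: (sum(t), t),
    )
    ties = tuple(WeightVector(*t) for t in tie_tuples)
    return GridSearchResult(
        best_weights=ties[0],
        best_auc=best_auc,
        n_candidates=len(candidates),
        ties=ties,
    )


def _grid_axes(grid) -> list[list[int]]:
    grid = list(grid)
    if grid and isinstance(grid[0], (list, tuple, range, np.ndarray)):
        axes = [sorted(int(v) for v in axis) for axis in grid]
        if len(axes) != 6:
            raise DegenerateDataError(f"need 6 per-coefficient grids, got {len(axes)}")
    else:
        axes = [sorted(int(v) for v in grid)] * 6
    if any(len(a) == 0 for a in axes):
        raise DegenerateDataError("empty weight grid")
    return axes
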