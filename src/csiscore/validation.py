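"""Internal validation: bootstrap AUC, inter-rater agreement, cross-tabs.

The bootstrap resamples patients (score and label jointly) with replacement,
recomputes the rank-based AUC on every resample, and summarizes the
resampled distribution by its mean, minimum, maximum and a percentile
confidence interval.  Resamples that lose one of the two classes are
skipped and counted.

Inter-rater reliability between two examiners scoring the same patients is
quantified by exact percent agreement and by unweighted Cohen's kappa with
its asymptotic confidence interval (scores treated as nominal categories;
a linearly weighted kappa is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa

from .errors import DegenerateDataError, SchemaError
from .derivation import LabeledScores, _labeled

__all__ = [
    "BootstrapConfig",
    "BootstrapSummary",
    "AgreementResult",
    "CrosstabResult",
    "bootstrap_auc",
    "percent_agreement",
    "cohen_kappa",
    "crosstab",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling configuration; the seed is mandatory for reproducibility."""

    n_reps: int = 100_000
    seed: int = 0
    level: float = 0.95
    stratified: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise DegenerateDataError(f"n_reps must be >= 1, got {self.n_reps}")
        if not 0.0 < self.level < 1.0:
            raise DegenerateDataError(f"level must lie in (0, 1), got {self.level!r}")


@dataclass(frozen=True)
class BootstrapSummary:
    """Summary of the resampled AUC distribution."""

    mean_auc: float
    min_auc: float
    max_auc: float
    std_auc: float
    ci_low: float
    ci_high: float
    level: float
    n_reps: int
    n_reps_effective: int


# chunk size for vectorized resampling; fixed so a given seed yields the same
# draw sequence regardless of n_reps
_CHUNK = 2_000


def bootstrap_auc(scores, labels, config: BootstrapConfig) -> BootstrapSummary:
    """Bootstrap the rank-based AUC of a labeled cohort.

    Patients are drawn with replacement (same size as the cohort); with
    ``config.stratified`` the positives and negatives are resampled within
    class, fixing the class sizes. Deterministic for a fixed config.
    """
    data = _labeled(scores, labels)
    n = len(data.scores)
    rng = np.random.default_rng(config.seed)
    aucs: list[np.ndarray] = []
    done = 0
    pos_idx = np.flatnonzero(data.labels)
    neg_idx = np.flatnonzero(~data.labels)
    while done < config.n_reps:
        reps = min(_CHUNK, config.n_reps - done)
        if config.stratified:
            ip = pos_idx[rng.integers(0, len(pos_idx), size=(reps, len(pos_idx)))]
            ineg = neg_idx[rng.integers(0, len(neg_idx), size=(reps, len(neg_idx)))]
            idx = np.concatenate([ip, ineg], axis=1)
        else:
            idx = rng.integers(0, n, size=(reps, n))
        s = data.scores[idx]
        y = data.labels[idx]
        n_pos = y.sum(axis=1)
        valid = (n_pos > 0) & (n_pos < n)
        if valid.any():
            ranks = stats.rankdata(s[valid], axis=1)
            npv = n_pos[valid]
            pos_sum = np.where(y[valid], ranks, 0.0).sum(axis=1)
            aucs.append((pos_sum - npv * (npv + 1) / 2.0) / (npv * (n - npv)))
        done += reps
    if not aucs:
        raise DegenerateDataError(
            "every bootstrap resample lost one of the classes; the cohort is too "
            "small or too unbalanced for resampling"
        )
    auc = np.concatenate(aucs)
    alpha = 1.0 - config.level
    lo, hi = np.percentile(auc, [100 * alpha / 2.0, 100 * (1.0 - alpha / 2.0)])
    return BootstrapSummary(
        mean_auc=float(auc.mean()),
        min_auc=float(auc.min()),
        max_auc=float(auc.max()),
        std_auc=float(auc.std(ddof=1)) if auc.size > 1 else 0.0,
        ci_low=float(lo),
        ci_high=float(hi),
        level=config.level,
        n_reps=config.n_reps,
        n_reps_effective=int(auc.size),
    )


def _paired(rater1, rater2) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(rater1)
    b = np.asarray(rater2)
    if a.ndim != 1 or a.shape != b.shape:
        raise SchemaError(
            f"rater sequences must be parallel 1-d sequences, got shapes {a.shape} and {b.shape}"
        )
    if a.size == 0:
        raise SchemaError("rater sequences are empty")
    return a, b


def percent_agreement(rater1, rater2) -> tuple[int, float]:
    """Exact agreement between two raters: (n_agree, unrounded percentage)."""
    a, b = _paired(rater1, rater2)
    n_agree = int((a == b).sum())
    return n_agree, 100.0 * n_agree / a.size


@dataclass(frozen=True)
class AgreementResult:
    """Percent agreement and Cohen's kappa between two raters."""

    n_agree: int
    n_total: int
    percent_agreement: float
    kappa: float
    kappa_ci_low: float
    kappa_ci_high: float
    level: float


def cohen_kappa(rater1, rater2, level: float = 0.95, weighted: bool = False) -> AgreementResult:
    """Cohen's kappa over exact score categories, with an asymptotic CI.

    kappa = (p_o − p_e) / (1 − p_e) on the square contingency table over the
    union of observed categories; the interval is kappa ± z_{(1+level)/2}
    times the asymptotic standard error.  ``weighted=True`` uses linear
    disagreement weights instead of the identity agreement matrix.
    """
    a, b = _paired(rater1, rater2)
    if not 0.0 < level < 1.0:
        raise DegenerateDataError(f"level must lie in (0, 1), got {level!r}")
    cats = np.union1d(a, b)
    if cats.size < 2:
        raise DegenerateDataError(
            "kappa is undefined: both raters assigned a single identical category "
            "(expected agreement is 1)"
        )
    idx = pd.CategoricalIndex(cats)
    table = pd.crosstab(
        pd.Categorical(a, categories=cats), pd.Categorical(b, categories=cats), dropna=False
    ).reindex(index=idx, columns=idx, fill_value=0)
    res = _sm_cohens_kappa(table.to_numpy(), wt="linear" if weighted else None)
    z = stats.norm.ppf((1.0 + level) / 2.0)
    n_agree, pct = percent_agreement(a, b)
    return AgreementResult(
        n_agree=n_agree,
        n_total=int(a.size),
        percent_agreement=pct,
        kappa=float(res.kappa),
        kappa_ci_low=float(res.kappa - z * res.std_kappa),
        kappa_ci_high=float(min(1.0, res.kappa + z * res.std_kappa)),
        level=level,
    )


@dataclass(frozen=True)
class CrosstabResult:
    """2x2 cross-tabulation of risk group against a binary attribute."""

    counts: pd.DataFrame        # rows: group levels; columns: [False, True]
    row_totals: pd.Series
    percent_true: pd.Series     # % of attribute=True within each row
    p_value: float
    test: str                   # "chi-square" or "fisher-exact"

    def formatted(self) -> pd.Series:
        """Rows rendered in the clinical "n (%)" style."""
        return pd.Series(
            {
                level: f"{int(self.counts.loc[level, True])} "
                f"({self.percent_true.loc[level]:.0f})"
                for level in self.counts.index
            }
        )


def crosstab(group, attribute) -> CrosstabResult:
    """Cross-tabulate a binary grouping against a binary attribute.

    Returns counts, within-row percentages of the attribute, and a Pearson
    chi-square p-value (Fisher's exact test is substituted when any expected
    cell count is below 5).
    """
    g = np.asarray(group)
    t = np.asarray(attribute, dtype=bool)
    if g.shape != t.shape or g.ndim != 1:
        raise SchemaError("group and attribute must be parallel 1-d sequences")
    levels = np.unique(g)
    if levels.size != 2:
        raise DegenerateDataError(
            f"grouping must have exactly two non-empty levels, got {levels.tolist()}"
        )
    counts = pd.DataFrame(
        {
            False: [int(((g == lv) & ~t).sum()) for lv in levels],
            True: [int(((g == lv) & t).sum()) for lv in levels],
        },
        index=pd.Index(levels, name="group"),
    )
    table = counts.to_numpy()
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateDataError("cross-tabulation has an empty margin")
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        _, p = stats.fisher_exact(table)
        test = "fisher-exact"
    else:
        p = stats.chi2_contingency(table, correction=False).pvalue
        test = "chi-square"
    row_totals = counts.sum(axis=1)
    return CrosstabResult(
        counts=counts,
        row_totals=row_totals,
        percent_true=100.0 * counts[True] / row_totals,
        p_value=float(p),
        test=test,
    )
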