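"""The CSI-score: weighted sum of the six lesion scales, and dichotomization.

The score is

    CSI = w1*C_extent + w2*C_grade + w3*S_extent + w4*S_grade
        + w5*I_extent + w6*I_grade

with published weights (1, 2, 1, 2, 1, 1), giving an integer score from 0
to 22 over the admissible component profiles (IMA extent capped at ostial).
Patients are dichotomized at a cut-off (published value 8) into a low-score
(< cut-off) and a high-score (>= cut-off) group; a finer five-bin
stratification (0–3, 4–7, 8–11, 12–15, >15) is also provided.

All arithmetic in this module is exact integer arithmetic.
"""

from __future__ import annotations

import functools
import itertools
import operator
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .errors import ConfigError, MeasurementError
from .lesion import ScoreComponents

__all__ = [
    "WeightVector",
    "DEFAULT_WEIGHTS",
    "DEFAULT_CUTOFF",
    "ScoredPatient",
    "csi_score",
    "iter_admissible_components",
    "score_range",
    "classify_risk",
    "score_subgroup",
    "SUBGROUP_LABELS",
]


@dataclass(frozen=True)
class WeightVector:
    """Non-negative integer coefficients of the score equation."""

    w_c_extent: int = 1
    w_c_grade: int = 2
    w_s_extent: int = 1
    w_s_grade: int = 2
    w_i_extent: int = 1
    w_i_grade: int = 1

    def __post_init__(self) -> None:
        for name, v in zip(self.__dataclass_fields__, self.as_tuple()):
            try:
                v = operator.index(v)
            except TypeError:
                raise ConfigError(f"{name} must be an integer, got {v!r}") from None
            if v < 0:
                raise ConfigError(f"{name} must be non-negative, got {v}")
            object.__setattr__(self, name, v)

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (
            self.w_c_extent,
            self.w_c_grade,
            self.w_s_extent,
            self.w_s_grade,
            self.w_i_extent,
            self.w_i_grade,
        )

    @classmethod
    def from_iterable(cls, values: Iterable[int]) -> "WeightVector":
        values = tuple(values)
        if len(values) != 6:
            raise ConfigError(f"a weight vector has 6 coefficients, got {len(values)}")
        return cls(*values)


#: Published weights of the score equation.
DEFAULT_WEIGHTS = WeightVector(1, 2, 1, 2, 1, 1)

#: Published low/high dichotomization cut-off.
DEFAULT_CUTOFF = 8


def csi_score(components: ScoreComponents, weights: WeightVector = DEFAULT_WEIGHTS) -> int:
    """Exact integer dot product of the component scales with the weights."""
    return sum(c * w for c, w in zip(components.as_tuple(), weights.as_tuple()))


def iter_admissible_components() -> Iterator[ScoreComponents]:
    """Enumerate every admissible component profile.

    Per vessel the admissible (extent, grade) pairs are (0, 0) plus any pair
    with extent >= 1 (grade 0 is a lesion below 51% stenosis); the IMA extent
    is restricted to {0, 1}. This yields 13 * 13 * 5 = 845 profiles.
    """
    ca_sma = [(0, 0)] + [(e, g) for e in (1, 2, 3) for g in (0, 1, 2, 3)]
    ima = [(0, 0)] + [(1, g) for g in (0, 1, 2, 3)]
    for (ce, cg), (se, sg), (ie, ig) in itertools.product(ca_sma, ca_sma, ima):
        yield ScoreComponents(ce, cg, se, sg, ie, ig)


@functools.lru_cache(maxsize=256)
def score_range(weights: WeightVector = DEFAULT_WEIGHTS) -> tuple[int, int]:
    """(min, max) of the score over all admissible component profiles."""
    scores = [csi_score(c, weights) for c in iter_admissible_components()]
    return min(scores), max(scores)


def classify_risk(score: int, cutoff: int = DEFAULT_CUTOFF) -> str:
    """Dichotomize a score: ``"high"`` iff score >= cutoff, else ``"low"``."""
    if score < 0:
        raise MeasurementError(f"a score cannot be negative, got {score}")
    return "high" if score >= cutoff else "low"


#: Stratification bins used for subgroup reports.
SUBGROUP_LABELS = ("0-3", "4-7", "8-11", "12-15", ">15")


def score_subgroup(score: int, max_score: int = 22) -> str:
    """Assign a score to its stratification bin (0–3, 4–7, 8–11, 12–15, >15)."""
    if not 0 <= score <= max_score:
        raise MeasurementError(f"score {score} outside the attainable range [0, {max_score}]")
    if score <= 3:
        return SUBGROUP_LABELS[0]
    if score <= 7:
        return SUBGROUP_LABELS[1]
    if score <= 11:
        return SUBGROUP_LABELS[2]
    if score <= 15:
        return SUBGROUP_LABELS[3]
    return SUBGROUP_LABELS[4]


@dataclass(frozen=True)
class ScoredPatient:
    """A patient's components, score and risk group under given weights."""

    patient_id: str
    components: ScoreComponents
    csi_score: int
    risk_group: str
    subgroup: str
    cmi_label: Optional[bool] = None
    annotations: frozenset[str] = field(default_factory=frozenset)


def score_patient(
    patient_id: str,
    components: ScoreComponents,
    weights: WeightVector = DEFAULT_WEIGHTS,
    cutoff: int = DEFAULT_CUTOFF,
    cmi_label: Optional[bool] = None,
    annotations: frozenset[str] = frozenset(),
) -> ScoredPatient:
    """Score one patient's components and attach the dichotomization."""
    score = csi_score(components, weights)
    _, max_score = score_range(weights)
    return ScoredPatient(
        patient_id=str(patient_id),
        components=components,
        csi_score=score,
        risk_group=classify_risk(score, cutoff),
        subgroup=score_subgroup(score, max_score=max(max_score, score)),
        cmi_label=cmi_label,
        annotations=annotations,
    )
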