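"""Lesion classification: from CTA measurements to extent/grade scales.

Each of the three main visceral arteries — celiac artery (CA), superior
mesenteric artery (SMA) and inferior mesenteric artery (IMA) — is described
by two ordinal scales read off CT angiography:

* **extent** of the lesion along the vessel: 0 none, 1 ostial (within the
  first 10 mm from the aortic lumen), 2 proximal (up to the first branch:
  the IPDA for the SMA, the bifurcation for the CA), 3 extended (beyond
  those landmarks).  For the IMA only ostial involvement is scored, so its
  extent scale is capped at 1.
* **grade** of the stenosis: 0 for 0–50% luminal narrowing, 1 for 51–70%,
  2 for 71–99%, 3 for occlusion.

Percent stenosis is computed from the residual luminal diameter and the
estimated normal luminal diameter at the same level as
``(1 - d_stenosis / d_normal) * 100``; a precomputed percent may be supplied
instead when diameters are unavailable (e.g. generalized calcification,
where the narrowest diameter drives the estimate).
"""

from __future__ import annotations

import logging
import operator
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from .errors import MeasurementError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "Vessel",
    "Reach",
    "LesionMeasurement",
    "ScoreComponents",
    "percent_stenosis",
    "grade_class",
    "extent_class",
    "components_from_measurements",
]


class Vessel(str, Enum):
    """The three scored visceral arteries, in canonical serialization order."""

    CA = "CA"
    SMA = "SMA"
    IMA = "IMA"

    @classmethod
    def parse(cls, value: "str | Vessel") -> "Vessel":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().upper())
        except ValueError:
            raise SchemaError(f"unknown vessel {value!r}; expected CA, SMA or IMA") from None


#: Canonical vessel ordering used for serialization and component layout.
VESSEL_ORDER: tuple[Vessel, ...] = (Vessel.CA, Vessel.SMA, Vessel.IMA)


class Reach(str, Enum):
    """Longitudinal reach of a lesion."""

    NONE = "none"
    OSTIAL = "ostial"
    PROXIMAL = "proximal"
    EXTENDED = "extended"

    @classmethod
    def parse(cls, value: "str | Reach", context: str = "") -> "Reach":
        if isinstance(value, cls):
            return value
        text = str(value).strip().lower()
        if text in ("", "na", "nan"):
            return cls.NONE
        try:
            return cls(text)
        except ValueError:
            where = f" ({context})" if context else ""
            raise SchemaError(
                f"unknown lesion reach {value!r}{where}; "
                "expected none, ostial, proximal or extended"
            ) from None


_REACH_SCALE = {Reach.NONE: 0, Reach.OSTIAL: 1, Reach.PROXIMAL: 2, Reach.EXTENDED: 3}


def percent_stenosis(d_stenosis: float, d_normal: float, vessel: Optional[Vessel] = None) -> float:
    """Percent diameter stenosis, ``(1 - d_stenosis/d_normal) * 100``.

    Parameters
    ----------
    d_stenosis : float
        Residual luminal diameter at the stenosis, mm.
    d_normal : float
        Estimated normal luminal diameter at the same level, mm.
    vessel : Vessel, optional
        Included in the error message when the measurement is invalid.

    Returns
    -------
    float in [0, 100].
    """
    where = f" for {vessel.value}" if vessel is not None else ""
    if d_normal <= 0:
        raise MeasurementError(f"d_normal must be > 0{where}, got {d_normal!r}")
    if d_stenosis < 0 or d_stenosis > d_normal:
        raise MeasurementError(
            f"d_stenosis must satisfy 0 <= d_stenosis <= d_normal{where}, "
            f"got d_stenosis={d_stenosis!r}, d_normal={d_normal!r}"
        )
    return 100.0 * (1.0 - d_stenosis / d_normal)


def grade_class(percent: float, occluded: bool = False) -> int:
    """Map percent stenosis to the ordinal grade scale 0..3.

    Occlusion (the flag, or percent == 100) is grade 3; otherwise the bands
    are 0–50% -> 0, 51–70% -> 1, 71–99% -> 2, applied to continuous input as
    grade 0 iff percent <= 50, grade 1 iff 50 < percent <= 70, grade 2 iff
    70 < percent < 100.
    """
    if not 0.0 <= percent <= 100.0:
        raise MeasurementError(f"percent stenosis must lie in [0, 100], got {percent!r}")
    if occluded or percent == 100.0:
        return 3
    if percent <= 50.0:
        return 0
    if percent <= 70.0:
        return 1
    return 2


def extent_class(reach: "Reach | str", vessel: "Vessel | str") -> int:
    """Map a lesion reach category to the ordinal extent scale.

    none -> 0, ostial -> 1, proximal -> 2, extended -> 3 for the CA and SMA.
    For the IMA only ostial involvement is scored: any non-none reach maps
    to 1 and a warning is logged.
    """
    vessel = Vessel.parse(vessel)
    reach = Reach.parse(reach, context=vessel.value)
    scale = _REACH_SCALE[reach]
    if vessel is Vessel.IMA and scale > 1:
        logger.warning(
            "IMA reach %r capped to ostial (extent 1): only ostial IMA stenosis is scored",
            reach.value,
        )
        return 1
    return scale


@dataclass(frozen=True)
class LesionMeasurement:
    """Raw per-vessel observation from CT angiography.

    Either both diameters or ``percent_override`` must be present for a
    vessel with a lesion; ``occluded`` forces an effective percent of 100,
    and ``absent`` (anatomic variant, vessel missing) makes the other fields
    irrelevant.
    """

    vessel: Vessel
    reach: Reach = Reach.NONE
    d_stenosis: Optional[float] = None
    d_normal: Optional[float] = None
    percent_override: Optional[float] = None
    occluded: bool = False
    absent: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "vessel", Vessel.parse(self.vessel))
        object.__setattr__(self, "reach", Reach.parse(self.reach, context=self.vessel.value))
        if self.absent:
            return
        if self.percent_override is not None and not 0.0 <= self.percent_override <= 100.0:
            raise MeasurementError(
                f"percent_override for {self.vessel.value} must lie in [0, 100], "
                f"got {self.percent_override!r}"
            )
        if self.d_stenosis is not None and self.d_normal is not None:
            # raises with vessel context if the diameters are inconsistent
            percent_stenosis(self.d_stenosis, self.d_normal, self.vessel)

    def effective_percent(self) -> float:
        """Percent stenosis this measurement implies, resolving overrides."""
        if self.occluded:
            return 100.0
        if self.reach is Reach.NONE:
            return 0.0
        if self.d_stenosis is not None and self.d_normal is not None:
            return percent_stenosis(self.d_stenosis, self.d_normal, self.vessel)
        if self.percent_override is not None:
            return float(self.percent_override)
        raise MeasurementError(
            f"{self.vessel.value}: a lesion is recorded (reach={self.reach.value}) but "
            "neither diameters nor a percent stenosis are available"
        )


@dataclass(frozen=True)
class ScoreComponents:
    """The six ordinal scales entering the score, in CA, SMA, IMA order.

    Invariants: every scale lies in 0..3, the IMA extent in 0..1, and a
    vessel without a lesion (extent 0) carries grade 0.
    """

    c_extent: int
    c_grade: int
    s_extent: int
    s_grade: int
    i_extent: int
    i_grade: int

    def __post_init__(self) -> None:
        for name in ("c_extent", "c_grade", "s_extent", "s_grade", "i_extent", "i_grade"):
            v = getattr(self, name)
            try:
                v = operator.index(v)
            except TypeError:
                raise MeasurementError(f"{name} must be an integer, got {v!r}") from None
            object.__setattr__(self, name, v)
        for name in ("c_extent", "c_grade", "s_extent", "s_grade", "i_grade"):
            v = getattr(self, name)
            if not 0 <= v <= 3:
                raise MeasurementError(f"{name} must be an integer in 0..3, got {v!r}")
        if self.i_extent not in (0, 1):
            raise MeasurementError(
                f"i_extent must be 0 or 1 (only ostial IMA stenosis is scored), "
                f"got {self.i_extent!r}"
            )
        for ext, grd, vessel in (
            (self.c_extent, self.c_grade, "CA"),
            (self.s_extent, self.s_grade, "SMA"),
            (self.i_extent, self.i_grade, "IMA"),
        ):
            if ext == 0 and grd != 0:
                raise MeasurementError(
                    f"{vessel}: grade {grd} recorded without a lesion (extent 0)"
                )

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (
            self.c_extent,
            self.c_grade,
            self.s_extent,
            self.s_grade,
            self.i_extent,
            self.i_grade,
        )


def components_from_measurements(
    measurements: Iterable[LesionMeasurement],
) -> tuple[ScoreComponents, frozenset[str]]:
    """Classify one patient's three vessel measurements into score components.

    Parameters
    ----------
    measurements :
        Exactly one :class:`LesionMeasurement` per vessel (CA, SMA, IMA, in
        any order).

    Returns
    -------
    (ScoreComponents, annotations)
        ``annotations`` flags absent vessels (``"ca_absent"``...) and capped
        IMA reach (``"ima_reach_capped"``).

    Notes
    -----
    An absent vessel contributes (0, 0). A measurement with percent 100 but
    ``occluded=False`` is resolved to grade 3 with a logged warning.
    """
    by_vessel: dict[Vessel, LesionMeasurement] = {}
    for m in measurements:
        if m.vessel in by_vessel:
            raise SchemaError(f"duplicate measurement for vessel {m.vessel.value}")
        by_vessel[m.vessel] = m
    missing = [v.value for v in VESSEL_ORDER if v not in by_vessel]
    if missing:
        raise SchemaError(f"missing measurement for vessel(s): {', '.join(missing)}")

    scales: list[int] = []
    annotations: set[str] = set()
    for vessel in VESSEL_ORDER:
        m = by_vessel[vessel]
        key = vessel.value.lower()
        if m.absent:
            annotations.add(f"{key}_absent")
            scales.extend((0, 0))
            continue
        if vessel is Vessel.IMA and _REACH_SCALE[m.reach] > 1:
            annotations.add("ima_reach_capped")
        extent = extent_class(m.reach, vessel)
        if m.reach is Reach.NONE:
            grade = 0
        else:
            percent = m.effective_percent()
            if percent == 100.0 and not m.occluded:
                logger.warning(
                    "%s: percent stenosis 100 with occluded=false; graded as occlusion",
                    vessel.value,
                )
            grade = grade_class(percent, m.occluded)
        scales.extend((extent, grade))
    return ScoreComponents(*scales), frozenset(annotations)
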