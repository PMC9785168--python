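"""Synthetic two-group cohort generator.

No patient-level data are published for this kind of cohort, so derivation
and validation are exercised on synthetic patients built from a latent
atherosclerotic severity scale:

1. Each patient belongs to a CMI or non-CMI mixture component (prevalence
   ``cmi_prevalence``) and draws a latent severity from a normal
   distribution located at the component's mean.
2. Each vessel observes the severity with independent noise; the noisy
   value is thresholded into the lesion reach (none / ostial / proximal /
   extended; the IMA is ostial-only) and mapped through a probit curve to
   percent stenosis, with occlusion above a fixed severity threshold.
   Higher severity therefore means more affected vessels, greater reach and
   higher grade, stochastically.
3. Luminal diameters consistent with the drawn percent are emitted
   (``d_normal`` uniform in a physiologic 5–9 mm range, ``d_stenosis``
   back-computed), so the lesion-classification pipeline can re-derive the
   true components exactly from the measurement table.
4. The CMI label is assigned from latent severity: ``label_model="logistic"``
   draws Bernoulli(sigmoid(slope * (severity - mid))) with ``mid`` solved so
   the expected prevalence matches the configured one (labels are then noisy
   in the score, and AUC < 1); ``label_model="threshold"`` labels a patient
   positive iff the true score reaches the default cut-off 8, an oracle mode
   for exact weight/cut-off recovery tests.

Default locations are calibrated so the simulated score distributions
bracket the reference cohort's group medians (CMI around 14, non-CMI around
4, scores spanning 0–22).  All randomness flows from one seed through
spawned sub-streams (mixture/severity, lesions, labels), so each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ConfigError
from .lesion import VESSEL_ORDER
from .scoring import DEFAULT_CUTOFF, DEFAULT_WEIGHTS, WeightVector

__all__ = ["SimConfig", "simulate_cohort", "simulate_raters", "cohort_to_input_frame"]

#: Truth columns appended to the measurement schema by the generator.
TRUTH_COLUMNS = [
    "latent_severity",
    "c_extent",
    "c_grade",
    "s_extent",
    "s_grade",
    "i_extent",
    "i_grade",
    "true_score",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    The reach thresholds, grade curve and occlusion threshold live on a
    common latent-severity scale (unitless); the component locations are the
    calibrated knobs that set how severe each group is.
    """

    n_patients: int = 242
    cmi_prevalence: float = 0.45
    severity_location_cmi: float = 0.85
    severity_location_non: float = 0.10
    severity_scale: float = 0.35
    vessel_noise: float = 0.30
    percent_noise: float = 0.20
    ima_offset: float = -0.15
    label_model: str = "logistic"
    logistic_slope: float = 5.0
    seed: int = 0
    # lesion mapping (latent scale): reach bands, probit grade curve, occlusion
    reach_thresholds: tuple[float, float, float] = (0.0, 0.55, 1.0)
    grade_curve_mid: float = 0.35
    grade_curve_scale: float = 0.45
    occlusion_threshold: float = 1.10

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigError(f"n_patients must be >= 2, got {self.n_patients}")
        if not 0.0 < self.cmi_prevalence < 1.0:
            raise ConfigError(f"cmi_prevalence must lie in (0, 1), got {self.cmi_prevalence!r}")
        if self.label_model not in ("logistic", "threshold"):
            raise ConfigError(
                f"label_model must be 'logistic' or 'threshold', got {self.label_model!r}"
            )
        for name in ("severity_scale", "vessel_noise", "percent_noise", "grade_curve_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        t1, t2, t3 = self.reach_thresholds
        if not t1 < t2 < t3:
            raise ConfigError(f"reach_thresholds must be increasing, got {self.reach_thresholds}")


def _grade_from_percent(percent: np.ndarray, occluded: np.ndarray) -> np.ndarray:
    return np.select(
        [occluded | (percent == 100.0), percent <= 50.0, percent <= 70.0],
        [3, 0, 1],
        default=2,
    )


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate a cohort table in the measurement schema plus truth columns.

    Returns a DataFrame with one row per patient: ``patient_id``,
    ``cmi_label``, per-vessel ``{ca,sma,ima}_reach / _d_sten_mm / _d_norm_mm /
    _percent / _occluded / _absent`` (diameters filled, percent left empty),
    and the truth columns ``latent_severity``, the six true components and
    ``true_score``.  Deterministic for a fixed config.
    """
    n = config.n_patients
    rng_sev, rng_les, rng_lab = (
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(3)
    )

    component = rng_sev.random(n) < config.cmi_prevalence
    loc = np.where(component, config.severity_location_cmi, config.severity_location_non)
    severity = loc + rng_sev.normal(0.0, config.severity_scale, size=n)

    t_lesion, t_prox, t_ext = config.reach_thresholds
    cols: dict[str, np.ndarray] = {"patient_id": np.array([f"P{i:05d}" for i in range(n)])}
    extents: list[np.ndarray] = []
    grades: list[np.ndarray] = []
    for vessel in VESSEL_ORDER:
        key = vessel.value.lower()
        offset = config.ima_offset if key == "ima" else 0.0
        u = severity + offset + rng_les.normal(0.0, config.vessel_noise, size=n)
        if key == "ima":
            extent = (u >= t_lesion).astype(np.int64)  # ostial-only scoring
        else:
            extent = (u >= t_lesion).astype(np.int64) + (u >= t_prox) + (u >= t_ext)
        has_lesion = extent > 0

        p_lat = u + rng_les.normal(0.0, config.percent_noise, size=n)
        occluded = has_lesion & (p_lat >= config.occlusion_threshold)
        percent = 100.0 * stats.norm.cdf(
            (p_lat - config.grade_curve_mid) / config.grade_curve_scale
        )
        percent = np.where(occluded, 100.0, np.where(has_lesion, percent, 0.0))
        grade = np.where(has_lesion, _grade_from_percent(percent, occluded), 0)

        d_norm = np.round(rng_les.uniform(5.0, 9.0, size=n), 1)
        d_sten = np.where(occluded, 0.0, d_norm * (1.0 - percent / 100.0))

        reach_names = np.array(["none", "ostial", "proximal", "extended"])
        reach = reach_names[np.minimum(extent, 1 if key == "ima" else 3)]
        cols[f"{key}_reach"] = reach
        cols[f"{key}_d_sten_mm"] = d_sten
        cols[f"{key}_d_norm_mm"] = d_norm
        cols[f"{key}_percent"] = np.full(n, np.nan)
        cols[f"{key}_occluded"] = occluded
        cols[f"{key}_absent"] = np.zeros(n, dtype=bool)
        extents.append(extent)
        grades.append(grade)

    weights = DEFAULT_WEIGHTS.as_tuple()
    comp_mat = np.stack(
        [extents[0], grades[0], extents[1], grades[1], extents[2], grades[2]], axis=1
    )
    true_score = comp_mat @ np.asarray(weights, dtype=np.int64)

    if config.label_model == "threshold":
        label = true_score >= DEFAULT_CUTOFF
    else:
        mid = _solve_logistic_mid(severity, config.logistic_slope, config.cmi_prevalence)
        p = special.expit(config.logistic_slope * (severity - mid))
        label = rng_lab.random(n) < p

    cols["cmi_label"] = label
    cols["latent_severity"] = severity
    for name, col in zip(TRUTH_COLUMNS[1:7], comp_mat.T):
        cols[name] = col
    cols["true_score"] = true_score

    order = ["patient_id", "cmi_label"]
    for vessel in VESSEL_ORDER:
        key = vessel.value.lower()
        order += [
            f"{key}_reach",
            f"{key}_d_sten_mm",
            f"{key}_d_norm_mm",
            f"{key}_percent",
            f"{key}_occluded",
            f"{key}_absent",
        ]
    return pd.DataFrame(cols)[order + TRUTH_COLUMNS]


def _solve_logistic_mid(severity: np.ndarray, slope: float, prevalence: float) -> float:
    """Midpoint of the label curve such that the expected prevalence matches."""

    def excess(mid: float) -> float:
        return float(special.expit(slope * (severity - mid)).mean() - prevalence)

    lo = float(severity.min()) - 50.0 / slope
    hi = float(severity.max()) + 50.0 / slope
    return float(optimize.brentq(excess, lo, hi))


def cohort_to_input_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop the truth columns, leaving the measurement-schema table."""
    return cohort.drop(columns=[c for c in TRUTH_COLUMNS if c in cohort.columns])


def simulate_raters(
    cohort: pd.DataFrame,
    disagreement_rate: float,
    seed: int,
    weights: WeightVector = DEFAULT_WEIGHTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Two examiners' scores: truth, and a perturbed re-reading.

    Rater 1 returns the true scores.  Rater 2 re-reads a Bernoulli
    ``disagreement_rate`` subset of patients differently: on one random
    vessel the grade moves one class up or down (reflected at the scale
    boundaries); a vessel with no lesion instead gains an ostial sub-50%
    lesion, so every perturbation changes the score and the expected
    agreement is approximately ``1 - disagreement_rate``.
    """
    if not 0.0 <= disagreement_rate <= 1.0:
        raise ConfigError(f"disagreement_rate must lie in [0, 1], got {disagreement_rate!r}")
    comp = cohort[TRUTH_COLUMNS[1:7]].to_numpy(dtype=np.int64, copy=True)
    w = np.asarray(weights.as_tuple(), dtype=np.int64)
    scores1 = comp @ w

    rng = np.random.default_rng(seed)
    n = len(comp)
    perturb = rng.random(n) < disagreement_rate
    vessel = rng.integers(0, 3, size=n)
    delta = np.where(rng.random(n) < 0.5, -1, 1)

    comp2 = comp.copy()
    for i in np.flatnonzero(perturb):
        e_col, g_col = 2 * vessel[i], 2 * vessel[i] + 1
        if comp2[i, e_col] == 0:
            comp2[i, e_col] = 1  # new ostial lesion, grade stays 0
            continue
        g = comp2[i, g_col] + delta[i]
        if g < 0 or g > 3:
            g = comp2[i, g_col] - delta[i]
        comp2[i, g_col] = g
    return scores1, comp2 @ w
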