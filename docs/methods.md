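# Methods

## Lesion classification

Each visceral artery (CA, SMA, IMA) contributes an *extent* scale (0 none,
1 ostial, 2 proximal, 3 extended) and a *grade* scale (0: 0–50 %, 1:
51–70 %, 2: 71–99 %, 3: occlusion) derived from percent diameter stenosis
`(1 − D_stenosis/D_normal) × 100`. Because measured percentages are
continuous while the bands are printed as integer ranges, the band edges
need a convention; we use grade 0 iff percent ≤ 50, grade 1 iff
50 < percent ≤ 70, grade 2 iff 70 < percent < 100, which preserves the
integer bands and leaves no gap. Occlusion (grade 3) is triggered by the
occlusion flag or by percent = 100, whichever is present; a lesion's extent
is classified by its reach category regardless of grade.

Conventions for the cases the scales do not pin down:

* **IMA beyond ostial.** Only ostial IMA stenosis is scored. A recorded
  proximal/extended IMA reach is capped to extent 1 with a logged warning
  rather than rejected — the input is physically meaningful, the scale
  simply does not distinguish it.
* **No lesion ⇒ no grade.** `reach = none` forces grade 0. The converse is
  *not* required: an ostial 40 % lesion has extent 1 and grade 0. The
  admissible profile set therefore has 13 (CA) × 13 (SMA) × 5 (IMA) = 845
  members.
* **Absent vessels** (anatomic variants) contribute (0, 0) and are flagged
  in the output; `absent_vessel_policy="missing"` excludes such patients
  instead. The morphologic reading (no vessel, no lesion to grade) is the
  default; whether absence should instead count as an occlusion
  hemodynamically is a genuinely open modelling question, so both the flag
  and the exclusion path are kept explicit.
* **Generalized calcification** enters through `percent_override`, the same
  path used whenever diameters are unavailable; there is no separate
  calcification model.

## The score

`CSI = w · (C_extent, C_grade, S_extent, S_grade, I_extent, I_grade)` with
default integer weights (1, 2, 1, 2, 1, 1); the scoring path is exact
integer arithmetic end to end. Over the 845 admissible profiles the default
score spans 0–22 (maximum at full occlusion of all three vessels,
(3,3,3,3,1,3)). Patients are dichotomized at the cut-off (default 8,
"high" iff score ≥ cut-off) and binned into the reporting subgroups 0–3,
4–7, 8–11, 12–15, >15.

## Derivation statistics

**AUC.** The tie-aware rank estimator
`P(score_pos > score_neg) + ½ P(score_pos = score_neg)`, computed from
midranks. Integer scores tie often, so the ½-weighting is not optional;
the test suite checks midrank and brute-force pairwise computation agree to
machine precision.

**Confidence intervals** invert the Brunner–Munzel test: with group sizes
`n₀, n₁`, within-group variances `v₀, v₁` of (overall midrank −
within-group midrank), the standard error of the AUC estimate is
`√(n₀v₀ + n₁v₁)/(n₀n₁)` and the interval uses a Student-t quantile with
Satterthwaite–Welch degrees of freedom, clamped to [0, 1]. No logit or
other transformation of the AUC scale is applied — the interval is the
direct inversion of the test statistic. Degenerate inputs: if every score
is identical the interval is undefined and an error instructs the caller;
if the groups are fully concordant (rank variance zero but AUC 0 or 1, e.g.
perfect separation) the interval degenerates to the point estimate with
`df = NaN`, which is the limit of the construction. Coverage under a
normal shift model (n = 50/50, true AUC 0.75) is verified to sit in the
92–98 % band at nominal 95 %.

**Grid search.** The weight vector is derived by exhaustive evaluation of
the rank AUC over a Cartesian grid of integer coefficients, default
{0,…,3}⁶ = 4,096 candidates (a superset of the published solution at
negligible cost; the grid is configurable, and only the six coefficients —
not the scale encodings — are searched). Evaluation is vectorized: the
n×4,096 score matrix is ranked columnwise. Equal-AUC candidates (within
1e-12) are all reported; the returned maximizer is the tie member with
minimal coefficient sum, then lexicographically smallest, making the search
deterministic and permutation-invariant in patient order.

**Cut-off.** Candidate cut-offs are the distinct observed score values
under the rule "positive iff score ≥ cut-off" (matching a dichotomization
at an attained integer value); the Youden-optimal cut-off maximizes
J = sensitivity + specificity − 1, with J values within 1e-9 of the maximum
treated as tied and the smallest cut-off returned, so rational ties are not
broken by floating-point summation order.

## Validation statistics

**Bootstrap.** Patients are resampled with replacement (score and label
jointly, same n) and the rank AUC recomputed per resample; resamples that
lose a class are skipped and counted. The summary reports mean, minimum,
maximum, the standard deviation and a percentile interval of the resampled
AUCs — the percentile interval is the simplest estimator consistent with a
plain resampling description. A `stratified` switch resamples within class
instead (fixing class sizes); it is off by default because the natural
resampling unit is the patient. Draws flow from one `numpy` generator in
fixed-size chunks, so a given seed is bit-reproducible regardless of
`n_reps`.

**Agreement.** Percent agreement counts exact score equality (rounding
happens only at the presentation layer). Cohen's kappa treats the 0–22
score as nominal categories (unweighted), matching the percent-agreement
framing; the statistic and its asymptotic standard error come from
statsmodels, with the normal-quantile interval assembled here and a
linearly weighted variant available but off by default. Kappa is undefined
when both raters are constant and identical (expected agreement 1).

**Cross-tabs.** 2×2 tables of risk group against a binary attribute report
counts, within-row percentages in the clinical "n (%)" style, and a Pearson
chi-square p-value without continuity correction; Fisher's exact test is
substituted whenever any expected cell count is below 5.

## The cohort simulator

The generator emulates a two-group referral cohort: a CMI mixture component
(prevalence 0.45) and a non-CMI component, each giving a normal latent
severity (locations 0.85 and 0.10, scale 0.35, unitless latent scale).
Each vessel observes severity with independent noise (sd 0.30; the IMA with
a −0.15 offset, as it is less often decisive), thresholds it into reach at
(0.0, 0.55, 1.0), and maps it through a probit curve (mid 0.35, scale 0.45)
to percent stenosis, with occlusion above latent 1.10. Diameters are then
emitted (d_normal uniform 5–9 mm, d_stenosis back-computed), so running the
classification pipeline on the emitted table reproduces the true components
and scores exactly — a closure property the tests exercise.

Labels: the default `logistic` model draws
`Bernoulli(sigmoid(slope · (severity − mid)))` with slope 5.0 and `mid`
solved (Brent root-finding on the drawn severities) so the expected label
prevalence equals the configured one; labels are then genuinely noisy in
the score and AUC < 1, making cut-off estimation a real statistical task.
The `threshold` model labels a patient positive iff the true score reaches
the default cut-off 8 — an oracle mode under which grid search must recover
AUC 1.0 with the default weights among the ties.

Calibration, done once at n = 10,000 and frozen: group score medians
14 (CMI) and 3 (non-CMI) — bracketing the reference cohort's 14 and 4 —
score range 0–22, label prevalence ≈ 0.45, point AUC ≈ 0.87, and the
Youden cut-off concentrated on 8–10 (98 % of 50 seeds inside the 6–10
window at n = 2,000). What the simulator does *not* model: correlated
vessel involvement beyond the shared latent factor, measurement rounding by
human readers, anatomic variants (absent vessels), MALS-type compression,
or any treatment/outcome process. Passing tests therefore show the
machinery is correct and well calibrated on this mechanism, not that the
score's clinical performance would replicate on real patients.

`simulate_raters` models the second examiner by re-reading a Bernoulli
subset of patients differently: one random vessel's grade moves one class
up or down (reflected at the boundaries); a vessel with no lesion instead
gains an ostial sub-50 % lesion so that every perturbation changes the
score and expected agreement ≈ 1 − rate.

## Problem sizes and numerical choices

The statistical suites run at sizes chosen to make the checks sharp while
keeping the full test run quick: oracle equivalence on 1,000 random
instances (n ≤ 30 per class), interval coverage on 2,000 replicates of
n = 50/50, recovery at n = 2,000 over 50 seeds, bootstrap consistency at
10,000 replicates on a 242-patient cohort. Reports serialize
deterministically (sorted keys; statistics at 3 decimals, percentages at
1), and the CLI maps validation failures to exit code 2 and degenerate
statistics to exit code 3.

## Known limitations

* The derivation machinery happily overfits small cohorts: at n ≈ 242 the
  grid search usually finds a weight vector whose in-sample AUC slightly
  exceeds the generating weights' (see the README example). That is a
  property of exhaustive in-sample maximization, and is why the bootstrap
  and (ultimately) external validation matter.
* The kappa interval uses the large-sample standard error; for very small
  n or near-constant tables it is approximate.
* The simulator's latent-factor mechanism is the simplest one producing the
  documented group structure; it is a testbed, not an epidemiological model.
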