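"""Published reference values from the motivating dental-caries cohort study.

The study followed 6007 dental-caries patients at a higher clinic in Hawassa,
Ethiopia, recording whether each patient's caries was *natural* (outcome 1)
or *non-natural* (outcome 0) together with five categorical risk factors.
The raw patient-level data were never deposited; what the study published is

* the covariate-by-outcome cross-tabulation (counts of non-natural and
  natural caries per covariate level), stored here in
  ``CROSSTAB_COUNTS``, and
* the posterior means of a Bayesian logistic regression on those data,
  stored in ``STUDY_COEFFICIENTS`` and used as the default "true"
  coefficients of the synthetic-cohort generator.

These printed numbers are inputs to the analysis, not outputs of this
package.
"""

from __future__ import annotations

#: Per-covariate (level -> (count of outcome 0, count of outcome 1)).
#: Level order is reference level first, matching the dummy coding.
CROSSTAB_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "gender": {"Female": (327, 2501), "Male": (451, 2728)},
    "residence": {"Urban": (434, 3510), "Rural": (344, 1719)},
    "region": {"Others": (595, 4478), "SNNPR": (183, 751)},
    "age_group": {
        "<18": (90, 872),
        "18-25": (295, 1742),
        "26-35": (211, 1392),
        ">=35": (182, 1223),
    },
    "clean_teeth": {"No": (710, 4924), "Yes": (68, 305)},
}

#: Total cohort size (each covariate's level counts sum to this).
N_PATIENTS: int = 6007

#: Count of natural-caries outcomes (y = 1) in the cohort: 5229 of 6007.
N_NATURAL: int = 2501 + 2728

#: Reported posterior-mean coefficients of the Bayesian logistic regression,
#: one per dummy-coded slot.  These are the default generator coefficients.
STUDY_COEFFICIENTS: dict[str, float] = {
    "intercept": 1.726,
    "Male": -0.2038,
    "Rural": -0.3699,
    "SNNPR": 0.4957,
    "18-25": -0.484,
    "26-35": -0.3205,
    ">=35": -0.2887,
    "Yes": 0.389,
}


def marginal_frequencies() -> dict[str, dict[str, float]]:
    """Per-covariate level frequencies implied by the published counts.

    Returns probabilities (level totals divided by 6007), the default
    marginals of the synthetic-cohort generator.
    """
    out: dict[str, dict[str, float]] = {}
    for cov, levels in CROSSTAB_COUNTS.items():
        out[cov] = {
            level: (c0 + c1) / N_PATIENTS for level, (c0, c1) in levels.items()
        }
    return out
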