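"""Bundled published normative models for the battery.

These are the released age + education regression coefficients from the
battery's norming study: a multisite US reference sample of 1063 adults
without HIV.  Each outcome was regressed, on the analysis scale, on age
(years, continuous) and education (five ordered levels coded as four
indicator offsets against the referent "completed high school").  The SE
column is the standard error of the estimate (residual SD) used to scale
residuals into T-scores.
"""

from __future__ import annotations

from .normative import NormativeModel
from .outcomes import OUTCOMES

__all__ = ["load_published_model", "PUBLISHED_N", "PUBLISHED_PREDICTORS"]

PUBLISHED_N = 1063
PUBLISHED_PREDICTORS = ("age", "education")
_N_PARAMS = 6  # intercept + age + 4 education indicators

# outcome -> (intercept, age, less_than_hs, some_college,
#             college_graduate, graduate_school, see)
_COEFFICIENTS = {
    "tmt_a": (-1.066, -0.004, -0.026, 0.065, 0.126, 0.126, 0.187),
    "tmt_b": (-1.474, -0.004, -0.013, 0.075, 0.162, 0.158, 0.14),
    "tmt_b_minus_a": (-19.494, -0.170, -0.026, 3.625, 8.809, 8.645, 13.749),
    "stroop_duration": (0.247, -0.004, -0.010, 0.026, 0.057, 0.056, 0.08),
    "stroop_accuracy": (36.166, -0.155, -0.500, 1.054, 2.686, 2.784, 3.752),
    "vslt": (2.035, -0.045, -0.420, 0.836, 1.403, 1.862, 2.453),
}


def load_published_model() -> dict[str, NormativeModel]:
    """Return the six bundled published normative models.

    The returned mapping is keyed by outcome name; each model carries the
    published intercept, age slope, education offsets, standard error of
    the estimate, reference-sample size and residual degrees of freedom,
    paired with the outcome's transform (see :mod:`bracenorms.outcomes`).
    """
    models: dict[str, NormativeModel] = {}
    for outcome, row in _COEFFICIENTS.items():
        intercept, age, less_hs, some_col, college, grad, see = row
        models[outcome] = NormativeModel(
            outcome=outcome,
            predictors=PUBLISHED_PREDICTORS,
            coefficients={
                "intercept": intercept,
                "age": age,
                "edu:less_than_hs": less_hs,
                "edu:some_college": some_col,
                "edu:college_graduate": college,
                "edu:graduate_school": grad,
            },
            see=see,
            n_reference=PUBLISHED_N,
            df_residual=PUBLISHED_N - _N_PARAMS,
            transform=OUTCOMES[outcome],
        )
    return models
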