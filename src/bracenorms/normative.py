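"""Regression-based normative models and SEE-standardized T-scores.

The normative procedure, per outcome:

1.  map the raw score to the analysis scale (higher = better; see
    :mod:`bracenorms.outcomes`);
2.  in a reference sample, fit ordinary least squares of the analysis-scale
    score on demographics (age in years; education as four indicator
    offsets against the referent "completed high school"; optionally
    biological sex and race/ethnicity);
3.  record the coefficients and the standard error of the estimate
    SEE = sqrt(RSS / (n − p)), the residual-degrees-of-freedom scale of
    the regression;
4.  for any scored individual,

        T = 50 + 10 · (observed − predicted) / SEE,

    so that the reference sample has mean T of exactly 50 (OLS residuals
    with an intercept sum to zero) and sample SD 10·sqrt((n − p)/(n − 1));
5.  classify impairment at T < 40 (≥1 SD below the normative mean) and
    T < 35 (≥1.5 SD below), strict inequalities;
6.  average the four designated test T-scores (TMT-A, TMT-B, Stroop
    duration, VSLT) into a global composite.

T-scores are never truncated or rounded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import ParticipantRecord, participants_to_frame
from .outcomes import (
    COMPOSITE_OUTCOMES,
    EDUCATION_LEVELS,
    EDUCATION_REFERENT,
    OUTCOMES,
    TransformSpec,
    transform_raw,
)

__all__ = [
    "NormativeModel",
    "TScoreSet",
    "fit_norms",
    "tscore",
    "score_cohort",
    "scored_frame",
    "classify_impairment",
    "global_composite",
    "serialize_models",
    "load_models",
    "IMPAIRMENT_CUTOFF_1SD",
    "IMPAIRMENT_CUTOFF_1_5SD",
]

logger = logging.getLogger(__name__)

IMPAIRMENT_CUTOFF_1SD = 40.0
IMPAIRMENT_CUTOFF_1_5SD = 35.0

SCHEMA_VERSION = "bracenorms-normative-1"

#: coefficient-name prefix for each categorical predictor
_CATEGORICAL = {
    "education": ("edu", EDUCATION_REFERENT, EDUCATION_LEVELS),
    "sex": ("sex", "female", ("female", "male")),
    "race_ethnicity": ("race", None, None),  # referent chosen at fit time
}
_KNOWN_PREDICTORS = ("age",) + tuple(_CATEGORICAL)


@dataclass
class NormativeModel:
    """Fitted (or published) normative regression for one outcome.

    Attributes
    ----------
    outcome
        Outcome name.
    predictors
        Ordered predictor set, a subset of
        ``("age", "education", "sex", "race_ethnicity")``.
    coefficients
        Ordered mapping of term name to value; ``"intercept"`` first, then
        ``"age"``, then indicator terms such as ``"edu:some_college"``.
    see
        Standard error of the estimate, sqrt(RSS / df_residual).
    n_reference
        Size of the reference sample the model was fitted in.
    df_residual
        n_reference − number of estimated parameters.
    transform
        The outcome's raw → analysis-scale recipe.
    referents
        Referent level per categorical predictor (carries no coefficient).
    """

    outcome: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    see: float
    n_reference: int
    df_residual: int
    transform: TransformSpec
    referents: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.predictors = tuple(self.predictors)
        for p in self.predictors:
            if p not in _KNOWN_PREDICTORS:
                raise ValueError(f"{self.outcome}: unknown predictor {p!r}")
        if not self.see > 0:
            raise ValueError(f"{self.outcome}: SEE must be positive")
        if self.df_residual < 1:
            raise ValueError(f"{self.outcome}: df_residual must be >= 1")
        if "intercept" not in self.coefficients:
            raise ValueError(f"{self.outcome}: missing intercept")
        for cat, (_, referent, _) in _CATEGORICAL.items():
            if cat in self.predictors and referent is not None:
                self.referents.setdefault(cat, referent)

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def predict(self, record: ParticipantRecord | Mapping[str, object]) -> float:
        """Linear predictor for one participant's demographics."""
        get = (
            record.get
            if isinstance(record, Mapping)
            else lambda k: getattr(record, k)
        )
        eta = self.coefficients["intercept"]
        for p in self.predictors:
            value = get(p)
            if p == "age":
                eta += self.coefficients["age"] * float(value)
                continue
            prefix = _CATEGORICAL[p][0]
            level = str(value)
            if level == self.referents.get(p):
                continue
            term = f"{prefix}:{level}"
            try:
                eta += self.coefficients[term]
            except KeyError:
                raise ValueError(
                    f"{self.outcome}: {p} level {level!r} was not seen by "
                    f"the model (known terms: {sorted(self.coefficients)})"
                ) from None
        return eta


@dataclass
class TScoreSet:
    """Per-participant standardized scores, impairment flags, composite."""

    participant_id: str
    tscores: dict[str, float]
    impaired_1sd: dict[str, bool]
    impaired_1_5sd: dict[str, bool]
    global_t: float | None = None
    global_impaired_1sd: bool | None = None
    global_impaired_1_5sd: bool | None = None


# ---------------------------------------------------------------------------
# fitting


def _design_matrix(
    frame: pd.DataFrame, predictors: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Build the OLS design matrix with explicit term names.

    Returns the matrix (constant first) and the referent level chosen for
    each categorical predictor.
    """
    cols: dict[str, np.ndarray] = {}
    referents: dict[str, str] = {}
    for p in predictors:
        if p == "age":
            cols["age"] = frame["age"].to_numpy(dtype=float)
            continue
        prefix, referent, levels = _CATEGORICAL[p]
        observed = list(pd.unique(frame[p].astype(str)))
        if levels is None:
            # referent = most frequent observed level, for stability
            referent = frame[p].astype(str).value_counts().idxmax()
            levels = sorted(observed)
        referents[p] = referent
        for level in levels:
            if level == referent:
                continue
            indicator = (frame[p].astype(str) == level).to_numpy(dtype=float)
            if level in observed:
                cols[f"{prefix}:{level}"] = indicator
    X = pd.DataFrame(cols, index=frame.index)
    X.insert(0, "intercept", 1.0)
    return X, referents


def fit_norms(
    reference: Sequence[ParticipantRecord] | pd.DataFrame,
    predictors: Sequence[str] = ("age", "education"),
    outcomes: Iterable[str] | None = None,
) -> dict[str, NormativeModel]:
    """Fit normative OLS models in a reference sample, one per outcome.

    Each outcome is fitted independently on the participants for whom it is
    present; the analysis-scale response is regressed on the requested
    predictors.  Raises on singular designs (an education level absent from
    the reference sample, collinear indicators) or when there are no
    residual degrees of freedom.
    """
    frame = (
        reference
        if isinstance(reference, pd.DataFrame)
        else participants_to_frame(reference)
    )
    predictors = tuple(predictors)
    for p in predictors:
        if p not in _KNOWN_PREDICTORS:
            raise ValueError(f"unknown predictor {p!r}")
    if outcomes is None:
        outcomes = [
            c[4:] for c in frame.columns if c.startswith("raw_") and c[4:] in OUTCOMES
        ]

    models: dict[str, NormativeModel] = {}
    for outcome in outcomes:
        col = f"raw_{outcome}"
        if col not in frame.columns:
            raise ValueError(f"reference table has no column {col!r}")
        sub = frame[frame[col].notna()]
        y = np.array([transform_raw(outcome, v) for v in sub[col]])
        X, referents = _design_matrix(sub, predictors)

        p_full = _expected_terms(predictors)
        missing = sorted(set(p_full) - set(X.columns))
        if missing:
            raise ValueError(
                f"{outcome}: singular design, no observations for terms "
                f"{missing}"
            )
        if len(sub) <= X.shape[1]:
            raise ValueError(
                f"{outcome}: {len(sub)} participants cannot identify "
                f"{X.shape[1]} parameters"
            )
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError(
                f"{outcome}: singular design matrix (collinear terms among "
                f"{list(X.columns)})"
            )

        res = sm.OLS(y, X).fit()
        see = float(np.sqrt(res.ssr / res.df_resid))
        models[outcome] = NormativeModel(
            outcome=outcome,
            predictors=predictors,
            coefficients={name: float(res.params[name]) for name in X.columns},
            see=see,
            n_reference=int(len(sub)),
            df_residual=int(res.df_resid),
            transform=OUTCOMES[outcome],
            referents=referents,
        )
    return models


def _expected_terms(predictors: Sequence[str]) -> list[str]:
    terms = ["intercept"]
    for p in predictors:
        if p == "age":
            terms.append("age")
        elif p != "race_ethnicity":  # race levels are data-dependent
            prefix, referent, levels = _CATEGORICAL[p]
            terms += [f"{prefix}:{lv}" for lv in levels if lv != referent]
    return terms


# ---------------------------------------------------------------------------
# scoring


def tscore(
    model: NormativeModel,
    record: ParticipantRecord,
    transform: TransformSpec | None = None,
) -> float | None:
    """SEE-standardized T-score for one participant on one outcome.

    Returns ``None`` when the participant has no raw value for the
    outcome (scored independently per outcome; not an error).
    """
    raw = record.raw_outcomes.get(model.outcome)
    if raw is None:
        return None
    spec = transform if transform is not None else model.transform
    observed = spec.to_analysis(raw)
    predicted = model.predict(record)
    return 50.0 + 10.0 * (observed - predicted) / model.see


def classify_impairment(t: float) -> dict[str, bool]:
    """Impairment flags at the two cutoffs (strict: T of exactly 40 passes)."""
    return {
        "impaired_1sd": t < IMPAIRMENT_CUTOFF_1SD,
        "impaired_1_5sd": t < IMPAIRMENT_CUTOFF_1_5SD,
    }


def global_composite(
    tscores: Mapping[str, float],
    components: Sequence[str] = COMPOSITE_OUTCOMES,
    participant_id: str = "?",
) -> float | None:
    """Unweighted mean of the four designated test T-scores.

    The TMT B−A difference and Stroop accuracy are not components.  Absent
    any component the composite is absent (reason logged), never partial.
    """
    missing = [c for c in components if tscores.get(c) is None]
    if missing:
        logger.info(
            "participant %s: no global composite (missing %s)",
            participant_id,
            ", ".join(missing),
        )
        return None
    return float(np.mean([tscores[c] for c in components]))


def score_cohort(
    participants: Sequence[ParticipantRecord],
    models: Mapping[str, NormativeModel],
) -> list[TScoreSet]:
    """Score every participant on every modeled outcome.

    Missing outcomes yield absent scores; the global composite requires all
    four component T-scores.
    """
    out = []
    for rec in participants:
        ts: dict[str, float] = {}
        for outcome, model in models.items():
            t = tscore(model, rec)
            if t is not None:
                ts[outcome] = t
        flags1 = {o: t < IMPAIRMENT_CUTOFF_1SD for o, t in ts.items()}
        flags15 = {o: t < IMPAIRMENT_CUTOFF_1_5SD for o, t in ts.items()}
        gt = global_composite(ts, participant_id=rec.participant_id)
        out.append(
            TScoreSet(
                participant_id=rec.participant_id,
                tscores=ts,
                impaired_1sd=flags1,
                impaired_1_5sd=flags15,
                global_t=gt,
                global_impaired_1sd=None if gt is None else gt < IMPAIRMENT_CUTOFF_1SD,
                global_impaired_1_5sd=None
                if gt is None
                else gt < IMPAIRMENT_CUTOFF_1_5SD,
            )
        )
    return out


def scored_frame(
    tsets: Sequence[TScoreSet],
    participants: Sequence[ParticipantRecord] | None = None,
) -> pd.DataFrame:
    """Tabulate T-score sets (one row per participant).

    When the participant records are supplied, demographics, covariates,
    raw and transformed scores are carried alongside for downstream
    comparisons and correlation panels.
    """
    rows = []
    by_id = (
        {r.participant_id: r for r in participants} if participants else {}
    )
    for ts in tsets:
        row: dict[str, object] = {"participant_id": ts.participant_id}
        rec = by_id.get(ts.participant_id)
        if rec is not None:
            row.update(
                hiv_status=rec.hiv_status,
                age=rec.age,
                sex=rec.sex,
                education=rec.education,
                race_ethnicity=rec.race_ethnicity,
                site=rec.site,
            )
            for name, value in rec.covariates.items():
                row[f"cov_{name}"] = value
            for name, value in rec.raw_outcomes.items():
                row[f"raw_{name}"] = value
                row[f"analysis_{name}"] = OUTCOMES[name].to_analysis(value)
        for outcome, t in ts.tscores.items():
            row[f"t_{outcome}"] = t
            row[f"imp40_{outcome}"] = ts.impaired_1sd[outcome]
            row[f"imp35_{outcome}"] = ts.impaired_1_5sd[outcome]
        row["t_global"] = ts.global_t
        row["imp40_global"] = ts.global_impaired_1sd
        row["imp35_global"] = ts.global_impaired_1_5sd
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model files (versioned structured text)


def serialize_models(
    models: Mapping[str, NormativeModel], path: str | Path
) -> None:
    """Write a model set to a versioned JSON file at full float precision."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "models": {
            name: {
                "outcome": m.outcome,
                "predictors": list(m.predictors),
                "coefficients": m.coefficients,
                "see": m.see,
                "n_reference": m.n_reference,
                "df_residual": m.df_residual,
                "referents": m.referents,
                "transform": {
                    "unit": m.transform.unit,
                    "transform": m.transform.transform,
                },
            }
            for name, m in models.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


_REQUIRED_FIELDS = (
    "outcome",
    "predictors",
    "coefficients",
    "see",
    "n_reference",
    "df_residual",
    "transform",
)


def load_models(path: str | Path) -> dict[str, NormativeModel]:
    """Load a model set written by :func:`serialize_models`."""
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model-file schema {version!r} "
            f"(expected {SCHEMA_VERSION!r})"
        )
    models: dict[str, NormativeModel] = {}
    for name, entry in payload["models"].items():
        missing = [f for f in _REQUIRED_FIELDS if f not in entry]
        if missing:
            raise ValueError(
                f"model {name!r}: missing required field(s) {missing}"
            )
        tr = entry["transform"]
        models[name] = NormativeModel(
            outcome=entry["outcome"],
            predictors=tuple(entry["predictors"]),
            coefficients=dict(entry["coefficients"]),
            see=float(entry["see"]),
            n_reference=int(entry["n_reference"]),
            df_residual=int(entry["df_residual"]),
            transform=TransformSpec(entry["outcome"], tr["unit"], tr["transform"]),
            referents=dict(entry.get("referents", {})),
        )
    return models
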