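"""Synthetic multisite cohort generator.

Emulates the statistical structure the normative pipeline assumes, so
every downstream stage (QC, fitting, scoring, group comparison) is
testable without access-controlled cohort data:

* demographics drawn to match the development cohort's reference group —
  age normal(56.95, 12.34) truncated to [18, 95], a five-level education
  mix, 47% women, and the published race/site margins sampled
  independently;
* analysis-scale outcomes generated from the bundled published linear
  models, ``y = intercept + β_age·age + β_edu(level) + ε``, with the
  residual vector multivariate normal: per-outcome SD equal to each
  model's SEE, common pairwise correlation ρ (default 0.30, calibrated so
  the 4-test composite T-score SD comes out near the printed 6.9);
* raw outcomes recovered by inverting each outcome's transform
  (``time_ms = 1000·10^(−y)``); the TMT B−A raw difference is derived
  from the two simulated completion times, matching how it is derived
  from real trial data;
* optional additive covariate effects on the analysis scale, off by
  default (covariates are otherwise independent of cognition);
* per-trial records whose aggregates reproduce each participant's raw
  outcomes (continuous aggregates exactly; counts to the nearest
  representable integer).

Randomness uses one master seed with per-participant substreams derived
by counter, so any subset of participants is reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import ParticipantRecord
from .normative import NormativeModel
from .outcomes import EDUCATION_LEVELS, MEASURED_OUTCOMES, OUTCOMES
from .published import load_published_model
from .qc import TrialRecord

__all__ = ["CohortSpec", "TrialConfig", "generate_cohort", "generate_trial_data"]

logger = logging.getLogger(__name__)

#: development-cohort reference-group education mix (n=1063):
#: 152 / 201 / 307 / 142 / 258
_EDU_COUNTS = (152, 201, 307, 142, 258)
DEFAULT_EDUCATION_PROBS = tuple(c / sum(_EDU_COUNTS) for c in _EDU_COUNTS)

DEFAULT_RACE_PROBS = {
    "black_african_american": 0.44,
    "hispanic_latinx": 0.11,
    "other": 0.45,
}

# reference-group site margin (counts out of 1063)
_SITE_COUNTS = {
    "bronx": 94, "brooklyn": 78, "washington_dc": 53, "san_francisco": 92,
    "chicago_cook_county": 48, "chapel_hill": 54, "atlanta": 91, "miami": 67,
    "birmingham": 36, "jackson": 43, "baltimore": 117,
    "chicago_northwestern": 85, "pittsburgh_ohio": 93, "los_angeles": 112,
}
DEFAULT_SITE_PROBS = {k: v / 1063 for k, v in _SITE_COUNTS.items()}

DEFAULT_COVARIATE_PREVALENCES = {
    "diabetes": 0.18,
    "hypertension": 0.68,
    "current_smoker": 0.26,
    "heavy_alcohol_use": 0.12,
    "recent_cannabis_use": 0.10,
}


#: lowest Stroop accurate-trial count that passes QC (rule is "> 15")
STROOP_QC_FLOOR = 16.0


def _default_models() -> dict[str, NormativeModel]:
    published = load_published_model()
    return {o: published[o] for o in MEASURED_OUTCOMES}


@dataclass
class TrialConfig:
    """Trial-level emission parameters (trial counts are instrument
    configuration the norming study does not publish; these are realistic
    fixed choices)."""

    stroop_trials: int = 45
    tmt_a_segments: int = 24
    tmt_b_segments: int = 24
    vslt_items: int = 24
    tmt_error_mean: float = 1.0
    qc_fail_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.qc_fail_rate <= 1:
            raise ValueError("qc_fail_rate must lie in [0, 1]")
        for name in ("stroop_trials", "tmt_a_segments", "tmt_b_segments",
                     "vslt_items"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class CohortSpec:
    """Generative specification for a synthetic cohort.

    Outcomes listed in ``coefficient_table`` (default: the five directly
    measured outcomes under their published age+education models) are
    simulated on the analysis scale with residual SDs ``residual_sd``
    (default: each model's SEE) and common residual correlation
    ``residual_corr``.
    """

    n_reference: int = 1063
    n_target: int = 1874
    age_mean: float = 56.95
    age_sd: float = 12.34
    age_bounds: tuple[float, float] = (18.0, 95.0)
    education_probs: Sequence[float] = DEFAULT_EDUCATION_PROBS
    sex_prob: float = 499 / 1063  # probability female
    race_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RACE_PROBS)
    )
    site_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_PROBS)
    )
    coefficient_table: dict[str, NormativeModel] = field(
        default_factory=_default_models
    )
    residual_sd: dict[str, float] | None = None
    residual_corr: float = 0.30
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES)
    )
    #: covariate -> outcome -> additive shift on the analysis scale
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    trial_config: TrialConfig = field(default_factory=TrialConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reference < 0 or self.n_target < 0:
            raise ValueError("cohort sizes must be non-negative")
        if len(self.education_probs) != len(EDUCATION_LEVELS):
            raise ValueError(
                f"education_probs needs {len(EDUCATION_LEVELS)} entries"
            )
        if any(p < 0 for p in self.education_probs):
            raise ValueError("education_probs must be non-negative")
        if abs(math.fsum(self.education_probs) - 1.0) > 1e-12:
            raise ValueError("education_probs must sum to 1 (within 1e-12)")
        if max(self.education_probs) == 1.0:
            logger.warning(
                "degenerate education distribution (a single level has "
                "probability 1); normative fits will drop absent levels"
            )
        if not 0 <= self.sex_prob <= 1:
            raise ValueError("sex_prob must lie in [0, 1]")
        if not self.age_sd > 0:
            raise ValueError("age_sd must be positive")
        if self.residual_sd is None:
            self.residual_sd = {
                o: m.see for o, m in self.coefficient_table.items()
            }
        missing = set(self.coefficient_table) - set(self.residual_sd)
        if missing:
            raise ValueError(f"residual_sd missing outcomes: {sorted(missing)}")
        if any(sd < 0 for sd in self.residual_sd.values()):
            raise ValueError("residual_sd must be non-negative")
        k = len(self.coefficient_table)
        rho = self.residual_corr
        if k > 1 and not (-1.0 / (k - 1) < rho < 1.0):
            raise ValueError(
                f"residual correlation {rho} gives a non-positive-definite "
                f"{k}x{k} equicorrelation matrix; need "
                f"-1/{k - 1} < rho < 1"
            )

    @property
    def outcomes(self) -> tuple[str, ...]:
        return tuple(self.coefficient_table)


def _residual_chol(spec: CohortSpec) -> np.ndarray:
    k = len(spec.coefficient_table)
    corr = np.full((k, k), spec.residual_corr)
    np.fill_diagonal(corr, 1.0)
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError(
            "residual correlation matrix is not positive definite"
        ) from None


def _participant_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    # counter-based substream: subsetting participants stays reproducible
    return np.random.default_rng([seed, index, stream])


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed")


def generate_cohort(spec: CohortSpec) -> list[ParticipantRecord]:
    """Draw ``n_reference + n_target`` participants from the spec.

    Deterministic given ``spec.seed``; participant ``i`` (0-based, reference
    group first) is generated from substream ``[seed, i]``.
    """
    chol = _residual_chol(spec)
    sds = np.array([spec.residual_sd[o] for o in spec.outcomes])
    edu_cdf = np.cumsum(np.asarray(spec.education_probs, dtype=float))
    race_names = list(spec.race_probs)
    race_p = np.array([spec.race_probs[r] for r in race_names], dtype=float)
    race_cdf = np.cumsum(race_p / race_p.sum())
    site_names = list(spec.site_probs)
    site_p = np.array([spec.site_probs[s] for s in site_names], dtype=float)
    site_cdf = np.cumsum(site_p / site_p.sum())

    def _pick(cdf: np.ndarray, u: float) -> int:
        return min(int(np.searchsorted(cdf, u, side="right")), len(cdf) - 1)

    records: list[ParticipantRecord] = []
    n_total = spec.n_reference + spec.n_target
    for i in range(n_total):
        rng = _participant_rng(spec.seed, i)
        hiv = "without_hiv" if i < spec.n_reference else "with_hiv"
        age = _truncated_normal(
            rng, spec.age_mean, spec.age_sd, *spec.age_bounds
        )
        sex = "female" if rng.random() < spec.sex_prob else "male"
        education = EDUCATION_LEVELS[_pick(edu_cdf, rng.random())]
        race = race_names[_pick(race_cdf, rng.random())]
        site = site_names[_pick(site_cdf, rng.random())]
        covariates = {
            name: float(rng.random() < prev)
            for name, prev in spec.covariate_prevalences.items()
        }

        eps = sds * (chol @ rng.standard_normal(len(spec.outcomes)))
        demo = {"age": age, "education": education, "sex": sex,
                "race_ethnicity": race}
        raw: dict[str, float] = {}
        for j, outcome in enumerate(spec.outcomes):
            y = spec.coefficient_table[outcome].predict(demo) + eps[j]
            for cov, effects in spec.covariate_effects.items():
                if outcome in effects:
                    y += effects[outcome] * covariates.get(cov, 0.0)
            raw[outcome] = OUTCOMES[outcome].from_analysis(y)
        if "stroop_accuracy" in raw:
            # the reference models describe the QC-passing population; floor
            # the accuracy count at the lowest passing value so the Gaussian
            # tail cannot imply task disengagement
            raw["stroop_accuracy"] = max(raw["stroop_accuracy"],
                                         STROOP_QC_FLOOR)
        if "tmt_a" in raw and "tmt_b" in raw:
            raw["tmt_b_minus_a"] = raw["tmt_b"] - raw["tmt_a"]

        records.append(
            ParticipantRecord(
                participant_id=f"P{i:06d}",
                age=age,
                sex=sex,
                education=education,
                race_ethnicity=race,
                site=site,
                hiv_status=hiv,
                covariates=covariates,
                raw_outcomes=raw,
            )
        )
    return records


# ---------------------------------------------------------------------------
# trial emission


def _participant_index(participant_id: str) -> int:
    digits = "".join(ch for ch in participant_id if ch.isdigit())
    return int(digits) if digits else 0


def _positive_times(
    rng: np.random.Generator, n: int, mean: float
) -> np.ndarray:
    """n positive times with mean exactly ``mean`` (lognormal shape,
    rescaled)."""
    t = rng.lognormal(mean=0.0, sigma=0.35, size=n)
    return t * (mean / t.mean())


def generate_trial_data(
    record: ParticipantRecord,
    spec: CohortSpec,
    config: TrialConfig | None = None,
) -> list[TrialRecord]:
    """Emit per-trial rows whose aggregates reproduce the record's raw
    outcomes.

    TMT completion times are split over Dirichlet-weighted segments that
    sum to the recorded total; Stroop trial times are rescaled to match
    the recorded per-trial mean exactly; count outcomes (Stroop accuracy,
    VSLT placement score) are reproduced at their nearest representable
    integer.  With ``qc_fail_rate`` > 0, a participant-level coin flips
    each QC'd test into a failing configuration (counts then deliberately
    break from the record).
    """
    cfg = config if config is not None else spec.trial_config
    rng = _participant_rng(spec.seed, _participant_index(record.participant_id),
                          stream=1)
    pid = record.participant_id
    raw = record.raw_outcomes
    trials: list[TrialRecord] = []

    for test, n_seg, err_limit in (
        ("tmt_a", cfg.tmt_a_segments, 5),
        ("tmt_b", cfg.tmt_b_segments, 10),
    ):
        total = raw.get(test)
        if total is None:
            continue
        if not total > 0:
            raise ValueError(f"{pid}/{test}: completion time must be positive")
        weights = rng.dirichlet(np.full(n_seg, 5.0))
        times = weights * total
        times *= total / math.fsum(times)  # exact sum under fsum
        idx = 0
        for t in times:
            trials.append(TrialRecord(pid, test, idx, float(t), None, False))
            idx += 1
        if rng.uniform() < cfg.qc_fail_rate:
            n_err = err_limit + int(rng.integers(0, 3))
        else:
            n_err = min(int(rng.poisson(cfg.tmt_error_mean)), err_limit - 1)
        for _ in range(n_err):
            trials.append(TrialRecord(pid, test, idx, None, None, True))
            idx += 1

    if "stroop_duration" in raw or "stroop_accuracy" in raw:
        n = cfg.stroop_trials
        acc_raw = raw.get("stroop_accuracy")
        if acc_raw is None:
            acc = n
        else:
            acc = int(round(acc_raw))
            if not 0 <= acc <= n:
                raise ValueError(
                    f"{pid}/stroop_accuracy: count {acc_raw!r} is not "
                    f"representable with {n} trials"
                )
        if rng.uniform() < cfg.qc_fail_rate:
            acc = int(rng.integers(0, 16))  # at most 15 accurate -> QC fail
        mean_rt = raw.get("stroop_duration")
        if mean_rt is not None and not mean_rt > 0:
            raise ValueError(f"{pid}/stroop_duration: mean time must be positive")
        times = (
            _positive_times(rng, n, mean_rt)
            if mean_rt is not None
            else np.full(n, np.nan)
        )
        correct = np.zeros(n, dtype=bool)
        correct[rng.permutation(n)[:acc]] = True
        for i in range(n):
            trials.append(
                TrialRecord(
                    pid, "stroop", i,
                    None if math.isnan(times[i]) else float(times[i]),
                    bool(correct[i]), None,
                )
            )

    if "vslt" in raw:
        n_items = cfg.vslt_items
        r = int(round(raw["vslt"]))
        if abs(r) > n_items:
            raise ValueError(
                f"{pid}/vslt: score {raw['vslt']!r} is not representable "
                f"with {n_items} items"
            )
        n_incorrect = (n_items - r) // 2
        n_correct = n_incorrect + r
        idx = 0
        for _ in range(n_correct):
            trials.append(TrialRecord(pid, "vslt", idx, None, True, None))
            idx += 1
        for _ in range(n_incorrect):
            trials.append(TrialRecord(pid, "vslt", idx, None, False, None))
            idx += 1

    return trials
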