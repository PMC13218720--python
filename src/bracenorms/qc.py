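"""Trial-level quality control and raw-outcome derivation.

A participant's battery run is a set of trial rows (taps, Stroop trials,
item placements).  QC verifies the participant interacted with each task
as intended, using count-based rules only:

* Stroop passes iff strictly more than 15 trials were answered accurately;
* TMT-A passes iff strictly fewer than 5 touch errors were made;
* TMT-B passes iff strictly fewer than 10 touch errors were made;
* VSLT has no QC rule and always passes when administered.

A test with no trials at all is "not administered" — a distinct state from
a QC failure.  Raw outcomes are derived only for passing tests:

* TMT-A / TMT-B: total time to completion (ms), the sum of segment times;
* TMT B−A: the difference of the two completion times (may be negative);
* Stroop: mean response time per trial (ms) and the accurate-trial count;
* VSLT: correctly placed minus incorrectly placed items (may be negative).

Implausibly long trial times are logged as warnings, never excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TrialRecord",
    "QCThresholds",
    "QCResult",
    "apply_qc",
    "derive_raw_outcomes",
    "complete_pass_ids",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials",
    "read_trials",
    "write_qc_report",
]

logger = logging.getLogger(__name__)

TESTS = ("tmt_a", "tmt_b", "stroop", "vslt")

#: trial time above which a warning (only) is logged
IMPLAUSIBLE_TRIAL_MS = 300_000.0


@dataclass(frozen=True)
class TrialRecord:
    """One trial row: a TMT segment or touch error, a Stroop trial, or a
    VSLT placement."""

    participant_id: str
    test: str
    trial_index: int
    response_time_ms: float | None = None
    correct: bool | None = None
    error: bool | None = None

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise ValueError(f"unknown test {self.test!r}")
        if self.response_time_ms is not None and not self.response_time_ms > 0:
            raise ValueError(
                f"{self.participant_id}/{self.test}: response time must be "
                f"positive, got {self.response_time_ms!r}"
            )


@dataclass(frozen=True)
class QCThresholds:
    """Strict-inequality QC rule thresholds."""

    stroop_min_accurate: int = 15  # pass iff count > this
    tmt_a_max_errors: int = 5      # pass iff errors < this
    tmt_b_max_errors: int = 10     # pass iff errors < this


@dataclass
class QCResult:
    """Per-participant QC outcome and derived raw scores."""

    participant_id: str
    passed: dict[str, bool]            # per administered test
    administered: dict[str, bool]      # per battery test
    reasons: list[str] = field(default_factory=list)
    raw_outcomes: dict[str, float] = field(default_factory=dict)

    @property
    def complete_pass(self) -> bool:
        """True iff every battery test was administered and passed QC."""
        return all(self.administered.get(t, False) for t in TESTS) and all(
            self.passed.get(t, False) for t in TESTS
        )


def _group_trials(
    trials: Iterable[TrialRecord],
) -> dict[str, dict[str, list[TrialRecord]]]:
    grouped: dict[str, dict[str, list[TrialRecord]]] = {}
    for t in trials:
        grouped.setdefault(t.participant_id, {}).setdefault(t.test, []).append(t)
    return grouped


def _qc_one(
    by_test: Mapping[str, Sequence[TrialRecord]],
    participant_id: str,
    thresholds: QCThresholds,
) -> QCResult:
    passed: dict[str, bool] = {}
    administered = {t: t in by_test and len(by_test[t]) > 0 for t in TESTS}
    reasons: list[str] = []

    counts: dict[str, int] = {}
    for test in TESTS:
        if not administered[test]:
            reasons.append(f"{test}:not_administered")
            continue
        rows = by_test[test]
        if test == "stroop":
            counts["stroop_accurate"] = sum(1 for r in rows if r.correct)
            ok = counts["stroop_accurate"] > thresholds.stroop_min_accurate
            if not ok:
                reasons.append("stroop:too_few_accurate_trials")
        elif test in ("tmt_a", "tmt_b"):
            counts[f"{test}_errors"] = sum(1 for r in rows if r.error)
            limit = (
                thresholds.tmt_a_max_errors
                if test == "tmt_a"
                else thresholds.tmt_b_max_errors
            )
            ok = counts[f"{test}_errors"] < limit
            if not ok:
                reasons.append(f"{test}:too_many_errors")
        else:  # vslt: no stated rule
            ok = True
        passed[test] = ok
        for r in rows:
            if (
                r.response_time_ms is not None
                and r.response_time_ms > IMPLAUSIBLE_TRIAL_MS
            ):
                logger.warning(
                    "%s/%s trial %d: implausibly long trial time %.0f ms "
                    "(retained)",
                    participant_id,
                    test,
                    r.trial_index,
                    r.response_time_ms,
                )

    result = QCResult(
        participant_id=participant_id,
        passed=passed,
        administered=administered,
        reasons=reasons,
    )
    result.raw_outcomes = derive_raw_outcomes(
        by_test, passed, participant_id=participant_id
    )
    return result


def apply_qc(
    trials: Iterable[TrialRecord] | pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> dict[str, QCResult]:
    """Apply the QC rules per participant and derive raw outcomes.

    Decisions depend only on trial counts, never on response times.
    Returns a mapping participant_id → :class:`QCResult`.
    """
    if isinstance(trials, pd.DataFrame):
        trials = frame_to_trials(trials)
    grouped = _group_trials(trials)
    return {
        pid: _qc_one(by_test, pid, thresholds)
        for pid, by_test in grouped.items()
    }


def derive_raw_outcomes(
    by_test: Mapping[str, Sequence[TrialRecord]],
    passed: Mapping[str, bool] | None = None,
    participant_id: str = "?",
) -> dict[str, float]:
    """Aggregate trial rows into the raw outcome scores.

    Only QC-passing tests contribute (``passed`` defaults to everything
    administered).  The TMT difference requires both completion times; when
    a prerequisite is missing the outcome is simply absent (reason logged).
    Aggregation is invariant to trial order.
    """
    if passed is None:
        passed = {t: True for t in by_test}
    out: dict[str, float] = {}

    for test in ("tmt_a", "tmt_b"):
        if passed.get(test) and test in by_test:
            times = [
                r.response_time_ms
                for r in by_test[test]
                if r.response_time_ms is not None
            ]
            out[test] = math.fsum(times)

    if "tmt_a" in out and "tmt_b" in out:
        out["tmt_b_minus_a"] = out["tmt_b"] - out["tmt_a"]
    elif "tmt_a" in out or "tmt_b" in out:
        logger.info(
            "participant %s: tmt_b_minus_a not derivable "
            "(needs both completion times)",
            participant_id,
        )

    if passed.get("stroop") and "stroop" in by_test:
        rows = by_test["stroop"]
        times = [
            r.response_time_ms for r in rows if r.response_time_ms is not None
        ]
        if times:
            out["stroop_duration"] = math.fsum(times) / len(times)
        out["stroop_accuracy"] = float(sum(1 for r in rows if r.correct))

    if passed.get("vslt") and "vslt" in by_test:
        rows = by_test["vslt"]
        correct = sum(1 for r in rows if r.correct)
        incorrect = sum(1 for r in rows if r.correct is False)
        out["vslt"] = float(correct - incorrect)

    return out


def complete_pass_ids(results: Mapping[str, QCResult]) -> list[str]:
    """Participants passing QC on the full battery (the reference-sample
    eligibility filter)."""
    return [pid for pid, r in results.items() if r.complete_pass]


# ---------------------------------------------------------------------------
# trial-table dialect (CSV: participant_id, test, trial_index,
# response_time_ms, correct, error)


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": t.participant_id,
                "test": t.test,
                "trial_index": t.trial_index,
                "response_time_ms": t.response_time_ms,
                "correct": t.correct,
                "error": t.error,
            }
            for t in trials
        ]
    )


def frame_to_trials(frame: pd.DataFrame) -> list[TrialRecord]:
    def _flag(v: object) -> bool | None:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        if isinstance(v, str):
            return v.strip().lower() in ("true", "1", "yes")
        return bool(v)

    records = []
    for _, row in frame.iterrows():
        rt = row.get("response_time_ms")
        records.append(
            TrialRecord(
                participant_id=str(row["participant_id"]),
                test=str(row["test"]),
                trial_index=int(row["trial_index"]),
                response_time_ms=None if pd.isna(rt) else float(rt),
                correct=_flag(row.get("correct")),
                error=_flag(row.get("error")),
            )
        )
    return records


def write_trials(
    trials: Iterable[TrialRecord] | pd.DataFrame, path: str | Path
) -> None:
    frame = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    frame.to_csv(path, index=False)


def read_trials(path: str | Path) -> list[TrialRecord]:
    return frame_to_trials(pd.read_csv(path))


def write_qc_report(results: Mapping[str, QCResult], path: str | Path) -> None:
    """One row per participant × test: pass state and derived outcomes."""
    rows = []
    for pid in sorted(results):
        r = results[pid]
        for test in TESTS:
            state = (
                "not_administered"
                if not r.administered.get(test, False)
                else ("pass" if r.passed.get(test) else "fail")
            )
            rows.append(
                {
                    "participant_id": pid,
                    "test": test,
                    "qc_state": state,
                    "reasons": ";".join(
                        x for x in r.reasons if x.startswith(test)
                    ),
                    "complete_pass": r.complete_pass,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
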