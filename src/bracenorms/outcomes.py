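"""Outcome definitions and raw-to-analysis-scale transforms.

The battery yields six outcomes: Trail Making Test A and B time to
completion, their difference (B − A, the set-shifting cost), Stroop-Color
mean per-trial response time, Stroop-Color accurate-trial count, and the
Visual Spatial Learning Test placement score (correct − incorrect).

Raw timed outcomes are recorded in milliseconds, where lower is faster
(better).  For normative modeling every outcome is mapped to an *analysis
scale* on which higher values uniformly mean better performance:

* timed completion / per-trial times: convert ms → s, take −log10,
* the TMT B−A difference: convert ms → s, negate,
* counts (Stroop accuracy, VSLT): identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TransformSpec",
    "OUTCOMES",
    "TIMED_OUTCOMES",
    "MEASURED_OUTCOMES",
    "COMPOSITE_OUTCOMES",
    "EDUCATION_LEVELS",
    "EDUCATION_REFERENT",
]

#: Ordered education levels; coded as indicator offsets against the referent.
EDUCATION_LEVELS = (
    "less_than_hs",
    "completed_hs",
    "some_college",
    "college_graduate",
    "graduate_school",
)
EDUCATION_REFERENT = "completed_hs"

MS_PER_SECOND = 1000.0


@dataclass(frozen=True)
class TransformSpec:
    """Recipe mapping a raw outcome to the analysis scale (higher = better).

    Parameters
    ----------
    outcome
        Outcome identifier, e.g. ``"tmt_a"``.
    unit
        ``"ms"`` for millisecond-valued raw scores (converted to seconds
        before the transform) or ``"count"`` (used as-is).
    transform
        ``"neg_log10"``, ``"negate"`` or ``"identity"``.
    """

    outcome: str
    unit: str
    transform: str

    def __post_init__(self) -> None:
        if self.unit not in ("ms", "count"):
            raise ValueError(f"unknown unit {self.unit!r} for {self.outcome}")
        if self.transform not in ("neg_log10", "negate", "identity"):
            raise ValueError(
                f"unknown transform {self.transform!r} for {self.outcome}"
            )

    def to_analysis(self, raw: float) -> float:
        """Map a raw-scale value to the analysis scale."""
        x = raw / MS_PER_SECOND if self.unit == "ms" else float(raw)
        if self.transform == "neg_log10":
            if x <= 0:
                raise ValueError(
                    f"{self.outcome}: non-positive timed value {raw!r} "
                    "cannot be log-transformed"
                )
            return -math.log10(x)
        if self.transform == "negate":
            return -x
        return x

    def from_analysis(self, value: float) -> float:
        """Invert :meth:`to_analysis`, returning a raw-scale value."""
        if self.transform == "neg_log10":
            x = 10.0 ** (-value)
        elif self.transform == "negate":
            x = -value
        else:
            x = float(value)
        return x * MS_PER_SECOND if self.unit == "ms" else x


#: Transform registry for all six outcomes.
OUTCOMES: dict[str, TransformSpec] = {
    "tmt_a": TransformSpec("tmt_a", "ms", "neg_log10"),
    "tmt_b": TransformSpec("tmt_b", "ms", "neg_log10"),
    "tmt_b_minus_a": TransformSpec("tmt_b_minus_a", "ms", "negate"),
    "stroop_duration": TransformSpec("stroop_duration", "ms", "neg_log10"),
    "stroop_accuracy": TransformSpec("stroop_accuracy", "count", "identity"),
    "vslt": TransformSpec("vslt", "count", "identity"),
}

#: Outcomes on the millisecond scale.
TIMED_OUTCOMES = ("tmt_a", "tmt_b", "tmt_b_minus_a", "stroop_duration")

#: Outcomes measured directly from trials (the B−A difference is derived).
MEASURED_OUTCOMES = (
    "tmt_a",
    "tmt_b",
    "stroop_duration",
    "stroop_accuracy",
    "vslt",
)

#: The four tests averaged into the global composite T-score.
COMPOSITE_OUTCOMES = ("tmt_a", "tmt_b", "stroop_duration", "vslt")


def transform_raw(outcome: str, raw: float) -> float:
    """Transform a raw outcome value to the analysis scale.

    Convenience wrapper around the registry: timed outcomes become
    −log10(seconds) (or −seconds for the TMT difference); counts pass
    through unchanged.
    """
    try:
        spec = OUTCOMES[outcome]
    except KeyError:
        raise KeyError(f"unknown outcome {outcome!r}") from None
    return spec.to_analysis(raw)
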