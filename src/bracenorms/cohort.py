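"""Participant-level data containers and the delimited-text table dialect.

A cohort is a list of :class:`ParticipantRecord` or, equivalently, a wide
pandas DataFrame with one row per participant:

==================  =====================================================
column              meaning
==================  =====================================================
participant_id      opaque string identifier
hiv_status          ``"with_hiv"`` / ``"without_hiv"``
age                 years
sex                 ``"female"`` / ``"male"``
education           one of the five ordered levels
race_ethnicity      categorical label
site                clinical-site label
cov_<name>          one column per covariate (binary 0/1 or continuous)
raw_<outcome>       raw-scale outcome value (times in ms, counts as-is)
==================  =====================================================

Tables are written as UTF-8 comma-separated text with a header row and
"." decimal, the dialect every pipeline stage reads and writes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .outcomes import EDUCATION_LEVELS

__all__ = [
    "ParticipantRecord",
    "participants_to_frame",
    "frame_to_participants",
    "write_participants",
    "read_participants",
]

_DEMOGRAPHICS = (
    "participant_id",
    "hiv_status",
    "age",
    "sex",
    "education",
    "race_ethnicity",
    "site",
)


@dataclass
class ParticipantRecord:
    """One participant: demographics, serostatus, covariates, raw outcomes."""

    participant_id: str
    age: float
    sex: str
    education: str
    race_ethnicity: str = "unspecified"
    site: str = "unspecified"
    hiv_status: str = "without_hiv"
    covariates: dict[str, float] = field(default_factory=dict)
    raw_outcomes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(
                f"participant {self.participant_id}: age must be positive, "
                f"got {self.age!r}"
            )
        if self.education not in EDUCATION_LEVELS:
            raise ValueError(
                f"participant {self.participant_id}: unknown education "
                f"level {self.education!r}; expected one of {EDUCATION_LEVELS}"
            )
        if self.sex not in ("female", "male"):
            raise ValueError(
                f"participant {self.participant_id}: sex must be 'female' "
                f"or 'male', got {self.sex!r}"
            )


def participants_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Flatten records into the wide table dialect."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "participant_id": r.participant_id,
            "hiv_status": r.hiv_status,
            "age": r.age,
            "sex": r.sex,
            "education": r.education,
            "race_ethnicity": r.race_ethnicity,
            "site": r.site,
        }
        for name, value in r.covariates.items():
            row[f"cov_{name}"] = value
        for name, value in r.raw_outcomes.items():
            row[f"raw_{name}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_participants(frame: pd.DataFrame) -> list[ParticipantRecord]:
    """Inverse of :func:`participants_to_frame`."""
    missing = [c for c in _DEMOGRAPHICS if c not in frame.columns]
    if missing:
        raise ValueError(f"participant table is missing columns: {missing}")
    cov_cols = [c for c in frame.columns if c.startswith("cov_")]
    raw_cols = [c for c in frame.columns if c.startswith("raw_")]
    records = []
    for _, row in frame.iterrows():
        covariates = {
            c[4:]: float(row[c]) for c in cov_cols if pd.notna(row[c])
        }
        raw = {c[4:]: float(row[c]) for c in raw_cols if pd.notna(row[c])}
        records.append(
            ParticipantRecord(
                participant_id=str(row["participant_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                education=str(row["education"]),
                race_ethnicity=str(row["race_ethnicity"]),
                site=str(row["site"]),
                hiv_status=str(row["hiv_status"]),
                covariates=covariates,
                raw_outcomes=raw,
            )
        )
    return records


def write_participants(
    records: Sequence[ParticipantRecord] | pd.DataFrame, path: str | Path
) -> None:
    frame = (
        records
        if isinstance(records, pd.DataFrame)
        else participants_to_frame(records)
    )
    frame.to_csv(path, index=False)


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    return frame_to_participants(pd.read_csv(path))
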