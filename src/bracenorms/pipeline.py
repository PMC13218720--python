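"""End-to-end pipeline: simulate → QC → fit → score → compare.

Every run is driven by a :class:`PipelineConfig`, executes only the
enabled stages, and writes a manifest (JSON) listing each produced file
with its row count and SHA-256 checksum plus the fully resolved
configuration, so a run is self-describing and a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .cohort import ParticipantRecord, read_participants, write_participants
from .groupstats import compare_continuous, impairment_rate_table
from .normative import fit_norms, score_cohort, scored_frame, serialize_models
from .outcomes import OUTCOMES
from .qc import (
    apply_qc,
    trials_to_frame,
    write_qc_report,
)
from .simulate import CohortSpec, generate_cohort, generate_trial_data

__all__ = ["PipelineConfig", "run_pipeline", "compare_outcomes"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "fit", "score", "compare")


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    out_dir: str | Path = "bracenorms-run"
    stages: Sequence[str] = ALL_STAGES
    cohort: CohortSpec = field(default_factory=CohortSpec)
    predictors: Sequence[str] = ("age", "education")
    cutoffs: Sequence[float] = (40.0, 35.0)
    compare_by: str = "hiv_status"
    stratify: str | None = None
    emit_trials: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        cohort_overrides = data.pop("cohort", {})
        cfg = cls(**data)
        if cohort_overrides:
            cfg.cohort = dataclasses.replace(cfg.cohort, **cohort_overrides)
        return cfg

    def to_dict(self) -> dict:
        cohort = {
            k: v
            for k, v in dataclasses.asdict(self.cohort).items()
            if k not in ("coefficient_table",)
        }
        cohort["coefficient_outcomes"] = list(self.cohort.coefficient_table)
        return {
            "out_dir": str(self.out_dir),
            "stages": list(self.stages),
            "predictors": list(self.predictors),
            "cutoffs": list(self.cutoffs),
            "compare_by": self.compare_by,
            "stratify": self.stratify,
            "emit_trials": self.emit_trials,
            "cohort": cohort,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _register(manifest: dict, path: Path, rows: int) -> None:
    manifest["files"][path.name] = {"rows": rows, "sha256": _sha256(path)}


def compare_outcomes(
    scored: pd.DataFrame,
    by: str = "hiv_status",
    cutoffs: Sequence[float] = (40.0, 35.0),
    strata: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Group contrasts for every raw and T-score column in a scored table.

    Continuous contrasts use the pooled t test with |Cohen's d| (two
    groups) or ANOVA with η²; impairment rates at each cutoff get the
    categorical contrast.  Mirrors the structure of a serostatus
    comparison table.
    """
    rows = []
    levels = sorted(scored[by].dropna().unique())
    value_cols = [
        c
        for c in scored.columns
        if c.startswith(("raw_", "t_")) and scored[c].notna().any()
    ]
    for col in value_cols:
        groups = {
            str(lv): scored.loc[scored[by] == lv, col].dropna().to_numpy()
            for lv in levels
        }
        groups = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:
            continue
        method = "t_test" if len(groups) == 2 else "anova"
        res = compare_continuous(groups, method=method, variable=col,
                                 strata=strata)
        row = {
            "variable": col,
            "kind": "continuous",
            "test": res.test,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "effect_size": res.effect_size,
            "effect_size_name": res.effect_size_name,
        }
        for g, s in res.summaries.items():
            row[f"n_{g}"] = s["n"]
            row[f"mean_{g}"] = s["mean"]
            row[f"sd_{g}"] = s["sd"]
        rows.append(row)

        if col.startswith("t_"):
            rates = impairment_rate_table(groups, cutoffs=cutoffs,
                                          variable=col, strata=strata)
            for res_c in rates:
                row = {
                    "variable": res_c.variable,
                    "kind": "impairment",
                    "test": res_c.test,
                    "statistic": res_c.statistic,
                    "p_value": res_c.p_value,
                    "effect_size": res_c.effect_size,
                    "effect_size_name": res_c.effect_size_name,
                }
                for g, s in res_c.summaries.items():
                    row[f"n_{g}"] = s["n"]
                    row[f"impaired_{g}"] = s["impaired"]
                    row[f"percent_{g}"] = s["percent"]
                rows.append(row)
    if strata:
        for row in rows:
            for k, v in strata.items():
                row[f"stratum_{k}"] = v
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the manifest (also written to
    ``out_dir/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.stages)
    manifest: dict = {
        "tool": f"bracenorms {__version__}",
        "seed": config.cohort.seed,
        "config": config.to_dict(),
        "files": {},
    }

    participants: list[ParticipantRecord] = []

    if "simulate" in stages:
        logger.info("simulate: drawing %d + %d participants",
                    config.cohort.n_reference, config.cohort.n_target)
        participants = generate_cohort(config.cohort)
        ppath = out / "participants.csv"
        write_participants(participants, ppath)
        _register(manifest, ppath, len(participants))
        if config.emit_trials:
            trials = []
            for rec in participants:
                trials.extend(generate_trial_data(rec, config.cohort))
            tframe = trials_to_frame(trials)
            tpath = out / "trials.csv"
            tframe.to_csv(tpath, index=False)
            _register(manifest, tpath, len(tframe))

    if "qc" in stages:
        if not participants:
            participants = read_participants(out / "participants.csv")
        tpath = out / "trials.csv"
        if config.emit_trials and tpath.exists():
            results = apply_qc(pd.read_csv(tpath))
            qpath = out / "qc_report.csv"
            write_qc_report(results, qpath)
            _register(manifest, qpath, sum(1 for _ in results) * 4)
            # replace raw outcomes with the QC-derived ones; drop QC failures
            kept = []
            for rec in participants:
                r = results.get(rec.participant_id)
                if r is None:
                    continue
                rec = dataclasses.replace(rec, raw_outcomes=dict(r.raw_outcomes))
                rec.covariates = dict(rec.covariates)
                kept.append(rec)
            participants = kept

    if {"fit", "score", "compare"} & set(stages) and not participants:
        participants = read_participants(out / "participants.csv")

    models = None
    if "fit" in stages:
        reference = [
            r
            for r in participants
            if r.hiv_status == "without_hiv"
            and all(o in r.raw_outcomes for o in OUTCOMES)
        ]
        logger.info("fit: %d complete-pass reference participants",
                    len(reference))
        models = fit_norms(reference, predictors=config.predictors)
        mpath = out / "models.json"
        serialize_models(models, mpath)
        _register(manifest, mpath, len(models))

    scored = None
    if "score" in stages:
        if models is None:
            from .normative import load_models

            models = load_models(out / "models.json")
        tsets = score_cohort(participants, models)
        scored = scored_frame(tsets, participants)
        spath = out / "scored.csv"
        scored.to_csv(spath, index=False)
        _register(manifest, spath, len(scored))

    if "compare" in stages:
        if scored is None:
            scored = pd.read_csv(out / "scored.csv")
        frames = []
        if config.stratify:
            for level in sorted(scored[config.stratify].dropna().unique()):
                sub = scored[scored[config.stratify] == level]
                frames.append(
                    compare_outcomes(sub, by=config.compare_by,
                                     cutoffs=config.cutoffs,
                                     strata={config.stratify: str(level)})
                )
        else:
            frames.append(
                compare_outcomes(scored, by=config.compare_by,
                                 cutoffs=config.cutoffs)
            )
        cmp_frame = pd.concat(frames, ignore_index=True)
        cpath = out / "comparisons.csv"
        cmp_frame.to_csv(cpath, index=False)
        _register(manifest, cpath, len(cmp_frame))

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
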