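"""Group comparisons, effect sizes, impairment-rate tables and
correlation panels.

Conventions:

* continuous two-group contrasts: pooled-variance t test (or rank-sum
  with normal approximation and tie correction), effect size |Cohen's d|;
* more than two groups: one-way ANOVA with η²;
* categorical contrasts: Pearson χ² without continuity correction, with
  Fisher's exact test for 2×2 tables whenever an expected cell count
  falls below 5; effect size Cramér's V;
* covariate panels: Pearson correlation for continuous covariates,
  point-biserial (Pearson on 0/1 coding) for binary ones; two-sided
  significance tiers at .001/.01/.05 with no multiplicity adjustment by
  default (Benjamini–Hochberg available behind a flag).

All tests are two-sided; effect sizes are reported as absolute values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "CorrelationPanel",
    "cohens_d",
    "cohens_d_from_arrays",
    "compare_continuous",
    "compare_categorical",
    "correlation_panel",
    "impairment_rate_table",
    "cramers_v",
]

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    """Outcome of one group contrast."""

    variable: str
    groups: tuple[str, ...]
    summaries: dict[str, dict[str, float]]
    test: str
    statistic: float
    p_value: float
    effect_size: float
    effect_size_name: str
    strata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect sizes use the absolute-value convention")


# ---------------------------------------------------------------------------
# effect sizes


def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """|Cohen's d| with the pooled-SD denominator.

    pooled SD = sqrt(((n1−1)·sd1² + (n2−1)·sd2²) / (n1+n2−2)); callable
    directly from printed summary statistics.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("cohens_d needs n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var == 0:
        if mean1 == mean2:
            return 0.0
        raise ValueError("Cohen's d undefined: both group SDs are zero")
    return abs(mean1 - mean2) / math.sqrt(pooled_var)


def cohens_d_from_arrays(x: Sequence[float], y: Sequence[float]) -> float:
    """|Cohen's d| from raw arrays (sample SDs, ddof=1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return cohens_d(
        float(x.mean()), float(x.std(ddof=1)), len(x),
        float(y.mean()), float(y.std(ddof=1)), len(y),
    )


def cramers_v(table: np.ndarray, chi2: float) -> float:
    table = np.asarray(table, dtype=float)
    n = table.sum()
    k = min(table.shape) - 1
    return math.sqrt(chi2 / (n * k)) if k > 0 and n > 0 else 0.0


# ---------------------------------------------------------------------------
# continuous comparisons


def compare_continuous(
    groups: Mapping[str, Sequence[float]],
    method: str = "t_test",
    variable: str = "",
    strata: Mapping[str, str] | None = None,
) -> ComparisonResult:
    """Compare a continuous variable across groups.

    ``method`` is ``"t_test"`` (two groups, pooled variance),
    ``"wilcoxon"`` (two groups, rank-sum, normal approximation with tie
    correction) or ``"anova"`` (any number of groups, returns F and η²).
    """
    labels = tuple(groups)
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    summaries = {
        g: {
            "n": float(len(a)),
            "mean": float(a.mean()),
            "sd": float(a.std(ddof=1)) if len(a) > 1 else float("nan"),
        }
        for g, a in arrays.items()
    }

    if method in ("t_test", "wilcoxon"):
        if len(labels) != 2:
            raise ValueError(f"{method} requires exactly 2 groups")
        x, y = arrays[labels[0]], arrays[labels[1]]
        if method == "t_test":
            if len(x) < 2 or len(y) < 2:
                raise ValueError("t_test needs n >= 2 per group")
            if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
                logger.warning(
                    "%s: zero within-group variance in the t test", variable
                )
            stat, p = stats.ttest_ind(x, y, equal_var=True)
            try:
                es = cohens_d_from_arrays(x, y)
            except ValueError:
                es = 0.0
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic")
            stat, p = res.statistic, res.pvalue
            try:
                es = cohens_d_from_arrays(x, y) if len(x) > 1 and len(y) > 1 else 0.0
            except ValueError:
                es = 0.0
        return ComparisonResult(
            variable, labels, summaries,
            "t_test" if method == "t_test" else "wilcoxon_rank_sum",
            float(stat), float(p), float(es), "abs_cohens_d",
            dict(strata or {}),
        )

    if method == "anova":
        if len(labels) < 2:
            raise ValueError("anova requires >= 2 groups")
        samples = [arrays[g] for g in labels]
        if any(len(s) < 2 for s in samples):
            raise ValueError("anova needs n >= 2 per group")
        stat, p = stats.f_oneway(*samples)
        grand = np.concatenate(samples)
        ss_total = float(((grand - grand.mean()) ** 2).sum())
        ss_between = float(
            sum(len(s) * (s.mean() - grand.mean()) ** 2 for s in samples)
        )
        eta_sq = ss_between / ss_total if ss_total > 0 else 0.0
        return ComparisonResult(
            variable, labels, summaries, "anova",
            float(stat), float(p), float(eta_sq), "eta_squared",
            dict(strata or {}),
        )

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# categorical comparisons


def compare_categorical(
    table: np.ndarray | Sequence[Sequence[int]],
    variable: str = "",
    group_labels: Sequence[str] | None = None,
    strata: Mapping[str, str] | None = None,
) -> ComparisonResult:
    """Pearson χ² (no continuity correction) on an r×k count table.

    Falls back to Fisher's exact test for 2×2 tables with any expected
    cell below 5 (the χ² statistic still supplies Cramér's V).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("contingency table must hold non-negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an all-zero margin")

    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    test = "pearson_chi2"
    if table.shape == (2, 2) and (expected < 5).any():
        _, p = stats.fisher_exact(table.astype(int))
        test = "fisher_exact"
        logger.info(
            "%s: expected cell below 5, Fisher exact test used", variable
        )
    v = cramers_v(table, float(chi2))

    labels = tuple(
        group_labels
        if group_labels is not None
        else (f"group{i}" for i in range(table.shape[0]))
    )
    n = table.sum()
    summaries = {
        lab: {
            "n": float(table[i].sum()),
            "proportion": float(table[i].sum() / n),
        }
        for i, lab in enumerate(labels)
    }
    return ComparisonResult(
        variable, labels, summaries, test,
        float(chi2), float(p), float(v), "cramers_v", dict(strata or {}),
    )


# ---------------------------------------------------------------------------
# correlation panels


@dataclass
class CorrelationPanel:
    """Covariate × outcome correlation grid.

    ``r``, ``p``, ``method`` and ``tier`` are DataFrames indexed by
    covariate with one column per outcome; non-computable cells (constant
    covariate, too few complete pairs) hold NaN / ``"nc"``.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    method: pd.DataFrame
    tier: pd.DataFrame


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return len(u) <= 2 and set(u).issubset({0.0, 1.0})


def _sig_tier(p: float) -> str:
    if math.isnan(p):
        return "nc"
    if p < 0.001:
        return "<.001"
    if p < 0.01:
        return "<.01"
    if p < 0.05:
        return "<.05"
    return "ns"


def correlation_panel(
    data: pd.DataFrame,
    covariates: Sequence[str],
    outcomes: Sequence[str],
    min_pairs: int = 3,
    fdr: bool = False,
) -> CorrelationPanel:
    """Pairwise-complete correlation panel.

    Pearson for continuous covariates; point-biserial (identically Pearson
    on the 0/1 coding) for binary ones.  With ``fdr=True`` the significance
    tiers are assigned to Benjamini–Hochberg-adjusted p-values instead of
    the raw ones.
    """
    r = pd.DataFrame(index=list(covariates), columns=list(outcomes), dtype=float)
    p = r.copy()
    meth = pd.DataFrame(index=list(covariates), columns=list(outcomes),
                        dtype=object)
    for cov in covariates:
        x_all = pd.to_numeric(data[cov], errors="coerce").to_numpy(dtype=float)
        binary = _is_binary(x_all)
        for outcome in outcomes:
            y_all = pd.to_numeric(data[outcome], errors="coerce").to_numpy(
                dtype=float
            )
            mask = ~(np.isnan(x_all) | np.isnan(y_all))
            x, y = x_all[mask], y_all[mask]
            meth.loc[cov, outcome] = "point_biserial" if binary else "pearson"
            if len(x) < min_pairs or np.std(x) == 0 or np.std(y) == 0:
                r.loc[cov, outcome] = np.nan
                p.loc[cov, outcome] = np.nan
                logger.info("panel cell (%s, %s) not computable", cov, outcome)
                continue
            rr, pp = stats.pearsonr(x, y)
            r.loc[cov, outcome] = rr
            p.loc[cov, outcome] = pp

    p_for_tiers = p.copy()
    if fdr:
        flat = p.to_numpy().ravel()
        ok = ~np.isnan(flat)
        if ok.any():
            from statsmodels.stats.multitest import multipletests

            adj = np.full_like(flat, np.nan)
            adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
            p_for_tiers = pd.DataFrame(
                adj.reshape(p.shape), index=p.index, columns=p.columns
            )
    tier = p_for_tiers.map(_sig_tier)
    return CorrelationPanel(r=r, p=p, method=meth, tier=tier)


# ---------------------------------------------------------------------------
# impairment rates


def impairment_rate_table(
    tscores_by_group: Mapping[str, Sequence[float]],
    cutoffs: Sequence[float] = (40.0, 35.0),
    variable: str = "t",
    strata: Mapping[str, str] | None = None,
) -> list[ComparisonResult]:
    """Per-group impairment counts/percentages below each cutoff, with the
    categorical group contrast (χ² / Fisher) at each cutoff."""
    labels = tuple(tscores_by_group)
    arrays = {g: np.asarray(v, dtype=float) for g, v in tscores_by_group.items()}
    for g, a in arrays.items():
        if len(a) == 0:
            raise ValueError(f"group {g!r} is empty")
    results = []
    for cutoff in cutoffs:
        counts = np.array(
            [
                [(arrays[g] < cutoff).sum(), (arrays[g] >= cutoff).sum()]
                for g in labels
            ],
            dtype=int,
        )
        if (counts.sum(axis=0) == 0).any():
            # nobody (or everybody) impaired in every group: no association
            n = counts.sum()
            res = ComparisonResult(
                f"{variable}<{cutoff:g}", labels,
                {
                    lab: {
                        "n": float(counts[i].sum()),
                        "proportion": float(counts[i].sum() / n),
                    }
                    for i, lab in enumerate(labels)
                },
                "degenerate", 0.0, 1.0, 0.0, "cramers_v", dict(strata or {}),
            )
        else:
            res = compare_categorical(
                counts,
                variable=f"{variable}<{cutoff:g}",
                group_labels=labels,
                strata=strata,
            )
        for i, g in enumerate(labels):
            res.summaries[g].update(
                n=float(len(arrays[g])),
                impaired=float(counts[i, 0]),
                percent=100.0 * counts[i, 0] / len(arrays[g]),
            )
        results.append(res)
    return results
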