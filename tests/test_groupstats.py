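"""Effect sizes, group tests, contingency tables, correlation panels."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bracenorms import (
    cohens_d,
    cohens_d_from_arrays,
    compare_categorical,
    compare_continuous,
    correlation_panel,
    impairment_rate_table,
)

# ---------------------------------------------------------------------------
# Cohen's d


@pytest.mark.parametrize(
    "g1, g2, expected",
    [
        # printed serostatus summaries reproduce the published |d| values:
        # TMT-B completion time (ms)
        ((44_331, 15_116, 1063), (45_404, 14_975, 1874), 0.07),
        # TMT B−A difference (ms)
        ((24_841, 14_189, 1063), (25_966, 14_423, 1874), 0.08),
        # Stroop duration T-score
        ((50.0, 9.98, 1063), (49.08, 10.14, 1874), 0.09),
    ],
)
def test_cohens_d_from_printed_summaries(g1, g2, expected):
    assert round(cohens_d(*g1, *g2), 2) == expected


def test_cohens_d_equal_means_is_zero():
    assert cohens_d(5.0, 1.0, 10, 5.0, 2.0, 20) == 0.0


def test_cohens_d_undefined_when_both_sds_zero():
    with pytest.raises(ValueError, match="undefined"):
        cohens_d(1.0, 0.0, 5, 2.0, 0.0, 5)


@settings(max_examples=100, deadline=None)
@given(
    x=st.lists(st.floats(-50, 50), min_size=3, max_size=30),
    y=st.lists(st.floats(-50, 50), min_size=3, max_size=30),
)
def test_cohens_d_summaries_equal_arrays(x, y):
    """d from (mean, sd, n) summaries equals d from the raw arrays."""
    x, y = np.array(x), np.array(y)
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        return
    from_summary = cohens_d(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )
    assert cohens_d_from_arrays(x, y) == pytest.approx(from_summary, abs=1e-12)


# ---------------------------------------------------------------------------
# continuous comparisons


def test_identical_groups_no_effect():
    g = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
    res = compare_continuous(g, method="t_test")
    assert res.p_value == pytest.approx(1.0)
    assert res.effect_size == 0.0


def test_t_statistic_matches_brute_force():
    rng = np.random.default_rng(1)
    x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1.3, 15)
    res = compare_continuous({"x": x, "y": y}, method="t_test")
    sp = math.sqrt(
        ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
        / (len(x) + len(y) - 2)
    )
    t_brute = (x.mean() - y.mean()) / (sp * math.sqrt(1 / len(x) + 1 / len(y)))
    assert res.statistic == pytest.approx(t_brute, abs=1e-12)
    assert res.summaries["x"]["n"] + res.summaries["y"]["n"] == 27


def test_wilcoxon_matches_scipy_asymptotic():
    rng = np.random.default_rng(2)
    x, y = rng.normal(0, 1, 20), rng.normal(0.7, 1, 25)
    res = compare_continuous({"x": x, "y": y}, method="wilcoxon")
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert res.p_value == pytest.approx(ref.pvalue)


def test_anova_eta_squared():
    rng = np.random.default_rng(3)
    groups = {
        "a": rng.normal(0, 1, 30),
        "b": rng.normal(1, 1, 30),
        "c": rng.normal(2, 1, 30),
    }
    res = compare_continuous(groups, method="anova")
    assert res.effect_size_name == "eta_squared"
    assert 0 < res.effect_size < 1
    # eta^2 = SSbetween/SStotal, cross-checked directly
    grand = np.concatenate(list(groups.values()))
    ssb = sum(len(v) * (v.mean() - grand.mean()) ** 2 for v in groups.values())
    sst = ((grand - grand.mean()) ** 2).sum()
    assert res.effect_size == pytest.approx(ssb / sst, abs=1e-12)


def test_zero_variance_group_handled(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="bracenorms.groupstats"):
        res = compare_continuous(
            {"a": [1.0, 1.0, 1.0], "b": [2.0, 3.0, 4.0]}, method="t_test"
        )
    assert math.isfinite(res.statistic)
    assert any("variance" in m for m in caplog.messages)


# ---------------------------------------------------------------------------
# categorical comparisons


def test_chi2_closed_form_2x2():
    res = compare_categorical([[10, 20], [20, 10]])
    assert res.statistic == pytest.approx(6.667, abs=1e-3)
    assert res.effect_size == pytest.approx(0.333, abs=1e-3)
    assert res.test == "pearson_chi2"


def test_identical_row_distributions_zero():
    res = compare_categorical([[10, 20, 30], [20, 40, 60]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.effect_size == pytest.approx(0.0, abs=1e-12)


def test_fisher_path_on_small_expected_cells():
    res = compare_categorical([[1, 9], [5, 5]])  # expected cell 3
    assert res.test == "fisher_exact"
    ref_p = stats.fisher_exact([[1, 9], [5, 5]])[1]
    assert res.p_value == pytest.approx(ref_p)


def test_all_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        compare_categorical([[0, 0], [3, 4]])


@settings(max_examples=100, deadline=None)
@given(
    counts=st.lists(
        st.lists(st.integers(1, 40), min_size=2, max_size=4),
        min_size=2,
        max_size=3,
    ).filter(lambda rows: len({len(r) for r in rows}) == 1)
)
def test_chi2_matches_brute_force(counts):
    """Pearson χ² equals Σ(O−E)²/E computed by hand (1e-9)."""
    table = np.array(counts, dtype=float)
    res = compare_categorical(table)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    brute = ((table - expected) ** 2 / expected).sum()
    assert res.statistic == pytest.approx(brute, abs=1e-9)
    assert res.effect_size == pytest.approx(
        math.sqrt(brute / (n * (min(table.shape) - 1))), abs=1e-9
    )


# ---------------------------------------------------------------------------
# correlation panels


def test_covariate_equal_to_outcome_r1():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
    df["y"] = df["x"]
    panel = correlation_panel(df, ["x"], ["y"])
    assert panel.r.loc["x", "y"] == pytest.approx(1.0)
    assert panel.method.loc["x", "y"] == "pearson"


def test_point_biserial_equals_pearson_on_binary():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(
        {"flag": rng.integers(0, 2, 60).astype(float), "y": rng.normal(0, 1, 60)}
    )
    panel = correlation_panel(df, ["flag"], ["y"])
    assert panel.method.loc["flag", "y"] == "point_biserial"
    r_ref, p_ref = stats.pearsonr(df["flag"], df["y"])
    assert panel.r.loc["flag", "y"] == pytest.approx(r_ref, abs=1e-12)
    assert panel.p.loc["flag", "y"] == pytest.approx(p_ref, abs=1e-12)


def test_constant_covariate_not_computable():
    df = pd.DataFrame({"c": [1.0] * 10, "y": np.arange(10.0)})
    panel = correlation_panel(df, ["c"], ["y"])
    assert np.isnan(panel.r.loc["c", "y"])
    assert panel.tier.loc["c", "y"] == "nc"


def test_panel_row_order_invariance():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        {"x": rng.normal(size=40), "y": rng.normal(size=40),
         "z": rng.normal(size=40)}
    )
    a = correlation_panel(df, ["x", "y"], ["z"])
    b = correlation_panel(df.sample(frac=1, random_state=0), ["x", "y"], ["z"])
    pd.testing.assert_frame_equal(a.r, b.r)
    pd.testing.assert_frame_equal(a.p, b.p)


def test_injected_covariate_effect_detected(published):
    """A +0.5·SEE additive effect at 50% prevalence, n=2000, yields r≈0.24
    with p<.001 (power oracle)."""
    import dataclasses

    from bracenorms import CohortSpec, generate_cohort
    from bracenorms.outcomes import OUTCOMES

    see = published["tmt_a"].see
    spec = CohortSpec(
        n_reference=2000, n_target=0, seed=55,
        covariate_prevalences={"diabetes": 0.5},
        covariate_effects={"diabetes": {"tmt_a": 0.5 * see}},
    )
    records = generate_cohort(spec)
    df = pd.DataFrame(
        {
            "diabetes": [r.covariates["diabetes"] for r in records],
            "resid": [
                OUTCOMES["tmt_a"].to_analysis(r.raw_outcomes["tmt_a"])
                - published["tmt_a"].predict(
                    {"age": r.age, "education": r.education}
                )
                for r in records
            ],
        }
    )
    panel = correlation_panel(df, ["diabetes"], ["resid"])
    assert panel.r.loc["diabetes", "resid"] == pytest.approx(0.24, abs=0.06)
    assert panel.tier.loc["diabetes", "resid"] == "<.001"


def test_null_tier_rate_near_alpha():
    """Under independence the .05 tier fires for about 5% of cells."""
    rng = np.random.default_rng(6)
    hits = 0
    reps = 1000
    for _ in range(reps):
        df = pd.DataFrame(
            {"x": rng.normal(size=50), "y": rng.normal(size=50)}
        )
        panel = correlation_panel(df, ["x"], ["y"])
        if panel.tier.loc["x", "y"] != "ns":
            hits += 1
    # binomial(1000, .05): 3 sigma band
    assert abs(hits / reps - 0.05) < 3 * math.sqrt(0.05 * 0.95 / reps)


def test_fdr_flag_tightens_tiers():
    rng = np.random.default_rng(7)
    df = pd.DataFrame(rng.normal(size=(60, 11)),
                      columns=[f"c{i}" for i in range(10)] + ["y"])
    raw = correlation_panel(df, [f"c{i}" for i in range(10)], ["y"])
    adj = correlation_panel(df, [f"c{i}" for i in range(10)], ["y"], fdr=True)
    order = {"<.001": 0, "<.01": 1, "<.05": 2, "ns": 3, "nc": 4}
    for cov in raw.tier.index:
        assert order[adj.tier.loc[cov, "y"]] >= order[raw.tier.loc[cov, "y"]]


# ---------------------------------------------------------------------------
# impairment rates


def test_impairment_rate_hand_counts():
    rates = impairment_rate_table(
        {"g": [30.0, 36.0, 50.0, 60.0]}, cutoffs=(40.0, 35.0)
    )
    at_40, at_35 = rates
    assert at_40.summaries["g"]["percent"] == pytest.approx(50.0)
    assert at_35.summaries["g"]["percent"] == pytest.approx(25.0)


def test_impairment_no_one_below_cutoff():
    rates = impairment_rate_table({"g": [50.0] * 8, "h": [50.0] * 8})
    for res in rates:
        assert res.summaries["g"]["percent"] == 0.0
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)


def test_identical_groups_v_zero():
    rates = impairment_rate_table(
        {"a": [30.0, 50.0, 50.0, 60.0], "b": [30.0, 50.0, 50.0, 60.0]}
    )
    assert rates[0].effect_size == pytest.approx(0.0, abs=1e-12)


def test_empty_group_rejected():
    with pytest.raises(ValueError, match="empty"):
        impairment_rate_table({"a": [50.0], "b": []})
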