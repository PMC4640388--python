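"""Validation-statistics tests: closed-form odds ratios, concordance
statistics against brute force, logistic oracle equivalence, and the
calibration/attenuation properties on synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import ydrisk
from ydrisk.errors import ParameterError
from ydrisk.validation import AGE_BANDS


def counts_frame(rows):
    return pd.DataFrame(rows, columns=["category", "n", "cases"]).set_index(
        "category"
    )


# ---------------------------------------------------------------------------
# closed-form odds ratios


def test_published_extreme_category_ors(overall_counts):
    ors = ydrisk.closed_form_category_or(overall_counts)
    assert ors.loc["very_much_below_average", "point"] == pytest.approx(0.42, abs=0.005)
    assert ors.loc["very_much_above_average", "point"] == pytest.approx(1.71, abs=0.005)


def test_equal_case_fractions_give_unit_or():
    counts = counts_frame(
        [("about_average", 1000, 50), ("above_average", 400, 20)]
    )
    ors = ydrisk.closed_form_category_or(counts)
    assert ors.loc["above_average", "point"] == pytest.approx(1.0)


def test_zero_cell_is_flagged_not_fatal():
    counts = counts_frame(
        [("about_average", 100, 10), ("above_average", 50, 0)]
    )
    ors = ydrisk.closed_form_category_or(counts)
    assert ors.loc["above_average", "zero_cell"]
    assert ors.loc["above_average", "point"] == 0.0
    assert np.isinf(ors.loc["above_average", "ci_high"])


def test_reference_without_cases_rejected():
    counts = counts_frame([("about_average", 100, 0), ("above_average", 50, 5)])
    with pytest.raises(ParameterError):
        ydrisk.closed_form_category_or(counts)


# ---------------------------------------------------------------------------
# concordance statistics


def test_perfect_separation_gives_unit_c():
    counts = counts_frame([("below_average", 50, 0), ("above_average", 30, 30)])
    assert ydrisk.c_statistic_from_counts(counts).c == pytest.approx(1.0)


def test_all_equal_rates_give_half_c():
    counts = counts_frame(
        [("below_average", 100, 10), ("above_average", 200, 20)]
    )
    res = ydrisk.c_statistic_from_counts(counts)
    assert res.c == pytest.approx(0.5)
    assert res.degenerate


def test_pairwise_trivials():
    same = ydrisk.c_statistic_pairwise([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])
    assert same.c == pytest.approx(0.5)
    assert same.degenerate
    top = ydrisk.c_statistic_pairwise([0.1, 0.2, 0.9], [0, 0, 1])
    assert top.c == pytest.approx(1.0)


def test_pairwise_matches_brute_force_and_reference_implementation():
    rng = np.random.default_rng(7)
    scores = rng.normal(size=500).round(1)  # rounding forces ties
    outcomes = (rng.random(500) < 0.25).astype(int)
    res = ydrisk.c_statistic_pairwise(scores, outcomes)
    cases = scores[outcomes == 1]
    ctrl = scores[outcomes == 0]
    num = sum((ctrl < s).sum() + 0.5 * (ctrl == s).sum() for s in cases)
    brute = num / (len(cases) * len(ctrl))
    assert res.c == pytest.approx(brute, abs=1e-12)
    assert res.c == pytest.approx(roc_auc_score(outcomes, scores), abs=1e-12)


def test_pairwise_equals_count_based_on_category_rates(consensus_scored):
    counts = ydrisk.category_counts(consensus_scored)
    rates = (counts["cases"] / counts["n"]).to_dict()
    scores = consensus_scored["ydr_category"].astype(str).map(rates)
    pairwise = ydrisk.c_statistic_pairwise(scores, consensus_scored["chd_10yr"])
    counted = ydrisk.c_statistic_from_counts(counts)
    assert pairwise.c == pytest.approx(counted.c, abs=1e-12)


def test_c_invariant_under_monotone_transforms():
    rng = np.random.default_rng(11)
    scores = rng.gamma(2.0, size=300)
    outcomes = (rng.random(300) < 0.3).astype(int)
    base = ydrisk.c_statistic_pairwise(scores, outcomes).c
    for transform in (np.log, np.sqrt, lambda s: 3 * s - 7, lambda s: s**3):
        assert ydrisk.c_statistic_pairwise(
            transform(scores), outcomes
        ).c == pytest.approx(base, abs=1e-12)


def test_delong_interval_close_to_hanley_mcneil():
    rng = np.random.default_rng(13)
    scores = rng.normal(size=2000) + np.repeat([0.0, 0.8], 1000)
    outcomes = np.repeat([0, 1], 1000)
    hm = ydrisk.c_statistic_pairwise(scores, outcomes, ci_method="hanley-mcneil")
    dl = ydrisk.c_statistic_pairwise(scores, outcomes, ci_method="delong")
    assert hm.c == dl.c
    assert dl.se == pytest.approx(hm.se, rel=0.25)


def test_degenerate_counts_flagged():
    counts = counts_frame([("about_average", 100, 5)])
    res = ydrisk.c_statistic_from_counts(counts)
    assert res.c == pytest.approx(0.5)
    assert res.degenerate


# ---------------------------------------------------------------------------
# comparing strata


def test_identical_strata_compare_equal():
    counts = counts_frame(
        [("below_average", 500, 10), ("above_average", 500, 40)]
    )
    a = ydrisk.c_statistic_from_counts(counts)
    z, p = ydrisk.compare_c_statistics(a, a)
    assert z == 0.0
    assert p == pytest.approx(1.0)


def test_age_strata_direction_from_published_counts():
    lt60 = (
        ydrisk.read_published_category_counts("age_lt60")
        .set_index("category")[["n", "cases"]]
    )
    ge60 = (
        ydrisk.read_published_category_counts("age_ge60")
        .set_index("category")[["n", "cases"]]
    )
    c_lt = ydrisk.c_statistic_from_counts(lt60)
    c_ge = ydrisk.c_statistic_from_counts(ge60)
    z, p = ydrisk.compare_c_statistics(c_lt, c_ge)
    assert c_lt.c > c_ge.c  # better discrimination among younger women
    assert z > 0 and p < 0.05


def test_zero_variance_comparison_rejected():
    a = ydrisk.CStatResult(0.6, 0.0, 0.6, 0.6, 10, 10)
    with pytest.raises(ParameterError):
        ydrisk.compare_c_statistics(a, a)


# ---------------------------------------------------------------------------
# logistic category models


def expand_counts_to_rows(counts, age=60):
    rows = []
    for cat, row in counts.iterrows():
        rows += [(cat, 1)] * int(row["cases"])
        rows += [(cat, 0)] * int(row["n"] - row["cases"])
    df = pd.DataFrame(rows, columns=["ydr_category", "chd_10yr"])
    df["age"] = age
    return df


def test_logistic_ors_equal_closed_form(overall_counts):
    scored = expand_counts_to_rows(overall_counts)
    table, _ = ydrisk.logistic_category_model(scored)
    oracle = ydrisk.closed_form_category_or(overall_counts)
    for cat in table.index:
        assert table.loc[cat, "point"] == pytest.approx(
            oracle.loc[cat, "point"], rel=1e-6
        )


def test_single_category_cohort_has_no_contrast():
    scored = pd.DataFrame(
        {"ydr_category": ["about_average"] * 50, "chd_10yr": [1] * 5 + [0] * 45,
         "age": 60}
    )
    with pytest.raises(ParameterError):
        ydrisk.logistic_category_model(scored)


def test_age_adjustment_is_neutral_without_confounding(consensus_scored):
    crude, _ = ydrisk.logistic_category_model(consensus_scored, adjust_age=False)
    adj, _ = ydrisk.logistic_category_model(consensus_scored, adjust_age=True)
    counts = ydrisk.category_counts(consensus_scored)
    for cat in crude.index:
        if cat == "about_average" or counts.loc[cat, "cases"] < 5:
            continue
        log_crude = np.log(crude.loc[cat, "point"])
        log_adj = np.log(adj.loc[cat, "point"])
        se = (
            np.log(crude.loc[cat, "ci_high"]) - np.log(crude.loc[cat, "ci_low"])
        ) / (2 * 1.959964)
        assert abs(log_adj - log_crude) < 3 * se


def test_null_or_interval_coverage():
    """Wald CI for the category OR covers the true null value at ~95% over
    200 replicated null cohorts."""
    rng = np.random.default_rng(2)
    n, covered = 2000, 0
    for _ in range(200):
        exposed = rng.random(n) < 0.3
        disease = rng.random(n) < 0.05  # independent of exposure: true OR 1
        counts = counts_frame(
            [
                ("about_average", int((~exposed).sum()), int(disease[~exposed].sum())),
                ("above_average", int(exposed.sum()), int(disease[exposed].sum())),
            ]
        )
        ors = ydrisk.closed_form_category_or(counts)
        row = ors.loc["above_average"]
        covered += bool(row["ci_low"] <= 1.0 <= row["ci_high"])
    assert 0.90 <= covered / 200 <= 0.99


# ---------------------------------------------------------------------------
# tabulation and report


def test_category_counts_conservation(consensus_scored):
    counts = ydrisk.category_counts(consensus_scored)
    assert counts["n"].sum() == len(consensus_scored)
    assert counts["cases"].sum() == consensus_scored["chd_10yr"].sum()
    assert (counts["cases"] <= counts["n"]).all()


def test_published_fixture_counts_pass_invariants(overall_counts):
    assert overall_counts["cases"].sum() == 1165
    assert overall_counts["n"].sum() == 55802
    assert ((overall_counts["cases"] >= 0)
            & (overall_counts["cases"] <= overall_counts["n"])).all()


def test_report_reproduces_published_crude_column():
    counts = ydrisk.read_published_category_counts()
    rep = ydrisk.report_from_counts(counts[["stratum", "category", "n", "cases"]])
    pub = counts[counts["stratum"] == "overall"].set_index("category")
    table = rep["or_tables"]["overall"]
    for cat in pub.index:
        assert table.loc[cat, "point"] == pytest.approx(
            pub.loc[cat, "published_or"], abs=0.005
        )
    assert rep["c_statistic"].c == pytest.approx(0.62, abs=0.005)


def test_full_report_on_synthetic_cohort(consensus_scored, model_us, tmp_path):
    report = ydrisk.build_report(consensus_scored, model=model_us)
    assert report.n == len(consensus_scored)
    assert set(report.category_tables) == {"overall", "age_lt60", "age_ge60"}
    assert {"overall", "overall_age_adjusted"} <= set(report.cstats)
    assert {band for band, _, _ in AGE_BANDS} <= set(report.cstats)
    # age-adjusted discrimination beats the crude category model, since age
    # drives the simulated outcome but not the score
    assert report.cstats["overall_age_adjusted"].c > report.cstats["overall"].c
    report.to_files(tmp_path)
    assert (tmp_path / "summary.txt").exists()
    assert (tmp_path / "cstatistics.csv").exists()


def test_tiny_cohort_report_degrades_gracefully(model_us):
    cohort = ydrisk.read_cohort(ydrisk.example_cohort_path(), model=model_us)
    scored = ydrisk.score_cohort(model_us, cohort)
    rng = np.random.default_rng(0)
    scored["chd_10yr"] = (rng.random(len(scored)) < 0.3).astype(int)
    report = ydrisk.build_report(scored, model=model_us)
    assert report.n == 20
    assert report.to_text()  # renders without crashing
    assert report.flags  # fragile fits are flagged, not fatal


def test_attenuated_effects_shrink_category_ors(model_us, model_nhs,
                                               consensus_scored):
    """Outcomes driven by weaker RRs than the score assumes yield category
    ORs closer to 1 than when the score's own RRs drive the outcome, and
    the extreme categories no longer reach their nominal score bands."""
    weak = ydrisk.load_effect_rrs(source="observed_multivariate")
    spec = ydrisk.CohortSpec(
        n_subjects=50_000, random_seed=20260926,
        effect_rr_source="observed_multivariate",
    )
    weak_scored = ydrisk.score_cohort(
        model_us, ydrisk.simulate_cohort(spec, model_nhs, weak)
    )
    strong_ors = ydrisk.closed_form_category_or(
        ydrisk.category_counts(consensus_scored)
    )
    weak_ors = ydrisk.closed_form_category_or(ydrisk.category_counts(weak_scored))
    for cat in ("very_much_below_average", "much_below_average",
                "much_above_average", "very_much_above_average"):
        assert abs(np.log(weak_ors.loc[cat, "point"])) < abs(
            np.log(strong_ors.loc[cat, "point"])
        )
    # overestimates risk at the bottom, underestimates at the top
    assert weak_ors.loc["very_much_below_average", "point"] > 0.2
    assert weak_ors.loc["very_much_above_average", "point"] < 5.1
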