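"""Evaluation statistics against independent oracles and hand computations."""

import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from anuadri import (
    EvaluationError,
    age_split_comparison,
    assign_quartiles,
    auc_confidence_interval,
    build_scorecard,
    c_statistic,
    chi_square_2x2,
    cox_quartile_hr,
    evaluate_index,
    filter_analysis_set,
    fit_score_coefficient,
    incidence_rates,
    score_cohort,
    SyntheticConfig,
    generate_cohort,
)

# ---------------------------------------------------------------------------
# Oracles (kept independent of the implementation under test)


def pairwise_auc(scores, labels) -> Fraction:
    """Exact concordance by enumeration of all case-control pairs."""
    cases = [s for s, y in zip(scores, labels) if y == 1]
    controls = [s for s, y in zip(scores, labels) if y == 0]
    total = Fraction(0)
    for c in cases:
        for d in controls:
            if c > d:
                total += 1
            elif c == d:
                total += Fraction(1, 2)
    return total / (len(cases) * len(controls))


def breslow_neg_log_partial_likelihood(beta, time, status, x):
    """One-covariate Cox partial likelihood, Breslow form."""
    eta = beta * np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    ll = 0.0
    for t in np.unique(time[status == 1]):
        deaths = (time == t) & (status == 1)
        at_risk = time >= t
        d = deaths.sum()
        ll += eta[deaths].sum() - d * np.log(np.exp(eta[at_risk]).sum())
    return -ll


def cox_oracle_coef(time, status, x) -> float:
    res = minimize_scalar(
        breslow_neg_log_partial_likelihood, bounds=(-10, 10), method="bounded",
        args=(time, status, x), options={"xatol": 1e-10})
    return float(res.x)


def random_small_cox_instance(rng):
    """Random <=6-subject survival instance with one binary covariate, or
    None when the partial likelihood has no identified interior maximiser
    (no events, no covariate contrast, monotone or flat likelihood)."""
    n = int(rng.integers(3, 7))
    time = np.round(rng.exponential(2, n), 3) + 0.01
    status = rng.integers(0, 2, n)
    x = rng.integers(0, 2, n).astype(float)
    if status.sum() == 0 or np.ptp(x) == 0:
        return None
    oracle = cox_oracle_coef(time, status, x)
    args = (time, status, x)
    curvature = (breslow_neg_log_partial_likelihood(oracle + 0.1, *args)
                 + breslow_neg_log_partial_likelihood(oracle - 0.1, *args)
                 - 2 * breslow_neg_log_partial_likelihood(oracle, *args))
    if abs(oracle) > 8 or curvature < 1e-6:
        return None
    return time, status, x, oracle


# ---------------------------------------------------------------------------
# c-statistic


def test_c_statistic_hand_example():
    """Cases {3, 1} vs controls {2, 0}: 3 concordant pairs, 1 discordant."""
    assert c_statistic([3, 1, 2, 0], [1, 1, 0, 0]) == pytest.approx(0.75)


def test_c_statistic_perfect_separation():
    assert c_statistic([5, 6, 1, 2], [1, 1, 0, 0]) == 1.0


def test_c_statistic_all_ties():
    assert c_statistic([2, 2, 2, 2], [1, 1, 0, 0]) == 0.5


def test_c_statistic_single_class_rejected():
    with pytest.raises(EvaluationError):
        c_statistic([1, 2, 3], [1, 1, 1])


def test_c_statistic_matches_exhaustive_enumeration():
    rng = np.random.default_rng(123)
    for _ in range(40):
        n = int(rng.integers(4, 51))
        scores = rng.integers(-5, 15, size=n)  # integer scores force ties
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if labels.sum() in (0, n):
            continue
        exact = pairwise_auc(scores.tolist(), labels.tolist())
        assert Fraction(c_statistic(scores, labels)).limit_denominator(10**9) == exact


def test_c_statistic_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(5)
    scores = rng.normal(size=300) + np.repeat([0.0, 0.7], 150)
    labels = np.repeat([0, 1], 150)
    assert c_statistic(scores, labels) == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.tuples(st.integers(-20, 20), st.booleans()), min_size=4, max_size=40))
def test_label_flip_antisymmetry(pairs):
    scores = [s for s, _ in pairs]
    labels = [int(y) for _, y in pairs]
    if sum(labels) in (0, len(labels)):
        return
    flipped = [1 - y for y in labels]
    assert c_statistic(scores, labels) + c_statistic(scores, flipped) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# DeLong / bootstrap confidence intervals


def test_delong_perfect_separation_zero_width():
    r = auc_confidence_interval([4, 5, 6, 1, 2, 3], [1, 1, 1, 0, 0, 0])
    assert (r.auc, r.ci_low, r.ci_high) == (1.0, 1.0, 1.0)


def test_delong_ci_covers_point_estimate():
    r = auc_confidence_interval([3, 1, 2, 0], [1, 1, 0, 0])
    assert r.ci_low <= 0.75 <= r.ci_high
    assert r.n_cases == 2 and r.n_controls == 2


def test_delong_and_bootstrap_roughly_agree():
    rng = np.random.default_rng(21)
    scores = np.concatenate([rng.normal(0.8, 1, 150), rng.normal(0, 1, 350)])
    labels = np.concatenate([np.ones(150, int), np.zeros(350, int)])
    d = auc_confidence_interval(scores, labels, method="delong")
    b = auc_confidence_interval(scores, labels, method="bootstrap", seed=1)
    assert d.auc == pytest.approx(b.auc)
    assert d.ci_low == pytest.approx(b.ci_low, abs=0.02)
    assert d.ci_high == pytest.approx(b.ci_high, abs=0.02)


def test_delong_coverage_of_generative_auc():
    """Binormal scores with a known population AUC: the 95% DeLong interval
    should attain at least 93% coverage over 400 replicates."""
    from scipy.stats import norm

    delta = 1.0
    true_auc = norm.cdf(delta / np.sqrt(2.0))
    rng = np.random.default_rng(77)
    hits = 0
    n_reps = 400
    for _ in range(n_reps):
        scores = np.concatenate([rng.normal(delta, 1, 60), rng.normal(0, 1, 140)])
        labels = np.concatenate([np.ones(60, int), np.zeros(140, int)])
        r = auc_confidence_interval(scores, labels)
        hits += r.ci_low <= true_auc <= r.ci_high
    assert hits / n_reps >= 0.93


def test_ci_requires_two_per_class():
    with pytest.raises(EvaluationError):
        auc_confidence_interval([1, 2, 3], [1, 0, 0])


# ---------------------------------------------------------------------------
# Quartiles and incidence


def test_quartiles_of_1_to_8_are_balanced():
    labels, bounds = assign_quartiles(np.arange(1, 9))
    assert np.bincount(labels)[1:].tolist() == [2, 2, 2, 2]
    assert bounds == (2.75, 4.5, 6.25)


def test_boundary_ties_go_to_lower_quartile():
    scores = np.array([1.0, 2, 2, 3, 4, 5, 6, 7])
    labels, (q25, _, _) = assign_quartiles(scores)
    assert q25 == 2.0
    assert (labels[scores == q25] == 1).all()


def test_degenerate_scores_all_in_first_quartile():
    with pytest.warns(UserWarning, match="degenerate"):
        labels, _ = assign_quartiles(np.full(10, 7.0))
    assert (labels == 1).all()


def test_empty_scores_rejected():
    with pytest.raises(EvaluationError):
        assign_quartiles([])


def test_quantile_defining_property_on_synthetic_scores():
    """At most 25% of scores lie strictly below the first cut and at least
    25% lie at or below it (analogously for the other cuts); with heavy
    integer ties the quartile sizes need not be n/4."""
    coh = generate_cohort(SyntheticConfig.for_cohort("cvhs_like", n=10_000, seed=13))
    s = score_cohort(coh, build_scorecard("anu_adri_cvhs")).to_numpy()
    labels, bounds = assign_quartiles(s)
    n = len(s)
    for frac, q in zip((0.25, 0.5, 0.75), bounds):
        assert (s < q).sum() <= frac * n <= (s <= q).sum()
    assert sorted(np.unique(labels)) == [1, 2, 3, 4]


def test_quartile_sizes_near_balanced_for_continuous_scores():
    rng = np.random.default_rng(31)
    labels, _ = assign_quartiles(rng.normal(size=10_000))
    counts = np.bincount(labels)[1:]
    se = np.sqrt(10_000 * 0.25 * 0.75)
    assert (np.abs(counts - 2_500) <= 3 * se).all()


def test_incidence_arithmetic():
    rates = incidence_rates([50.0, 50.0], [1, 1], [1, 1])
    assert rates[1]["incidence_per_1000py"] == pytest.approx(20.0)
    assert not rates[1]["zero_events"]


def test_incidence_zero_events_flagged():
    rates = incidence_rates([10.0, 10.0], [0, 0], [1, 1])
    assert rates[1]["incidence_per_1000py"] == 0.0
    assert rates[1]["zero_events"]


def test_incidence_sum_rule():
    coh = generate_cohort(SyntheticConfig.for_cohort("map_like", n=2_000, seed=14))
    s = score_cohort(coh, build_scorecard("anu_adri_map"))
    labels, _ = assign_quartiles(s)
    rates = incidence_rates(coh["followup_years"], coh["event_ad"], labels)
    assert sum(r["events"] for r in rates.values()) == coh["event_ad"].sum()
    assert sum(r["person_years"] for r in rates.values()) == pytest.approx(
        coh["followup_years"].sum())
    assert sum(r["n"] for r in rates.values()) == len(coh)


# ---------------------------------------------------------------------------
# Cox


def _cox_df(time, status, x):
    return pd.DataFrame({"followup_years": time, "event_ad": status,
                         "event_dementia": status})


def test_cox_three_subject_analytic_example():
    """Single binary covariate, subjects (t=1, event, x=1), (t=2, event,
    x=0), (t=3, censored, x=1): the partial likelihood e^b/(2e^b+1) x
    1/(1+e^b) is maximised at b = -ln(2)/2."""
    df = _cox_df([1.0, 2.0, 3.0], [1, 1, 0], None)
    fit = fit_score_coefficient(df, [1.0, 0.0, 1.0], "ad")
    assert fit["coef"] == pytest.approx(-0.5 * np.log(2.0), abs=1e-6)


def test_cox_matches_grid_oracle_on_small_instances():
    rng = np.random.default_rng(99)
    checked = 0
    while checked < 25:
        inst = random_small_cox_instance(rng)
        if inst is None:
            continue
        time, status, x, oracle = inst
        fit = fit_score_coefficient(_cox_df(time, status, None), x, "ad")
        assert fit["coef"] == pytest.approx(oracle, abs=1e-6)
        checked += 1


def test_cox_quartile_recovers_dose_response():
    coh = generate_cohort(SyntheticConfig.for_cohort(
        "cvhs_like", n=5_000, seed=15, beta_per_point=0.08))
    s = score_cohort(coh, build_scorecard("anu_adri_cvhs"))
    qa = cox_quartile_hr(coh, s, outcome="ad")
    hrs = [qa.quartiles[q]["hazard_ratio"] for q in (2, 3, 4)]
    assert qa.quartiles[1]["hazard_ratio"] == 1.0
    assert 1.0 < hrs[0] < hrs[1] < hrs[2]
    assert qa.trend_p < 1e-3
    rates = [qa.quartiles[q]["incidence_per_1000py"] for q in (1, 2, 3, 4)]
    assert rates == sorted(rates)


def test_cox_no_contrast_degenerates_cleanly():
    df = _cox_df([1.0, 2.0, 3.0, 4.0] * 3, [1, 0, 1, 0] * 3, None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        qa = cox_quartile_hr(df, np.full(12, 5.0), outcome="ad")
    assert "degenerate_quartiles" in qa.flags
    assert qa.trend_p == 1.0
    assert all(qa.quartiles[q]["hazard_ratio"] == 1.0 for q in (1, 2, 3, 4))


def test_cox_requires_reference_events():
    coh = generate_cohort(SyntheticConfig.for_cohort("cvhs_like", n=200, seed=16))
    s = score_cohort(coh, build_scorecard("anu_adri_cvhs"))
    df = coh.copy()
    labels, _ = assign_quartiles(s)
    df.loc[labels == 1, "event_ad"] = 0
    with pytest.raises(EvaluationError, match="reference quartile"):
        cox_quartile_hr(df, s, outcome="ad")


def test_breslow_agrees_with_lifelines_without_ties():
    """With continuous (tie-free) times the Breslow and Efron likelihoods
    coincide, so lifelines provides an independent check."""
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(8)
    n = 400
    x = rng.normal(size=n)
    time = rng.exponential(np.exp(-0.5 * x))
    status = (rng.random(n) < 0.7).astype(int)
    df = _cox_df(time, status, None)
    fit = fit_score_coefficient(df, x, "ad")
    ldf = pd.DataFrame({"T": time, "E": status, "x": x})
    cph = CoxPHFitter().fit(ldf, duration_col="T", event_col="E")
    assert fit["coef"] == pytest.approx(float(cph.params_["x"]), abs=1e-5)


# ---------------------------------------------------------------------------
# Filtering


def _toy_cohort(n=10):
    cfg = SyntheticConfig.for_cohort("cvhs_like", n=n, seed=17)
    return generate_cohort(cfg)


def test_filter_removes_baseline_dementia():
    df = _toy_cohort(10)
    df.loc[df.index[0], "baseline_dementia"] = 1
    card = build_scorecard("anu_adri_cvhs")
    out, log = filter_analysis_set(df, card)
    assert len(out) == 9
    assert log["baseline_dementia"] == 1
    assert log["analyzed_n"] == 9


def test_filter_is_identity_on_complete_data():
    df = _toy_cohort(10)
    out, log = filter_analysis_set(df, build_scorecard("anu_adri_cvhs"))
    assert len(out) == 10
    assert log == {"input_n": 10, "baseline_dementia": 0, "missing_outcome": 0,
                   "incomplete_factors": 0, "analyzed_n": 10}


def test_filter_complete_case_fraction_matches_map():
    """Missingness injected at the observed MAP rate leaves about 903 of
    1164 records (the published complete-case fraction), within 3 SE."""
    target = 903 / 1164
    cfg = SyntheticConfig.for_cohort("map_like", n=1_164, seed=18,
                                     missingness=1 - target)
    coh = generate_cohort(cfg)
    out, log = filter_analysis_set(coh, build_scorecard("anu_adri_map"))
    se = np.sqrt(target * (1 - target) / 1_164)
    assert abs(len(out) / 1_164 - target) <= 3 * se
    assert log["incomplete_factors"] + log["analyzed_n"] == 1_164


# ---------------------------------------------------------------------------
# evaluate_index and the age split


def test_evaluate_index_null_discrimination():
    cfg = SyntheticConfig.for_cohort("cvhs_like", n=6_000, seed=19, beta_per_point=0.0)
    coh = generate_cohort(cfg)
    report = evaluate_index(coh, build_scorecard("anu_adri_cvhs"))
    for outcome in ("ad", "any_dementia"):
        block = report["outcomes"][outcome]
        assert abs(block["overall"]["auc"] - 0.5) < 0.05
        assert {"overall", "male", "female", "common_variables"} <= set(block)


def test_common_variable_auc_uses_same_participants():
    coh = _toy_cohort(800)
    report = evaluate_index(coh, build_scorecard("anu_adri_cvhs"))
    block = report["outcomes"]["ad"]
    full_n = block["overall"]["n_cases"] + block["overall"]["n_controls"]
    common_n = (block["common_variables"]["n_cases"]
                + block["common_variables"]["n_controls"])
    assert full_n == common_n == report["exclusions"]["analyzed_n"]
    assert block["common_minus_full_auc"] == pytest.approx(
        block["common_variables"]["auc"] - block["overall"]["auc"])


def test_chi_square_independence():
    chi2, p = chi_square_2x2([[10, 10], [10, 10]])
    assert chi2 == 0.0 and p == pytest.approx(1.0)


def test_chi_square_hand_computed():
    """[[20, 80], [40, 60]]: n(ad-bc)^2 / product of margins = 9.5238..."""
    chi2, p = chi_square_2x2([[20, 80], [40, 60]])
    assert chi2 == pytest.approx(200 * (20 * 60 - 80 * 40) ** 2 / (100 * 100 * 60 * 140))
    assert chi2 == pytest.approx(9.5238, abs=1e-4)
    assert p == pytest.approx(0.002, abs=5e-4)


def test_chi_square_empty_margin_rejected():
    with pytest.raises(EvaluationError, match="margin"):
        chi_square_2x2([[0, 0], [10, 10]])


def test_age_split_null_rates_mostly_nonsignificant():
    """With no age effect beyond the score itself, per-quartile young vs
    old case-rate chi-squares should rarely reject."""
    nonsig = 0
    total = 0
    for seed in range(6):
        coh = generate_cohort(SyntheticConfig.for_cohort(
            "cvhs_like", n=3_000, seed=40 + seed, beta_per_point=0.0))
        s = score_cohort(coh, build_scorecard("anu_adri_cvhs"))
        comp = age_split_comparison(coh, s, split_age=70)
        for q in (1, 2, 3, 4):
            p = comp.quartiles[q]["p_value"]
            if p is not None:
                total += 1
                nonsig += p > 0.05
    assert nonsig / total > 0.8


def test_age_split_percentages_consistent():
    coh = _toy_cohort(2_000)
    s = score_cohort(coh, build_scorecard("anu_adri_cvhs"))
    comp = age_split_comparison(coh, s)
    for q, d in comp.quartiles.items():
        if d["n_young"]:
            assert d["pct_young"] == pytest.approx(100 * d["cases_young"] / d["n_young"])
    assert sum(d["n_young"] + d["n_old"] for d in comp.quartiles.values()) == 2_000


def test_age_split_requires_both_groups():
    coh = _toy_cohort(100)
    s = score_cohort(coh, build_scorecard("anu_adri_cvhs"))
    with pytest.raises(EvaluationError):
        age_split_comparison(coh, s, split_age=30)
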