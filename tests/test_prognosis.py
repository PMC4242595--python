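"""IHC scoring, association tests, Kaplan-Meier, log-rank, Cox regression."""

import math

import numpy as np
import pandas as pd
import pytest

from dgekit.config import SimulationConfig
from dgekit.prognosis import (
    chi_square_test,
    cox_fit,
    fisher_exact_2x2,
    kaplan_meier,
    logrank_test,
    marker_combination,
    proportion_score,
    staining_index,
    association_tests,
)
from dgekit.simulate import simulate_cohort


# ---------------------------------------------------------------- scoring
@pytest.mark.parametrize(
    "pct, expected",
    [(0, 0), (3, 1), (5, 1), (5.5, 2), (6, 2), (25, 2), (30, 3), (50, 3),
     (51, 4), (75, 4), (80, 5), (100, 5)],
)
def test_proportion_bins(pct, expected):
    assert proportion_score(pct) == expected


def test_staining_index_product_and_group():
    s = staining_index(80, 3)
    assert (s.proportion_score, s.staining_index, s.group) == (5, 15, "high")
    s4 = staining_index(30, 1)  # 3 * 1 = 3 -> low
    assert (s4.staining_index, s4.group) == (3, "low")
    s5 = staining_index(45, 2)  # 3 * 2 = 6 -> high
    assert (s5.staining_index, s5.group) == (6, "high")
    for grade in (0, 1, 2, 3):
        s0 = staining_index(0, grade)
        assert (s0.staining_index, s0.group) == (0, "low")


def test_staining_index_sum_alternative():
    s = staining_index(30, 1, combine="sum")
    assert s.staining_index == 4 and s.group == "low"


def test_staining_index_input_validation():
    with pytest.raises(ValueError):
        staining_index(120, 1)
    with pytest.raises(ValueError):
        staining_index(50, 5)


# ----------------------------------------------------------- associations
def test_fisher_perfect_independence_is_one():
    assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)


def test_fisher_perfect_separation_closed_form():
    # both extreme tables have probability 1/C(20,10); two-sided doubles it
    assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(
        2.0 / math.comb(20, 10), rel=1e-10
    )


def test_chi_square_matches_textbook_formula_on_random_tables():
    rng = np.random.default_rng(17)
    for _ in range(30):
        table = rng.integers(1, 30, size=(2, 3)).astype(float)
        stat, p = chi_square_test(table)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        stat_ref = ((table - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(stat_ref, rel=1e-10)
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf(stat_ref, df=2), rel=1e-10)


def test_chi_square_refuses_empty_column():
    with pytest.raises(ValueError, match="empty"):
        chi_square_test([[0, 3, 4], [0, 2, 5]])


def test_association_table_structure():
    cohort = simulate_cohort(SimulationConfig(seed=5))
    for m in ("ALDH2", "CCNE1", "SMAD3"):
        scores = [
            staining_index(p, int(g)).group
            for p, g in zip(cohort[f"{m}_proportion_pct"],
                            cohort[f"{m}_intensity_grade"])
        ]
        cohort[f"{m}_group"] = scores
    table = association_tests(cohort)
    assert set(table["test"]) == {"fisher", "chi-square"}
    assert ((table["p"] >= 0) & (table["p"] <= 1)).all()
    # markers load on a shared latent factor: marker-marker association
    # should be detectable in at least one pair
    marker_rows = table[(table["test"] == "fisher")
                        & table["var_b"].isin(["CCNE1", "SMAD3"])]
    assert (marker_rows["p"] < 0.05).any()


# ------------------------------------------------------------ Kaplan-Meier
def km_survival_at(curves, group, t):
    c = curves[group]
    past = c[c["time"] <= t]
    return past["survival"].iloc[-1]


def test_km_two_deaths_no_censoring():
    rec = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1], "g": ["a", "a"]})
    curves = kaplan_meier(rec, "g")
    assert km_survival_at(curves, "a", 1.0) == pytest.approx(0.5)
    assert km_survival_at(curves, "a", 2.0) == pytest.approx(0.0)


def test_km_all_censored_stays_at_one():
    rec = pd.DataFrame({"time": [3.0, 5.0, 9.0], "event": [0, 0, 0], "g": "a"})
    curves = kaplan_meier(rec, "g")
    assert (curves["a"]["survival"] == 1.0).all()


def test_km_mixed_censoring_hand_fixture():
    # events at 2, 5, 8; censored at 3 and 10:
    # S(2) = 4/5; S(5) = 4/5 * 2/3 = 8/15; S(8) = 8/15 * 1/2 = 4/15
    rec = pd.DataFrame(
        {"time": [2.0, 3.0, 5.0, 8.0, 10.0], "event": [1, 0, 1, 1, 0], "g": "a"}
    )
    curves = kaplan_meier(rec, "g")
    assert km_survival_at(curves, "a", 2) == pytest.approx(4 / 5)
    assert km_survival_at(curves, "a", 5) == pytest.approx(8 / 15)
    assert km_survival_at(curves, "a", 8) == pytest.approx(4 / 15)
    assert km_survival_at(curves, "a", 10) == pytest.approx(4 / 15)


def test_km_without_censoring_equals_empirical_survival():
    rng = np.random.default_rng(9)
    times = rng.exponential(10, size=30).round(2) + 0.01
    rec = pd.DataFrame({"time": times, "event": 1, "g": "a"})
    curves = kaplan_meier(rec, "g")
    for t in np.quantile(times, [0.2, 0.5, 0.9]):
        emp = (times > t).mean()
        assert km_survival_at(curves, "a", t) == pytest.approx(emp, abs=1e-10)


def test_km_rejects_nonpositive_times():
    rec = pd.DataFrame({"time": [0.0, 2.0], "event": [1, 1], "g": "a"})
    with pytest.raises(ValueError):
        kaplan_meier(rec, "g")


# ---------------------------------------------------------------- log-rank
def logrank_by_hand(time, event, in_group1):
    """Observed-minus-expected over risk sets, hypergeometric variance."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g1 = np.asarray(in_group1, dtype=bool)
    O = E = V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n, n1 = at_risk.sum(), (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def test_logrank_identical_groups_is_null():
    times = [1.0, 2.0, 3.0, 4.0]
    rec = pd.DataFrame(
        {"time": times + times, "event": [1] * 8, "g": ["a"] * 4 + ["b"] * 4}
    )
    stat, p = logrank_test(rec, "g")
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_hand_computation_n8():
    rec = pd.DataFrame(
        {
            "time": [1.0, 3.0, 4.0, 7.0, 2.0, 5.0, 6.0, 9.0],
            "event": [1, 1, 0, 1, 1, 1, 1, 0],
            "g": ["a"] * 4 + ["b"] * 4,
        }
    )
    stat, p = logrank_test(rec, "g")
    want = logrank_by_hand(rec["time"], rec["event"], rec["g"] == "a")
    assert stat == pytest.approx(want, rel=1e-9)


def test_logrank_invariant_to_group_relabeling():
    rng = np.random.default_rng(23)
    rec = pd.DataFrame(
        {
            "time": rng.exponential(10, 30) + 0.1,
            "event": rng.integers(0, 2, 30),
            "g": rng.choice(["a", "b"], 30),
        }
    )
    rec.loc[rec.index[0], "event"] = 1
    s1, p1 = logrank_test(rec, "g")
    flipped = rec.assign(g=rec["g"].map({"a": "b", "b": "a"}))
    s2, p2 = logrank_test(flipped, "g")
    assert s1 == pytest.approx(s2, rel=1e-12)


def test_logrank_single_group_refused():
    rec = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1], "g": "a"})
    with pytest.raises(ValueError):
        logrank_test(rec, "g")


# -------------------------------------------------------------------- Cox
def efron_partial_loglik(beta, time, event, x):
    """One-covariate Efron partial log-likelihood on a beta grid."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = np.zeros_like(beta)
    eb = np.exp(np.outer(beta, x))  # (B, n)
    for t in np.unique(time[event == 1]):
        D = (time == t) & (event == 1)
        R = time >= t
        d = D.sum()
        s_r = eb[:, R].sum(axis=1)
        s_d = eb[:, D].sum(axis=1)
        ll += beta * x[D].sum()
        for l in range(d):
            ll -= np.log(s_r - (l / d) * s_d)
    return ll


def test_cox_single_covariate_matches_grid_search_n12():
    rng = np.random.default_rng(31)
    x = np.array([0, 1] * 6, dtype=float)
    time = rng.exponential(1.0 / np.exp(0.8 * x)).round(1) + 0.1
    event = np.ones(12, dtype=int)
    rec = pd.DataFrame({"time": time, "event": event, "x": x})
    fit = cox_fit(rec, ["x"])
    coarse = np.linspace(-4, 4, 801)
    b0 = coarse[np.argmax(efron_partial_loglik(coarse, time, event, x))]
    fine = np.linspace(b0 - 0.02, b0 + 0.02, 4001)
    b_star = fine[np.argmax(efron_partial_loglik(fine, time, event, x))]
    assert fit.summary["coef"].iloc[0] == pytest.approx(b_star, abs=1e-4)


def test_efron_and_breslow_agree_without_ties():
    rng = np.random.default_rng(13)
    n = 60
    x = rng.normal(size=n)
    time = rng.exponential(1.0 / np.exp(0.5 * x))  # continuous: no ties
    rec = pd.DataFrame({"time": time, "event": 1, "x": x})
    fe = cox_fit(rec, ["x"], ties="efron")
    fb = cox_fit(rec, ["x"], ties="breslow")
    assert fe.summary["coef"].iloc[0] == pytest.approx(
        fb.summary["coef"].iloc[0], abs=1e-10
    )


def test_cox_null_rejection_rate_calibrated():
    """Zero-effect covariate: Wald test rejects at ~alpha."""
    rng = np.random.default_rng(77)
    rejections = 0
    n_rep = 500
    for _ in range(n_rep):
        n = 100
        x = (rng.random(n) < 0.5).astype(float)
        time = rng.exponential(10.0, size=n)
        censor = rng.exponential(30.0, size=n)
        rec = pd.DataFrame(
            {"time": np.minimum(time, censor), "event": (time <= censor).astype(int),
             "x": x}
        )
        fit = cox_fit(rec, ["x"])
        rejections += fit.summary["p"].iloc[0] < 0.05
    assert 0.03 <= rejections / n_rep <= 0.07


def test_cox_categorical_t_stage_coded_against_t3():
    rng = np.random.default_rng(3)
    rec = pd.DataFrame(
        {
            "time": rng.exponential(10, 60) + 0.1,
            "event": 1,
            "t_stage": rng.choice(["T1", "T2", "T3"], 60),
        }
    )
    fit = cox_fit(rec, ["t_stage"])
    assert list(fit.summary.index) == ["t_stage[T1 vs T3]", "t_stage[T2 vs T3]"]


def test_cox_zero_events_refused():
    rec = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
    with pytest.raises(ValueError):
        cox_fit(rec, ["x"])


def test_cox_constant_covariate_refused():
    rec = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1], "x": 1.0})
    with pytest.raises(ValueError, match="constant"):
        cox_fit(rec, ["x"])


def test_cox_complete_separation_flagged():
    # the covariate perfectly orders survival: monotone likelihood
    rec = pd.DataFrame(
        {"time": np.arange(1.0, 13.0), "event": 1,
         "x": [1.0] * 6 + [0.0] * 6}
    )
    fit = cox_fit(rec, ["x"])
    assert not fit.converged
    assert fit.message


# --------------------------------------------------------- marker stratum
def _cohort_with_groups(seed=5, **kwargs):
    cfg = SimulationConfig(seed=seed, **kwargs)
    cohort = simulate_cohort(cfg)
    for m in ("ALDH2", "CCNE1", "SMAD3"):
        cohort[f"{m}_group"] = [
            staining_index(p, int(g)).group
            for p, g in zip(cohort[f"{m}_proportion_pct"],
                            cohort[f"{m}_intensity_grade"])
        ]
    return cohort


def test_marker_combination_is_pure_function_of_groups():
    cohort = _cohort_with_groups()
    res = marker_combination(cohort)
    high = (
        (cohort["ALDH2_group"] == "low")
        & (cohort["CCNE1_group"] == "high")
        & (cohort["SMAD3_group"] == "high")
    )
    assert (res["strata"] == high.map({True: "high-risk", False: "other"})).all()
    assert res["n_high_risk"] + res["n_other"] == len(cohort)


def test_marker_combination_single_stratum_refused():
    cohort = _cohort_with_groups()
    for m in ("ALDH2", "CCNE1", "SMAD3"):
        cohort[f"{m}_group"] = "high"
    with pytest.raises(ValueError, match="single"):
        marker_combination(cohort)


def test_combined_marker_power_similar_to_best_single_under_shared_risk():
    """With a strongly shared latent risk factor the markers nearly
    coincide, so the combined stratification adds little over the best
    single marker (log-rank statistics within +/-20%)."""
    cohort = _cohort_with_groups(seed=19, cohort_size=400, marker_latent_rho=0.9)
    single = max(
        logrank_test(cohort, f"{m}_group")[0] for m in ("ALDH2", "CCNE1", "SMAD3")
    )
    combined = marker_combination(cohort)["logrank_statistic"]
    assert abs(combined - single) / single <= 0.20
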