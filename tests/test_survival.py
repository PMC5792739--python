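"""Survival-screen unit tests: partial-likelihood oracle, BH, KM, intersection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossmeta import survival as surv
from crossmeta import synthetic as syn


# ---------------------------------------------------------------------------
# brute-force partial-likelihood oracle (independent of the Newton fitter)

def breslow_log_partial_likelihood(beta, x, time, event):
    """Hand-written Breslow log partial likelihood for one covariate."""
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        d_idx = np.flatnonzero((time == t) & (event == 1))
        risk = np.flatnonzero(time >= t)
        ll += beta * x[d_idx].sum()
        ll -= len(d_idx) * np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def grid_search_beta(x, time, event, lo=-4.0, hi=4.0, step=1e-4):
    grid = np.arange(lo, hi + step, step)
    lls = [breslow_log_partial_likelihood(b, x, time, event) for b in grid]
    return grid[int(np.argmax(lls))]


SMALL_INSTANCES = [
    # (expression, time, event): n <= 10, mixes ties and censoring
    (np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0]),
     np.array([1.0, 4, 5, 8, 2, 3, 6, 7]),
     np.ones(8, dtype=int)),
    (np.array([1.0, 2, 3, 4, 5, 6]),
     np.array([3.0, 1, 4, 1, 5, 9]),
     np.array([1, 1, 0, 1, 1, 1])),
    (np.array([-1.0, 0.5, 0.5, 2, -2, 0, 1, -1, 0.3, 0.7]),
     np.array([2.0, 2, 3, 1, 5, 4, 2, 6, 3, 7]),
     np.array([1, 0, 1, 1, 1, 0, 1, 1, 1, 0])),
    (np.array([0.2, -0.4, 1.1, 0.0, -1.3]),
     np.array([1.0, 1, 2, 2, 3]),
     np.array([1, 1, 1, 0, 1])),
]


@pytest.mark.parametrize("x,time,event", SMALL_INSTANCES)
def test_cox_matches_brute_force_grid_search(x, time, event):
    """Newton beta-hat equals exhaustive grid maximisation to 1e-4."""
    ws = surv.CoxWorkspace(time, event)
    beta, _, _, _, score = ws.fit(x, ties="breslow")
    beta_grid = grid_search_beta(x, time, event)
    assert abs(beta[0] - beta_grid) <= 1e-4 + 1e-12
    assert score < 1e-6


def test_two_group_toy_no_censoring():
    """8-sample two-group instance agrees with the hand-written likelihood."""
    x, time, event = SMALL_INSTANCES[0]
    ws = surv.CoxWorkspace(time, event)
    beta, _, ll, _, _ = ws.fit(x, ties="breslow")
    assert ll == pytest.approx(
        breslow_log_partial_likelihood(beta[0], x, time, event), abs=1e-9)


def test_cox_agrees_with_lifelines():
    """Independent cross-check of coefficients and SEs on continuous data."""
    from lifelines import CoxPHFitter

    cohort = syn.simulate_cohort(syn.CohortSimSpec(
        n_patients=150, n_genes=3, effect_genes={0: -0.5}, seed=3))
    df = pd.DataFrame({
        "x": cohort.expression.iloc[0].to_numpy(),
        "age": cohort.survival["age"].to_numpy(),
        "T": cohort.survival["time"].to_numpy(),
        "E": cohort.survival["event"].to_numpy(),
    })
    cph = CoxPHFitter()
    cph.fit(df, "T", "E")
    ws = surv.CoxWorkspace(df["T"].to_numpy(), df["E"].to_numpy())
    beta, se, _, _, _ = ws.fit(df[["x", "age"]].to_numpy(), ties="efron")
    np.testing.assert_allclose(beta, cph.params_.to_numpy(), atol=2e-5)
    np.testing.assert_allclose(se, cph.standard_errors_.to_numpy(), rtol=1e-4)


def test_effect_recovery_within_3_se():
    """A single planted effect of -0.7 at n=500 is recovered."""
    cohort = syn.simulate_cohort(syn.CohortSimSpec(
        n_patients=500, n_genes=5, effect_genes={0: -0.7}, seed=11))
    res = surv.fit_cox_single_gene(
        cohort.expression.iloc[0].to_numpy(),
        cohort.survival["time"].to_numpy(),
        cohort.survival["event"].to_numpy())
    se = (np.log(res.ci_high) - np.log(res.ci_low)) / (2 * 1.959964)
    assert abs(np.log(res.hr) - (-0.7)) < 3 * se


def test_constant_expression_not_estimable():
    res = surv.fit_cox_single_gene(
        np.ones(20), np.arange(1.0, 21), np.ones(20, dtype=int))
    assert not res.estimable
    assert np.isnan(res.hr)


def test_no_events_raises():
    with pytest.raises(surv.NonEstimableError):
        surv.CoxWorkspace(np.arange(1.0, 6), np.zeros(5, dtype=int))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg

def test_bh_hand_values():
    np.testing.assert_allclose(surv.bh_adjust([0.05]), [0.05])
    np.testing.assert_allclose(surv.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


def test_bh_permutation_invariant_and_bounded(rng):
    p = rng.uniform(size=57)
    q = surv.bh_adjust(p)
    perm = rng.permutation(57)
    np.testing.assert_allclose(surv.bh_adjust(p[perm]), q[perm])
    assert np.all(q <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)
    assert np.all(q >= p - 1e-15)


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        surv.bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# screen and intersection

def test_screen_null_calibration():
    """All-null cohort: p-values uniform (KS) and BH at 0.1 nearly silent."""
    cohort = syn.simulate_cohort(syn.CohortSimSpec(
        n_patients=300, n_genes=200, seed=21))
    res = surv.run_cohort_screen(cohort)
    ks = stats.kstest(res["p"], "uniform")
    assert ks.pvalue > 0.01
    assert (res["fdr"] < 0.1).sum() <= 5


def test_screen_power_run():
    """Ten strong co-expressed effects all reach FDR < 0.1 at n=400."""
    effects = {i: (-0.9 if i % 2 else 0.9) for i in range(10)}
    cohort = syn.simulate_cohort(syn.CohortSimSpec(
        n_patients=400, n_genes=300, effect_genes=effects,
        effect_correlation=0.3, seed=5))
    res = surv.run_cohort_screen(cohort)
    hits = res.loc[[f"G{i:05d}" for i in range(10)]]
    assert (hits["fdr"] < 0.1).all()


def test_screen_excludes_constant_gene():
    cohort = syn.simulate_cohort(syn.CohortSimSpec(
        n_patients=60, n_genes=10, seed=2))
    cohort.expression.iloc[3] = 1.5
    res = surv.run_cohort_screen(cohort)
    assert "G00003" not in res.index
    assert len(res) == 9


def test_intersect_cohorts_direction_flags():
    def table(hrs, fdrs):
        genes = [f"g{i}" for i in range(len(hrs))]
        return pd.DataFrame({"hr": hrs, "ci_low": hrs, "ci_high": hrs,
                             "p": fdrs, "fdr": fdrs},
                            index=pd.Index(genes, name="gene"))

    res_a = table([0.5, 0.5, 0.9], [0.01, 0.01, 0.5])
    res_b = table([0.6, 1.5, 0.9], [0.01, 0.01, 0.5])
    out = surv.intersect_cohorts(res_a, res_b, 0.1)
    assert list(out.index) == ["g0", "g1"]
    assert out.loc["g0", "same_direction"]
    assert not out.loc["g1", "same_direction"]
    assert out.attrs["fraction_same_direction"] == pytest.approx(0.5)


def test_intersect_disjoint_significant_sets_empty():
    a = pd.DataFrame({"hr": [0.5, 2.0], "fdr": [0.01, 0.9]},
                     index=pd.Index(["g0", "g1"], name="gene"))
    b = pd.DataFrame({"hr": [0.5, 2.0], "fdr": [0.9, 0.01]},
                     index=pd.Index(["g0", "g1"], name="gene"))
    assert len(surv.intersect_cohorts(a, b, 0.1)) == 0
    with pytest.raises(ValueError):
        surv.intersect_cohorts(a, b.set_axis(["h0", "h1"]), 0.1)


# ---------------------------------------------------------------------------
# Kaplan-Meier median split

def test_km_matches_hand_product_limit():
    """6-sample toy: KM steps equal the hand product-limit computation."""
    expr = np.array([0.0, 0.0, 0.0, 2.0, 2.0, 2.0])
    time = np.array([2.0, 4.0, 6.0, 1.0, 3.0, 5.0])
    event = np.array([1, 1, 0, 1, 0, 1])
    km_low, km_high, _ = surv.km_median_split(expr, time, event)
    # low stratum (expr 0): events at 2, 4; censored at 6
    # S(2) = 1 - 1/3 = 2/3 ; S(4) = 2/3 * (1 - 1/2) = 1/3
    low = dict(zip(km_low["time"], km_low["survival"]))
    assert low[2.0] == pytest.approx(2 / 3)
    assert low[4.0] == pytest.approx(1 / 3)
    # high stratum: event at 1 (3 at risk) -> 2/3; censored at 3; event at 5
    # with a single subject left at risk -> 0
    high = dict(zip(km_high["time"], km_high["survival"]))
    assert high[1.0] == pytest.approx(2 / 3)
    assert high[5.0] == pytest.approx(0.0)


def test_km_direction_for_protective_gene():
    """Low expression of a protective gene carries the higher hazard."""
    cohort = syn.simulate_cohort(syn.CohortSimSpec(
        n_patients=400, n_genes=2, effect_genes={0: -1.0}, seed=9))
    _, _, res = surv.km_median_split(
        cohort.expression.iloc[0].to_numpy(),
        cohort.survival["time"].to_numpy(),
        cohort.survival["event"].to_numpy())
    assert res.hr > 1.0


def test_km_identical_strata_hr_near_one(rng):
    time = rng.exponential(10, size=200)
    event = np.ones(200, dtype=int)
    expr = np.tile([0.0, 1.0], 100)  # split independent of survival
    _, _, res = surv.km_median_split(expr, time, event)
    se = (np.log(res.ci_high) - np.log(res.ci_low)) / (2 * 1.959964)
    assert abs(np.log(res.hr)) < 3 * se


# ---------------------------------------------------------------------------
# Wald p reconstruction

def test_wald_p_round_trip_with_fit():
    cohort = syn.simulate_cohort(syn.CohortSimSpec(
        n_patients=200, n_genes=2, effect_genes={0: -0.6}, seed=13))
    res = surv.fit_cox_single_gene(
        cohort.expression.iloc[0].to_numpy(),
        cohort.survival["time"].to_numpy(),
        cohort.survival["event"].to_numpy())
    p = surv.wald_p_from_hr_ci(res.hr, res.ci_low, res.ci_high)
    assert p == pytest.approx(res.p, rel=1e-6)


def test_wald_p_symmetric_ci_about_one():
    assert surv.wald_p_from_hr_ci(1.0, 0.5, 2.0) == pytest.approx(1.0)


def test_wald_p_rejects_bad_bounds():
    with pytest.raises(ValueError):
        surv.wald_p_from_hr_ci(0.5, 0.6, 0.7)
    with pytest.raises(ValueError):
        surv.wald_p_from_hr_ci(-1.0, -2.0, 1.0)
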