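"""Kaplan-Meier, log-rank and Cox against hand oracles and lifelines."""

import numpy as np
import pandas as pd
import pytest

from nbtsig import (
    DataError,
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
    screen_then_multivariate,
    survival_at,
)

from oracles import km_oracle, logrank_oracle


def _dataset(rng, n=120, beta=np.log(2.0), censor_scale=40.0):
    z = (rng.random(n) < 0.5).astype(float)
    t_event = rng.exponential(1 / (0.03 * np.exp(beta * z)))
    t_cens = rng.exponential(censor_scale, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"z": z}), time, event


# ---------------------------------------------------------------- Kaplan-Meier

def test_km_all_censored_stays_at_one():
    km = km_estimate([3.0, 5.0, 8.0], [0, 0, 0])
    assert km.table.empty
    assert survival_at(km, 100.0) == 1.0


def test_km_all_events_steps_by_product_limit():
    km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
    np.testing.assert_allclose(km.table["survival"], [2 / 3, 1 / 3, 0.0])


def test_km_matches_hand_oracle(rng):
    time = rng.exponential(20, size=40).round(1) + 0.1
    event = (rng.random(40) < 0.7).astype(int)
    km = km_estimate(time, event)
    expected = km_oracle(time, event)
    np.testing.assert_allclose(
        km.table[["time", "survival"]].to_numpy(), np.array(expected)
    )


def test_km_depends_on_censor_times_only_through_event_order():
    """Moving a censored time anywhere within the same inter-event interval
    (here: anywhere past the last event) leaves the curve unchanged."""
    time = np.array([2.0, 4.0, 6.0, 8.0, 9.0, 10.0])
    event = np.array([1, 1, 0, 1, 0, 0])
    km1 = km_estimate(time, event)
    moved = time.copy()
    moved[4], moved[5] = 500.0, 900.0   # still after the last event at t=8
    km2 = km_estimate(moved, event)
    np.testing.assert_allclose(
        km1.table[["time", "survival"]].to_numpy(),
        km2.table[["time", "survival"]].to_numpy(),
    )


def test_km_rejects_nonpositive_times():
    with pytest.raises(DataError):
        km_estimate([0.0, 1.0], [1, 1])


# -------------------------------------------------------------------- log-rank

def test_logrank_identical_groups_is_null():
    t = [1.0, 2.0, 3.0, 4.0]
    e = [1, 1, 0, 1]
    res = logrank_test([t, t], [e, e])
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_matches_summation_oracle():
    ta, ea = [1.0, 2.0, 3.0], [1, 1, 1]
    tb, eb = [4.0, 5.0, 6.0], [1, 1, 1]
    res = logrank_test([ta, tb], [ea, eb])
    assert res.chi_square == pytest.approx(logrank_oracle(ta, ea, tb, eb),
                                           abs=1e-10)


def test_logrank_matches_oracle_on_random_data(rng):
    for _ in range(10):
        ta = rng.exponential(10, 25).round(0) + 1
        tb = rng.exponential(14, 30).round(0) + 1
        ea = (rng.random(25) < 0.8).astype(int)
        eb = (rng.random(30) < 0.8).astype(int)
        if ea.sum() + eb.sum() == 0:
            continue
        res = logrank_test([ta, tb], [ea, eb])
        assert res.chi_square == pytest.approx(
            logrank_oracle(ta, ea, tb, eb), abs=1e-8
        )


def test_logrank_agrees_with_lifelines(rng):
    from lifelines.statistics import logrank_test as ll_logrank

    ta, tb = rng.exponential(10, 40) + 0.1, rng.exponential(20, 35) + 0.1
    ea = (rng.random(40) < 0.7).astype(int)
    eb = (rng.random(35) < 0.7).astype(int)
    ours = logrank_test([ta, tb], [ea, eb])
    theirs = ll_logrank(ta, tb, ea, eb)
    assert ours.chi_square == pytest.approx(theirs.test_statistic, rel=1e-8)
    assert ours.p_value == pytest.approx(theirs.p_value, rel=1e-8)


def test_logrank_requires_events_and_groups():
    with pytest.raises(DataError):
        logrank_test([[1.0, 2.0]], [[1, 1]])
    with pytest.raises(DataError):
        logrank_test([[1.0], [2.0]], [[0], [0]])


# ------------------------------------------------------------------------- Cox

def test_cox_rejects_constant_covariate():
    x = pd.DataFrame({"z": [0.0, 0.0, 0.0, 0.0]})
    with pytest.raises(DataError, match="constant"):
        cox_fit(x, [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0])


def test_cox_score_test_equals_logrank_for_binary_covariate(rng):
    """Rao score test at beta=0 with Breslow ties reproduces the two-group
    log-rank chi-square (classical identity)."""
    for _ in range(10):
        x, time, event = _dataset(rng, n=60)
        chi2, df, _ = cox_score_test(x, time, event, ties="breslow")
        mask = x["z"].to_numpy() == 1
        lr = logrank_test(
            [time[mask], time[~mask]], [event[mask], event[~mask]]
        )
        assert chi2 == pytest.approx(lr.chi_square, abs=1e-8)


def test_cox_agrees_with_lifelines_efron(rng):
    from lifelines import CoxPHFitter

    x, time, event = _dataset(rng, n=150)
    x["w"] = rng.normal(size=len(time))
    fit = cox_fit(x, time, event, ties="efron")
    df = x.assign(time=time, event=event)
    cph = CoxPHFitter().fit(df, "time", "event")
    np.testing.assert_allclose(
        fit.summary["beta"].to_numpy(),
        cph.params_[["z", "w"]].to_numpy(), atol=1e-6,
    )
    np.testing.assert_allclose(
        fit.summary["se"].to_numpy(),
        cph.standard_errors_[["z", "w"]].to_numpy(), atol=1e-6,
    )
    assert fit.converged


def test_cox_is_invariant_to_time_rescaling(rng):
    x, time, event = _dataset(rng)
    a = cox_fit(x, time, event)
    b = cox_fit(x, 37.5 * time, event)
    np.testing.assert_allclose(
        a.summary["beta"].to_numpy(), b.summary["beta"].to_numpy(), atol=1e-8
    )


def test_cox_confidence_interval_is_wald(rng):
    x, time, event = _dataset(rng)
    fit = cox_fit(x, time, event)
    row = fit.summary.loc["z"]
    assert row["ci_low"] == pytest.approx(
        np.exp(row["beta"] - 1.959963984540054 * row["se"])
    )
    assert row["hr"] == pytest.approx(np.exp(row["beta"]))


def test_cox_flags_separation():
    # group 0 all fails early, group 1 all survives late -> monotone likelihood
    time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    event = np.array([1, 1, 1, 1, 1, 1])
    x = pd.DataFrame({"z": [0.0, 0, 0, 1, 1, 1]})
    fit = cox_fit(x, time, event)
    assert fit.separation_suspected


# ------------------------------------------------------------------- screening

def test_single_qualifying_covariate_reduces_to_univariate(rng):
    x, time, event = _dataset(rng, n=200, beta=np.log(3.0))
    data = x.assign(noise=rng.normal(size=len(time)) * 1e-2,
                    time=time, event=event)
    uni, multi = screen_then_multivariate(
        data, "time", "event", ["z", "noise"])
    assert "z" in uni and "noise" in uni
    if list(multi.summary.index) == ["z"]:
        np.testing.assert_allclose(
            multi.summary.loc["z", "beta"], uni["z"].summary.loc["z", "beta"]
        )


def test_no_qualifying_covariates_yields_empty_model(rng):
    rng2 = np.random.default_rng(1234)
    n = 60
    time = rng2.exponential(30, n) + 0.1
    event = (rng2.random(n) < 0.7).astype(int)
    data = pd.DataFrame(
        {
            "a": np.tile([0.0, 1.0], n // 2),
            "b": np.repeat([0.0, 1.0], n // 2),
            "time": time,
            "event": event,
        }
    )
    uni, multi = screen_then_multivariate(data, "time", "event", ["a", "b"],
                                          screen_p=1e-6)
    assert multi is None
    assert set(uni) == {"a", "b"}


def test_group_covariate_survives_screening_against_noise(rng):
    hits = 0
    for rep in range(10):
        x, time, event = _dataset(rng, n=250, beta=np.log(2.5))
        data = x.assign(noise=rng.normal(size=len(time)),
                        time=time, event=event)
        uni, multi = screen_then_multivariate(
            data, "time", "event", ["z", "noise"])
        if multi is not None and "z" in multi.summary.index:
            hits += 1
    assert hits >= 8
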