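"""Mixed models, likelihood-ratio tests and the group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from clutterlab.stats import (
    ModelSpec,
    FlightCharacteristicsModel,
    fit_mixed_model,
    lrt_compare,
    random_effect_gain,
    ranksum_test,
    compare_groups,
    NestingError,
)


def simulate_table(n_bees=16, n_trials=15, slope=-0.15, env_effect=0.0,
                   bee_sd=0.3, noise_sd=0.2, intercept=4.0, seed=0,
                   environment_id="env1"):
    """Log-linear flight-time data: log y = a + slope*trial + u_bee + eps."""
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_bees):
        u = rng.normal(0.0, bee_sd)
        for trial in range(1, n_trials + 1):
            log_y = intercept + slope * trial + env_effect + u + rng.normal(0.0, noise_sd)
            rows.append({"bee_id": f"{environment_id}-b{b:02d}", "trial": trial,
                         "environment_id": environment_id, "flight_time": np.exp(log_y)})
    return pd.DataFrame(rows)


def two_env_table(seed=0, env_effect=0.0, **kwargs):
    a = simulate_table(seed=seed, environment_id="env1", **kwargs)
    b = simulate_table(seed=seed + 10_000, environment_id="env2", env_effect=env_effect, **kwargs)
    return pd.concat([a, b], ignore_index=True)


# ---- fitting ---------------------------------------------------------------

def test_trial_slope_recovered_within_ci():
    """16 bees x 15 trials, log-slope -0.15: the 95% CI covers the truth."""
    table = simulate_table(seed=1)
    res = fit_mixed_model(table, ModelSpec("flight_time", ("trial",), "bee"))
    lo, hi = res.conf_int().loc["trial"]
    assert lo < -0.15 < hi
    assert res.converged
    assert res.n_obs == 240
    assert 0.0 < res.random_effect_var < 0.3  # truth 0.09; wide band for 16 bees


def test_null_slope_ci_coverage():
    """Slope 0: the CI covers 0 in at least 90 of 100 simulated replicates."""
    hits = 0
    for rep in range(100):
        table = simulate_table(n_bees=10, n_trials=8, slope=0.0, seed=1000 + rep)
        res = fit_mixed_model(table, ModelSpec("flight_time", ("trial",), "bee"))
        lo, hi = res.conf_int().loc["trial"]
        hits += lo < 0.0 < hi
    assert hits >= 90


def test_single_bee_rejected():
    table = simulate_table(n_bees=1)
    with pytest.raises(ValueError, match="bees"):
        FlightCharacteristicsModel(table, ModelSpec("flight_time", ("trial",), "bee"))


def test_missing_responses_dropped_and_counted():
    table = simulate_table(n_bees=6, n_trials=6, seed=3)
    table.loc[table.index[:7], "flight_time"] = np.nan
    res = fit_mixed_model(table, ModelSpec("flight_time", ("trial",), "bee"))
    assert res.n_dropped == 7
    assert res.n_obs == len(table) - 7


def test_row_order_invariance():
    table = simulate_table(n_bees=8, n_trials=8, seed=5)
    shuffled = table.sample(frac=1.0, random_state=9).reset_index(drop=True)
    a = fit_mixed_model(table, ModelSpec("flight_time", ("trial",), "bee"))
    b = fit_mixed_model(shuffled, ModelSpec("flight_time", ("trial",), "bee"))
    assert a.params["trial"] == pytest.approx(b.params["trial"], rel=1e-6)
    assert a.log_likelihood == pytest.approx(b.log_likelihood, rel=1e-8)


def test_gamma_family_fits_fixed_effects():
    table = simulate_table(n_bees=8, n_trials=8, seed=6)
    res = fit_mixed_model(
        table, ModelSpec("flight_time", ("trial",), "none", "gamma_log")
    )
    assert res.converged
    assert -0.25 < res.params["trial"] < -0.05


def test_gamma_family_refuses_random_intercept():
    with pytest.raises(ValueError, match="gamma_log"):
        ModelSpec("flight_time", ("trial",), "bee", "gamma_log")


# ---- likelihood-ratio comparisons -----------------------------------------

def test_identical_models_chi2_zero_p_one():
    table = simulate_table(n_bees=6, n_trials=6, seed=7)
    res = fit_mixed_model(table, ModelSpec("flight_time", ("trial",), "bee"))
    chi2, df, p = lrt_compare(res, res)
    assert chi2 == pytest.approx(0.0, abs=1e-9)
    assert df == 0 and p == 1.0


def test_strong_trial_effect_detected():
    table = two_env_table(seed=2)
    full = fit_mixed_model(table, ModelSpec("flight_time", ("trial", "environment"), "bee"))
    reduced = fit_mixed_model(table, ModelSpec("flight_time", ("environment",), "bee"))
    chi2, df, p = lrt_compare(full, reduced)
    assert df == 1
    assert chi2 > 0.0
    assert p < 0.01


def test_nesting_violations_raise():
    table = two_env_table(seed=3, n_bees=6, n_trials=6)
    full = fit_mixed_model(table, ModelSpec("flight_time", ("trial",), "bee"))
    other = fit_mixed_model(table, ModelSpec("flight_time", ("environment",), "bee"))
    with pytest.raises(NestingError):
        lrt_compare(full, other)
    fewer = fit_mixed_model(table.iloc[: len(table) - 12],
                            ModelSpec("flight_time", (), "bee"))
    with pytest.raises(NestingError):
        lrt_compare(full, fewer)


# ---- random-effect gain ----------------------------------------------------

def test_random_effect_detected_when_present():
    table = simulate_table(bee_sd=0.5, noise_sd=0.2, seed=4)
    chi2, p = random_effect_gain(table, ModelSpec("flight_time", ("trial",), "bee"))
    assert chi2 > 0.0
    assert p < 0.01


def test_random_effect_boundary_null_rarely_significant():
    """With zero bee variance, the halved-tail p is < 0.05 only ~5% of the time."""
    sig = 0
    for rep in range(100):
        table = simulate_table(n_bees=8, n_trials=6, bee_sd=0.0, seed=5000 + rep)
        _, p = random_effect_gain(table, ModelSpec("flight_time", ("trial",), "bee"))
        sig += p < 0.05
    assert sig <= 10


# ---- rank-sum comparisons --------------------------------------------------

def test_ranksum_matches_scipy_asymptotic():
    rng = np.random.default_rng(14)
    for _ in range(20):
        x = np.round(rng.normal(0, 1, rng.integers(8, 25)), 1)  # rounding makes ties
        y = np.round(rng.normal(0.3, 1, rng.integers(8, 25)), 1)
        _, p = ranksum_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=1e-9)


def test_identical_groups_raw_p_near_one():
    table = simulate_table(n_bees=10, n_trials=6, seed=8)
    comps = compare_groups(table, table.copy(), "first", metrics=("flight_time",))
    assert (comps.raw_p > 0.9).all()


def test_bonferroni_definition():
    table = simulate_table(n_bees=10, n_trials=6, seed=8)
    comps = compare_groups(table, table.copy(), "last", m_tests=6, metrics=("flight_time",))
    row = comps.iloc[0]
    assert row.adjusted_p == pytest.approx(min(1.0, row.raw_p * 6))
    assert row.adjusted_p >= row.raw_p


def test_location_shift_detected():
    """15 vs 15 values with a 1-SD shift: raw p < 0.05."""
    rng = np.random.default_rng(15)
    rows1 = [{"bee_id": f"a{i}", "trial": 1, "environment_id": "env1",
              "flight_time": float(np.exp(rng.normal(3.0, 0.3)))} for i in range(15)]
    rows2 = [{"bee_id": f"b{i}", "trial": 1, "environment_id": "env2",
              "flight_time": float(np.exp(rng.normal(3.3, 0.3)))} for i in range(15)]
    comps = compare_groups(pd.DataFrame(rows1), pd.DataFrame(rows2), "first",
                           metrics=("flight_time",))
    assert comps.iloc[0].raw_p < 0.05


def test_first_and_last_select_per_bee_extremes():
    table = simulate_table(n_bees=4, n_trials=6, seed=9)
    table = table[~((table.bee_id == "env1-b00") & (table.trial == 1))]
    from clutterlab.stats import _select_trial
    first = _select_trial(table, "first")
    assert set(first[first.bee_id == "env1-b00"].trial) == {2}
    last = _select_trial(table, "last")
    assert set(last.trial) == {6}


def test_empty_group_raises():
    table = simulate_table(n_bees=4, n_trials=4, seed=10)
    empty = table.iloc[0:0]
    with pytest.raises(ValueError):
        compare_groups(table, empty, "first", metrics=("flight_time",))


# ---- qualitative pattern recovery ------------------------------------------

def test_experience_pattern_recovered_across_metrics():
    """Data generated with a per-trial trend in each characteristic: trial is a
    significant predictor for every one of them."""
    rng = np.random.default_rng(20)
    rows = []
    trends = {"flight_time": -0.15, "speed_sd": -0.05, "sinuosity": -0.1,
              "lateral_sd": -0.04, "obj_dist_mean": 0.02, "obj_dist_sd": 0.03}
    for b in range(12):
        u = rng.normal(0, 0.25, size=len(trends))
        for trial in range(1, 13):
            row = {"bee_id": f"b{b:02d}", "trial": trial, "environment_id": "env1"}
            for k, (name, sl) in enumerate(trends.items()):
                base = 0.0 if name != "sinuosity" else 0.3
                val = np.exp(base + sl * trial + u[k] + rng.normal(0, 0.15))
                row[name] = val + 1.0 if name == "sinuosity" else val
            rows.append(row)
    table = pd.DataFrame(rows)
    for name in trends:
        full = fit_mixed_model(table, ModelSpec(name, ("trial",), "bee"))
        reduced = fit_mixed_model(table, ModelSpec(name, (), "bee"))
        _, _, p = lrt_compare(full, reduced)
        assert p < 0.01, name
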