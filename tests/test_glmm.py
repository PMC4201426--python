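"""Binomial random-intercept GLMM and the predictor screen."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from invade.glmm import fit_binomial_glmm, redundancy_filter, screen_traits
from invade.synthetic import (simulate_glmm_dataset, simulate_status,
                              simulate_traits, simulate_tree)
from invade.tables import TraitTable


def test_zero_variance_data_match_plain_logistic_oracle():
    """With no between-group variance the marginal ML fit collapses to
    ordinary logistic regression (IRLS oracle via statsmodels Logit)."""
    df = simulate_glmm_dataset(50, 40, slope=0.5, sigma=0.0, seed=2)
    ours = fit_binomial_glmm(df.y, df.x, df.group)
    ref = sm.Logit(df.y, sm.add_constant(df.x)).fit(disp=0)
    assert ours.estimate == pytest.approx(float(ref.params.iloc[1]), abs=1e-3)
    assert ours.intercept == pytest.approx(float(ref.params.iloc[0]), abs=1e-3)
    assert ours.se == pytest.approx(float(ref.bse.iloc[1]), abs=1e-3)
    assert ours.sigma < 0.05


def test_matches_adaptive_quadrature_reference():
    """Frozen cross-check against lme4::glmer (binomial, nAGQ=15) on the
    regenerated seed-77 dataset: 12 groups x 15 obs, slope 0.8,
    intercept -0.5, sigma 1."""
    df = simulate_glmm_dataset(12, 15, slope=0.8, intercept=-0.5,
                               sigma=1.0, seed=77)
    ours = fit_binomial_glmm(df.y, df.x, df.group)
    assert ours.estimate == pytest.approx(0.69416987, abs=1e-3)
    assert ours.se == pytest.approx(0.17826133, abs=1e-3)
    assert ours.sigma == pytest.approx(0.28001016, abs=1e-3)
    assert ours.intercept == pytest.approx(-0.27040597, abs=1e-3)


def test_null_predictor_estimate_near_zero():
    df = simulate_glmm_dataset(40, 25, slope=0.0, sigma=0.8, seed=3)
    res = fit_binomial_glmm(df.y, df.x, df.group)
    assert abs(res.estimate) < 3 * res.se
    assert res.converged


def test_input_validation():
    df = simulate_glmm_dataset(10, 10, seed=4)
    with pytest.raises(ValueError, match="constant"):
        fit_binomial_glmm(df.y, np.ones(len(df)), df.group)
    with pytest.raises(ValueError, match="binary"):
        fit_binomial_glmm(df.x, df.x, df.group)
    with pytest.raises(ValueError, match="single class"):
        fit_binomial_glmm(np.ones(len(df)), df.x, df.group)
    with pytest.raises(ValueError, match="2 groups"):
        fit_binomial_glmm(df.y, df.x, ["g"] * len(df))


def test_screen_recovers_true_predictor():
    """One real effect among noise traits: the screen flags the true one;
    the Table-1-style output schema carries the four statistic columns."""
    tree = simulate_tree(150, "yule", seed=5)
    status = simulate_status(tree, "random", prevalence=50, seed=6)
    traits, status2 = simulate_traits(
        status, {"signal": 1.2, "noise1": 0.0, "noise2": 0.0, "noise3": 0.0},
        intercept_sd=0.5, seed=7)
    screen = screen_traits(status2, traits=traits, alpha=0.05)
    assert {"estimate", "se", "z", "p"} <= set(screen.results.columns)
    assert "signal" in screen.significant
    row = screen.results.set_index("predictor").loc["signal"]
    assert row["z"] == pytest.approx(row["estimate"] / row["se"])
    assert row["n_used"] == 150


def test_screen_skips_degenerate_predictors():
    tree = simulate_tree(40, "yule", seed=8)
    status = simulate_status(tree, "random", prevalence=10, seed=9)
    data = pd.DataFrame(
        {"ok": np.random.default_rng(0).normal(size=40),
         "empty": [np.nan] * 40,
         "constant": [1.0] * 40},
        index=pd.Index(status.species, name="species"))
    screen = screen_traits(status, traits=TraitTable(data))
    assert "empty" in screen.skipped
    assert "constant" in screen.skipped
    assert list(screen.results["predictor"]) == ["ok"]


def test_screen_insensitive_to_column_order():
    tree = simulate_tree(60, "yule", seed=10)
    status = simulate_status(tree, "random", prevalence=20, seed=11)
    traits, status2 = simulate_traits(status, {"a": 0.8, "b": 0.0, "c": 0.0},
                                      seed=12)
    shuffled = TraitTable(traits.data[["c", "a", "b"]], traits.sentinel)
    r1 = screen_traits(status2, traits=traits).results.set_index("predictor")
    r2 = screen_traits(status2, traits=shuffled).results.set_index("predictor")
    pd.testing.assert_frame_equal(r1.sort_index(), r2.sort_index())


def test_redundancy_filter_keeps_most_significant_of_correlated_pair():
    rng = np.random.default_rng(13)
    base = rng.normal(size=60)
    data = pd.DataFrame({"p_small": base, "p_big": base,  # r = 1.0
                         "other": rng.normal(size=60)})
    results = pd.DataFrame({"predictor": ["p_small", "p_big", "other"],
                            "p": [0.01, 0.03, 0.02]})
    assert redundancy_filter(results, data, threshold=0.7) == ["p_small", "other"]


def test_redundancy_filter_no_pair_above_threshold_is_noop():
    rng = np.random.default_rng(14)
    data = pd.DataFrame({c: rng.normal(size=80) for c in "abc"})
    results = pd.DataFrame({"predictor": list("abc"), "p": [0.01, 0.02, 0.03]})
    assert redundancy_filter(results, data, threshold=0.7) == list("abc")


def test_redundancy_filter_chain_hand_trace():
    """A~B and B~C correlated, A least significant then C: dropping the
    largest p first removes A, then C (B still conflicts with C), so only
    B survives — matching the hand execution of the stated rule."""
    rng = np.random.default_rng(15)
    b = rng.normal(size=200)
    a = b + rng.normal(scale=0.3, size=200)   # corr(a,b) ~ 0.95
    c = b + rng.normal(scale=0.3, size=200)   # corr(b,c) ~ 0.95, corr(a,c) ~ 0.9
    data = pd.DataFrame({"A": a, "B": b, "C": c})
    results = pd.DataFrame({"predictor": ["A", "B", "C"],
                            "p": [0.04, 0.001, 0.02]})
    assert redundancy_filter(results, data, threshold=0.7) == ["B"]
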