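"""Unit and property tests for the Bayesian observer core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal, norm

from metabet.observer import (
    ObserverConfig,
    EvidenceSample,
    PosteriorResult,
    alternative_decision,
    compare_confidence,
    decide_orientation,
    draw_evidence,
    posterior_arrays,
    posterior_orientation,
    run_observer_trial,
    simulate_trials,
)

GRID5 = tuple(np.linspace(0.5, 3.0, 5))


# ---------------------------------------------------------------------------
# configuration validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        {"contrast_grid": ()},
        {"contrast_grid": (1.0, -0.5)},
        {"contrast_grid": (1.0, float("nan"))},
        {"orientation_prior": 0.0},
        {"orientation_prior": 1.0},
        {"sigma_d": -0.1},
        {"rho": 1.0},
        {"sigma_add": 0.0, "sigma_mult": 0.0},
        {"decision_rule": "magic"},
        {"tie_rule": "coin"},
    ],
)
def test_invalid_configuration_rejected(kwargs):
    with pytest.raises(ValueError):
        ObserverConfig(**kwargs)


def test_target_absent_sample_must_have_zero_contrast():
    with pytest.raises(ValueError):
        EvidenceSample(0.1, 0.2, "TA", 1.0, "left")
    with pytest.raises(ValueError):
        EvidenceSample(0.1, 0.2, "TP", 1.0, "none")


# ---------------------------------------------------------------------------
# evidence sampling
# ---------------------------------------------------------------------------

def test_draw_evidence_matches_source_distributions(rng):
    cfg = ObserverConfig(contrast_grid=GRID5)
    noise = draw_evidence(cfg, "none", 0.0, rng, size=100_000)
    assert np.allclose(noise.mean(axis=0), [0, 0], atol=0.02)
    assert np.allclose(noise.std(axis=0), [1, 1], atol=0.02)
    left = draw_evidence(cfg, "left", 2.0, rng, size=100_000)
    assert np.allclose(left.mean(axis=0), [2, 0], atol=0.02)


def test_draw_evidence_correlated_noise(rng):
    cfg = ObserverConfig(contrast_grid=GRID5, rho=0.5)
    right = draw_evidence(cfg, "right", 1.5, rng, size=100_000)
    assert np.allclose(right.mean(axis=0), [0, 1.5], atol=0.02)
    assert np.corrcoef(right.T)[0, 1] == pytest.approx(0.5, abs=0.01)


def test_draw_evidence_contrast_dependent_scale(rng):
    cfg = ObserverConfig(contrast_grid=GRID5, sigma_add=1.0, sigma_mult=0.5)
    d = draw_evidence(cfg, "left", 2.0, rng, size=100_000)
    expected_sd = math.sqrt(1.0 + (0.5 * 2.0) ** 2)
    assert np.allclose(d.std(axis=0), expected_sd, atol=0.02)


def test_draw_evidence_orientation_contrast_consistency(rng):
    cfg = ObserverConfig(contrast_grid=GRID5)
    with pytest.raises(ValueError):
        draw_evidence(cfg, "none", 1.0, rng)
    with pytest.raises(ValueError):
        draw_evidence(cfg, "left", 0.0, rng)


# ---------------------------------------------------------------------------
# posterior inference
# ---------------------------------------------------------------------------

def test_posterior_hand_oracle_single_contrast():
    # d=(2,0), grid {1}, identity covariance: densities at means (1,0)/(0,1)
    # give p_left = 1 / (1 + e^{-2})
    cfg = ObserverConfig(contrast_grid=(1.0,), seed=0)
    post = posterior_orientation(np.array([2.0, 0.0]), cfg)
    assert post.p_left == pytest.approx(1 / (1 + math.exp(-2)), abs=1e-12)
    assert post.chosen == "left"
    assert decide_orientation(post) == "left"
    assert post.confidence == pytest.approx(post.p_left)


def test_posterior_symmetric_evidence_is_uninformative():
    cfg = ObserverConfig(contrast_grid=GRID5, seed=3)
    for x in (-1.0, 0.0, 0.7, 3.2):
        post = posterior_orientation(np.array([x, x]), cfg)
        assert post.p_left == pytest.approx(0.5, abs=1e-12)


def test_zero_contrast_grid_gives_chance_posteriors(rng):
    cfg = ObserverConfig(contrast_grid=(0.0,), seed=4)
    for _ in range(10):
        post = posterior_orientation(rng.normal(size=2), cfg, rng)
        assert post.p_left == pytest.approx(0.5, abs=1e-12)


def test_posterior_brute_force_oracle(rng):
    """Log-space marginalisation agrees with direct density summation."""
    cfg = ObserverConfig(contrast_grid=GRID5, orientation_prior=0.4, rho=0.3,
                         sigma_mult=0.2)
    for _ in range(100):
        d = rng.normal(scale=3.0, size=2)
        post = posterior_orientation(d, cfg, rng)
        num = {"left": 0.0, "right": 0.0}
        for ori, prior in (("left", 0.4), ("right", 0.6)):
            for c in cfg.contrast_grid:
                num[ori] += prior / len(cfg.contrast_grid) * multivariate_normal.pdf(
                    d, mean=cfg.mean(ori, c), cov=cfg.covariance(c)
                )
        expected = num["left"] / (num["left"] + num["right"])
        assert post.p_left == pytest.approx(expected, abs=1e-10)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    dx=st.floats(-10, 10),
    dy=st.floats(-10, 10),
    prior=st.floats(0.05, 0.95),
)
def test_posterior_normalisation_and_mirror_symmetry(dx, dy, prior):
    cfg = ObserverConfig(contrast_grid=GRID5, orientation_prior=prior, seed=0)
    post = posterior_orientation(np.array([dx, dy]), cfg)
    assert post.p_left + post.p_right == pytest.approx(1.0, abs=1e-12)
    # relabelling left/right while reflecting d across the diagonal
    mirrored = ObserverConfig(contrast_grid=GRID5, orientation_prior=1 - prior, seed=0)
    post_m = posterior_orientation(np.array([dy, dx]), mirrored)
    assert post.p_left == pytest.approx(post_m.p_right, abs=1e-12)


def test_posterior_no_underflow_at_extreme_evidence():
    cfg = ObserverConfig(contrast_grid=(0.5, 90.0), seed=0)
    post = posterior_orientation(np.array([90.0, 0.0]), cfg)
    assert post.p_left == pytest.approx(1.0, abs=1e-10)
    assert math.isfinite(post.confidence)


def test_tie_breaking_reproducible_under_seed():
    cfg = ObserverConfig(contrast_grid=GRID5, seed=42)
    choices_a = [posterior_orientation(np.array([1.0, 1.0]), cfg, cfg.rng()).chosen
                 for _ in range(5)]
    choices_b = [posterior_orientation(np.array([1.0, 1.0]), cfg, cfg.rng()).chosen
                 for _ in range(5)]
    assert choices_a == choices_b
    first = ObserverConfig(contrast_grid=GRID5, tie_rule="first", seed=42)
    post = posterior_orientation(np.array([1.0, 1.0]), first)
    assert post.chosen == "left"


# ---------------------------------------------------------------------------
# interval comparison
# ---------------------------------------------------------------------------

def test_compare_confidence_log_ratio_sign():
    cfg = ObserverConfig(contrast_grid=(1.0,), sigma_d=0.0, seed=0)
    post_tp = PosteriorResult(0.8808, 0.1192, "left", 0.8808)
    post_ta = PosteriorResult(0.5, 0.5, "left", 0.5)
    dec = compare_confidence(post_tp, post_ta, cfg)
    assert dec.D == pytest.approx(math.log(0.8808 / 0.5), abs=1e-12)
    assert dec.bet_interval == "TP"
    # swapping the intervals flips the bet: the comparison is label-blind
    dec_sw = compare_confidence(post_ta, post_tp, cfg)
    assert dec_sw.bet_interval == "TA"


def test_compare_confidence_tie_uses_tie_rule():
    post = PosteriorResult(0.7, 0.3, "left", 0.7)
    cfg = ObserverConfig(contrast_grid=(1.0,), tie_rule="first", seed=0)
    assert compare_confidence(post, post, cfg).bet_interval == "TP"


def test_compare_confidence_rejects_nonfinite_confidence():
    cfg = ObserverConfig(contrast_grid=(1.0,), seed=0)
    bad = PosteriorResult(1.0, 0.0, "left", float("nan"))
    good = PosteriorResult(0.6, 0.4, "left", 0.6)
    with pytest.raises(ValueError):
        compare_confidence(bad, good, cfg)


def test_noiseless_decision_variable_determines_bet(rng):
    cfg = ObserverConfig(contrast_grid=GRID5, sigma_d=0.0, seed=9)
    sim = simulate_trials(cfg, np.repeat("left", 2000), np.full(2000, 1.5), rng)
    assert np.all(sim["bet_tp"] == (sim["D"] > 0))


# ---------------------------------------------------------------------------
# whole trials
# ---------------------------------------------------------------------------

def test_run_observer_trial_easy_contrast_high_accuracy():
    cfg = ObserverConfig(contrast_grid=GRID5, seed=7)
    rng = cfg.rng()
    n = 10_000
    sim = simulate_trials(cfg, np.repeat("left", n), np.full(n, GRID5[-1]), rng)
    assert sim["correct_tp"].mean() > 0.95
    assert sim["bet_tp"].mean() > 0.9


def test_run_observer_trial_single_call_matches_contract():
    cfg = ObserverConfig(contrast_grid=GRID5, seed=12)
    dec = run_observer_trial(cfg, "left", 3.0)
    assert dec.bet_interval in ("TP", "TA")
    assert dec.orientation_choice_tp in ("left", "right")
    with pytest.raises(ValueError):
        run_observer_trial(cfg, "left", 0.0)


def test_chance_floor_when_both_intervals_are_noise(rng):
    """Two noise intervals are statistically identical: accuracy and betting
    both sit at chance."""
    cfg = ObserverConfig(contrast_grid=GRID5, seed=5)
    n = 10_000
    d1 = rng.standard_normal((n, 2))
    d2 = rng.standard_normal((n, 2))
    p1 = posterior_arrays(d1, cfg)
    p2 = posterior_arrays(d2, cfg)
    bet_first = (p1["log_score"] - p2["log_score"]) > 0
    assert bet_first.mean() == pytest.approx(0.5, abs=0.02)
    truth = rng.random(n) < 0.5
    correct = p1["choose_left"] == truth
    assert correct.mean() == pytest.approx(0.5, abs=0.02)


def test_closed_form_accuracy_single_point_grid(rng):
    """With a one-point grid and identity covariance the tilt rule reduces to
    d_left > d_right, so accuracy is Phi(c / sqrt(2))."""
    for c in (0.5, 1.0, 2.0):
        cfg = ObserverConfig(contrast_grid=(c,), seed=1)
        sim = simulate_trials(cfg, np.repeat("left", 100_000), np.full(100_000, c), rng)
        assert sim["correct_tp"].mean() == pytest.approx(norm.cdf(c / math.sqrt(2)), abs=0.005)


def test_betting_degrades_monotonically_with_decisional_noise(rng):
    n = 10_000
    contrast = 2.5
    rates = []
    for sd in (0.0, 0.5, 1.0, 2.0, 50.0):
        cfg = ObserverConfig(contrast_grid=GRID5, sigma_d=sd, seed=2)
        sim = simulate_trials(
            cfg, np.repeat("left", n), np.full(n, contrast), np.random.default_rng(77)
        )
        rates.append(sim["bet_tp"].mean())
    assert all(b <= a + 0.02 for a, b in zip(rates, rates[1:]))
    assert rates[-1] == pytest.approx(0.5, abs=0.02)


# ---------------------------------------------------------------------------
# alternative decision rules
# ---------------------------------------------------------------------------

def test_hierarchical_map_equals_ideal_on_single_point_grid(rng):
    ideal = ObserverConfig(contrast_grid=(1.5,), seed=6)
    hier = ObserverConfig(contrast_grid=(1.5,), decision_rule="hierarchical_map", seed=6)
    d = rng.normal(scale=2.0, size=(200, 2))
    pi = posterior_arrays(d, ideal)
    ph = posterior_arrays(d, hier)
    assert np.allclose(pi["log_confidence"], ph["log_confidence"], atol=1e-12)
    assert np.array_equal(pi["choose_left"], ph["choose_left"])


def test_hierarchical_map_close_to_ideal_on_full_grid(rng):
    """The contrast-estimating observer behaves like the marginalising one."""
    n = 20_000
    accs, bets = [], []
    for rule in ("ideal_marginal", "hierarchical_map"):
        cfg = ObserverConfig(contrast_grid=GRID5, decision_rule=rule, seed=8)
        sim = simulate_trials(
            cfg, np.repeat("left", n), np.full(n, 1.5), np.random.default_rng(99)
        )
        accs.append(sim["correct_tp"].mean())
        bets.append(sim["bet_tp"].mean())
    assert accs[0] == pytest.approx(accs[1], abs=0.02)
    assert bets[0] == pytest.approx(bets[1], abs=0.03)


def test_likelihood_only_rule_deviates_from_ideal(rng):
    """Comparing maximised likelihoods instead of posteriors changes the
    betting pattern at high contrast."""
    n = 20_000
    bets = {}
    for rule in ("ideal_marginal", "likelihood_only"):
        cfg = ObserverConfig(contrast_grid=GRID5, decision_rule=rule, seed=8)
        sim = simulate_trials(
            cfg, np.repeat("left", n), np.full(n, 3.0), np.random.default_rng(13)
        )
        bets[rule] = sim["bet_tp"].mean()
    assert abs(bets["likelihood_only"] - bets["ideal_marginal"]) > 0.03


def test_alternative_decision_requires_non_default_rule():
    cfg = ObserverConfig(contrast_grid=GRID5, seed=0)
    post = PosteriorResult(0.7, 0.3, "left", 0.7)
    with pytest.raises(ValueError):
        alternative_decision(post, post, cfg)
    hier = ObserverConfig(contrast_grid=GRID5, decision_rule="hierarchical_map",
                          tie_rule="first", seed=0)
    assert alternative_decision(post, post, hier).bet_interval == "TP"
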