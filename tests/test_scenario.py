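"""Synthetic-shift generator: arrivals, patience, outcome surrogates."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from mhcc_sim.config import ScenarioConfig, SimConfig, make_setting
from mhcc_sim.scenario import (
    ArrivalIntensity,
    generate_scenario,
    outcome_surrogate,
    patience_mean,
    realize_outcome,
    sample_caller,
    sample_nhpp_arrivals,
    sample_patience,
)
from conftest import make_agent, make_caller


# ---------------------------------------------------------------- arrivals
def test_zero_rate_gives_no_arrivals(rng):
    intensity = ArrivalIntensity(0.0)
    assert sample_nhpp_arrivals(intensity, 3600.0, rng) == []


def test_zero_intensity_region_has_no_arrivals(rng):
    intensity = ArrivalIntensity(12.0, ((0.0, 0.0), (1800.0, 1.0)))
    for _ in range(50):
        times = sample_nhpp_arrivals(intensity, 3600.0, rng)
        assert all(t >= 1800.0 for t in times)


def test_flat_rate_counts_match_poisson_chisq(rng):
    """Counts over 1 h at 7/h replicate the Poisson(7) pmf (chi-square)."""
    intensity = ArrivalIntensity(7.0)
    counts = np.array(
        [len(sample_nhpp_arrivals(intensity, 3600.0, rng)) for _ in range(10_000)]
    )
    kmax = 15
    observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
    expected = stats.poisson(7.0).pmf(np.arange(kmax)) * counts.size
    expected = np.append(expected, counts.size - expected.sum())
    p = stats.chisquare(observed, expected).pvalue
    assert p > 0.01


def test_nhpp_superposition_moments(rng):
    """Merged thinned streams at rates r1 + r2 match a single r1+r2 stream."""
    h = 3600.0
    n = 4000
    merged = [
        len(sample_nhpp_arrivals(ArrivalIntensity(4.0), h, rng))
        + len(sample_nhpp_arrivals(ArrivalIntensity(3.0), h, rng))
        for _ in range(n)
    ]
    single = [len(sample_nhpp_arrivals(ArrivalIntensity(7.0), h, rng)) for _ in range(n)]
    # Poisson(7) either way: compare mean and variance within sampling error
    assert np.mean(merged) == pytest.approx(np.mean(single), abs=4 * math.sqrt(7 / n) * 2)
    assert np.var(merged) == pytest.approx(np.var(single), rel=0.15)


def test_invalid_intensity_rejected():
    with pytest.raises(ValueError):
        ArrivalIntensity(-1.0)
    with pytest.raises(ValueError):
        ArrivalIntensity(5.0, ((100.0, 1.0),))  # profile must start at 0


# ---------------------------------------------------------------- patience
def test_patience_mean_device_anchors():
    cfg = replace(
        ScenarioConfig(), patience_scale=1.0, patience_trait_w=0.0,
        patience_age_mult=(1.0, 1.0, 1.0, 1.0),
    )
    desktop = make_caller(device="desktop")
    mobile = make_caller(device="mobile")
    assert patience_mean(desktop, cfg) == pytest.approx(402.0)
    assert patience_mean(mobile, cfg) == pytest.approx(266.0)


def test_patience_mean_multiplier_arithmetic():
    cfg = replace(
        ScenarioConfig(), patience_scale=1.0, patience_trait_w=0.0,
        patience_age_mult=(1.0, 2.0, 1.0, 1.0),
    )
    mobile = make_caller(device="mobile", age_group="18-35")
    assert patience_mean(mobile, cfg) == pytest.approx(532.0)


def test_patience_draws_are_exponential(rng):
    """KS test of 10,000 draws against the configured exponential."""
    cfg = replace(ScenarioConfig(), patience_trait_w=0.0)
    caller = make_caller(device="mobile")
    mean = patience_mean(caller, cfg)
    draws = np.array([sample_patience(caller, cfg, rng) for _ in range(10_000)])
    assert (draws > 0).all()
    p = stats.kstest(draws, "expon", args=(0, mean)).pvalue
    assert p > 0.01
    # survival anchor: P(X > mean) ~ 1/e, and the sample mean matches
    assert (draws > mean).mean() == pytest.approx(math.exp(-1), abs=0.015)
    assert draws.mean() == pytest.approx(mean, rel=0.03)


# ---------------------------------------------------------------- callers
def test_degenerate_bernoulli_device(rng):
    cfg = replace(ScenarioConfig(), p_mobile=1.0)
    for _ in range(25):
        assert sample_caller("c", 0.0, cfg, rng).device == "mobile"


def test_sample_caller_deterministic_under_seed():
    cfg = ScenarioConfig()
    a = sample_caller("c", 5.0, cfg, np.random.default_rng(7))
    b = sample_caller("c", 5.0, cfg, np.random.default_rng(7))
    assert a == b


def test_mobile_fraction_matches_p_mobile(rng):
    cfg = replace(ScenarioConfig(), p_mobile=0.6)
    n = 10_000
    frac = np.mean(
        [sample_caller("c", 0.0, cfg, rng).device == "mobile" for _ in range(n)]
    )
    se = math.sqrt(0.6 * 0.4 / n)
    assert abs(frac - 0.6) < 3 * se


# ------------------------------------------------------------- surrogates
def test_degenerate_surrogate_is_constant():
    cfg = replace(
        ScenarioConfig(), a_dur=0.0, c_dur=0.0, w_d=0.0, w_q=0.0, c_q=0.0,
        age_penalty=0.0,
    )
    pairs = [
        (make_caller(trait=(t, -t)), make_agent(style=(s, s)))
        for t, s in [(0.0, 0.0), (1.0, -1.0), (-2.0, 0.5)]
    ]
    outs = [outcome_surrogate(c, a, cfg) for c, a in pairs]
    assert all(o.base_duration == pytest.approx(math.exp(cfg.mu_d)) for o in outs)
    expected_q = 1 / (1 + math.exp(-cfg.mu_q))
    assert all(o.base_quality == pytest.approx(expected_q) for o in outs)


def test_quality_increases_with_affinity():
    cfg = replace(ScenarioConfig(), age_penalty=0.0)
    agent = make_agent(style=(1.0, 0.0))
    lo = outcome_surrogate(make_caller(trait=(0.0, 0.0)), agent, cfg)
    hi = outcome_surrogate(make_caller(trait=(1.0, 0.0)), agent, cfg)
    assert hi.base_quality > lo.base_quality


def test_agent_age_penalty_waived_for_older_callers(rng):
    """Mean quality is lower for a 70-year-old agent, except with 65+ callers."""
    cfg = ScenarioConfig()
    young = make_agent(age=30.0)
    old = make_agent(agent_id="a1", age=70.0)
    qs = {"young": [], "old": [], "old_with_senior": []}
    for _ in range(10_000):
        trait = tuple(rng.normal(size=2))
        c = make_caller(trait=trait, age_group="18-35")
        qs["young"].append(outcome_surrogate(c, young, cfg).base_quality)
        qs["old"].append(outcome_surrogate(c, old, cfg).base_quality)
        senior = make_caller(trait=trait, age_group="65+")
        qs["old_with_senior"].append(outcome_surrogate(senior, old, cfg).base_quality)
    assert np.mean(qs["old"]) < np.mean(qs["young"])
    assert np.mean(qs["old_with_senior"]) > np.mean(qs["old"])


def test_trait_style_dimension_mismatch():
    with pytest.raises(ValueError):
        outcome_surrogate(
            make_caller(trait=(0.0,) * 3), make_agent(style=(0.0,) * 2), ScenarioConfig()
        )


# ------------------------------------------------------- realized outcomes
def test_noiseless_realization_reproduces_surrogate(rng):
    cfg = replace(ScenarioConfig(), sigma_d=0.0, sigma_q=0.0)
    s = outcome_surrogate(make_caller(), make_agent(), cfg)
    out = realize_outcome(s, cfg, rng)
    assert out.duration == pytest.approx(s.base_duration)
    assert out.feedback == round(1 + 4 * s.base_quality)


def test_quality_one_clips_to_feedback_five(rng):
    from mhcc_sim.scenario import OutcomeSurrogate

    cfg = replace(ScenarioConfig(), sigma_q=0.0)
    out = realize_outcome(OutcomeSurrogate(1000.0, 1.0), cfg, rng)
    assert out.feedback == 5 and out.quality == 1.0


def test_duration_noise_is_centered(rng):
    from mhcc_sim.scenario import OutcomeSurrogate

    cfg = replace(ScenarioConfig(), duration_floor_s=0.0)
    base = 5000.0  # far above the floor so flooring never binds
    n = 100_000
    durs = np.array(
        [realize_outcome(OutcomeSurrogate(base, 0.5), cfg, rng).duration for _ in range(n)]
    )
    se = cfg.sigma_d / math.sqrt(n)
    assert abs(durs.mean() - base) < 3 * se


def test_feedback_stochastically_increasing_in_base_quality(rng):
    from mhcc_sim.scenario import OutcomeSurrogate

    cfg = ScenarioConfig()
    lo = [realize_outcome(OutcomeSurrogate(1000, 0.4), cfg, rng).feedback for _ in range(4000)]
    hi = [realize_outcome(OutcomeSurrogate(1000, 0.8), cfg, rng).feedback for _ in range(4000)]
    assert np.mean(hi) > np.mean(lo)


# --------------------------------------------------------- reproducibility
def test_scenario_fully_reproducible_from_seed(heavy_cfg):
    s1 = generate_scenario(heavy_cfg.scenario, 99)
    s2 = generate_scenario(heavy_cfg.scenario, 99)
    assert [c.arrival_time for c in s1.callers] == [c.arrival_time for c in s2.callers]
    assert [c.true_patience for c in s1.callers] == [c.true_patience for c in s2.callers]
    assert s1.agents == s2.agents
    # realized outcomes agree regardless of query order
    if s1.callers:
        c1, a1 = s1.callers[-1], s1.agents[0]
        c2, a2 = s2.callers[-1], s2.agents[0]
        assert s1.realized_outcome(c1, a1) == s2.realized_outcome(c2, a2)


def test_scenario_serializes_to_jsonl(tmp_path, heavy_cfg):
    scen = generate_scenario(heavy_cfg.scenario, 3)
    path = tmp_path / "scenario.jsonl"
    scen.to_jsonl(str(path))
    lines = path.read_text().splitlines()
    assert len(lines) == len(scen.agents) + len(scen.callers)


def test_unknown_setting_rejected():
    with pytest.raises(ValueError):
        make_setting("rush_hour")
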