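"""Routing policies: FCFS order, CMT utility and greedy matching, MCTS contract."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhcc_sim.config import MctsConfig, SimConfig, make_setting
from mhcc_sim.engine import PolicyDecision, run_shift, apply_decision
from mhcc_sim.policies import CmtPolicy, FcfsPolicy, cmt_utility, make_policy
from mhcc_sim.predictors import PredictorBundle
from mhcc_sim.scenario import generate_scenario
from conftest import make_agent, make_caller, manual_scenario


# ---------------------------------------------------------------- FCFS
def _state_with(standard_cfg, callers, agents):
    from mhcc_sim.engine import CallerView, SimState

    views = tuple(
        CallerView(c.caller_id, c.arrival_time, c.age_group, c.device, c.is_returning, c.trait)
        for c in callers
    )
    return SimState(
        clock=max((c.arrival_time for c in callers), default=0.0),
        shift_horizon_s=standard_cfg.scenario.horizon_s,
        waiting=views,
        free_agents=tuple(agents),
        busy=(),
        n_served=0,
        n_abandoned=0,
    )


def test_fcfs_matches_earliest_arrival(standard_cfg, bundle):
    state = _state_with(
        standard_cfg,
        [make_caller("c1", arrival=10.0), make_caller("c2", arrival=50.0)],
        [make_agent("a0")],
    )
    d = FcfsPolicy().decide(state, bundle)
    assert d.matches == (("c1", "a0"),)


def test_fcfs_empty_queue_gives_null(standard_cfg, bundle):
    state = _state_with(standard_cfg, [], [make_agent("a0")])
    assert FcfsPolicy().decide(state, bundle).matches == ()


def test_fcfs_fills_all_free_agents(standard_cfg, bundle):
    state = _state_with(
        standard_cfg,
        [make_caller(f"c{i}", arrival=float(i)) for i in range(3)],
        [make_agent("a0"), make_agent("a1")],
    )
    d = FcfsPolicy().decide(state, bundle)
    assert d.matches == (("c0", "a0"), ("c1", "a1"))


def test_fcfs_ignores_caller_features(standard_cfg, bundle):
    fancy = make_caller("c1", arrival=10.0, device="desktop", trait=(3.0, 3.0))
    plain = make_caller("c2", arrival=5.0, device="mobile", trait=(0.0, 0.0))
    state = _state_with(standard_cfg, [fancy, plain], [make_agent("a0")])
    assert FcfsPolicy().decide(state, bundle).matches == (("c2", "a0"),)


# ------------------------------------------------------------- CMT utility
@pytest.mark.parametrize(
    "q, d, p, expected",
    [
        (0.8, 1200.0, 300.0, 0.8 / 360_000.0),
        (0.6, 600.0, 300.0, 0.6 / 180_000.0),
        (0.0, 900.0, 100.0, 0.0),
    ],
)
def test_cmt_utility_closed_form(q, d, p, expected):
    assert cmt_utility(q, d, p) == pytest.approx(expected, rel=1e-12)


def test_cmt_utility_rejects_nonpositive_denominators():
    with pytest.raises(ValueError):
        cmt_utility(0.5, 0.0, 300.0)
    with pytest.raises(ValueError):
        cmt_utility(0.5, 600.0, -1.0)
    with pytest.raises(ValueError):
        cmt_utility(1.5, 600.0, 300.0)


@given(
    q=st.floats(0.05, 1.0),
    d=st.floats(60.0, 3600.0),
    p=st.floats(30.0, 2000.0),
    dq=st.floats(0.001, 0.5),
    dd=st.floats(1.0, 500.0),
    dp=st.floats(1.0, 500.0),
)
@settings(max_examples=100, deadline=None)
def test_cmt_utility_monotonicity(q, d, p, dq, dd, dp):
    base = cmt_utility(min(q, 1.0 - dq), d, p)
    assert cmt_utility(min(q, 1.0 - dq) + dq, d, p) > base
    assert cmt_utility(min(q, 1.0 - dq), d + dd, p) < base
    assert cmt_utility(min(q, 1.0 - dq), d, p + dp) < base


# ------------------------------------------------------------- CMT greedy
def test_cmt_prefers_higher_quality_agent(standard_cfg, bundle):
    caller = make_caller("c0", trait=(1.0, 0.0))
    good = make_agent("a_good", style=(1.0, 0.0))  # positive affinity
    bad = make_agent("a_bad", style=(-1.0, 0.0))
    state = _state_with(standard_cfg, [caller], [bad, good])
    d = CmtPolicy().decide(state, bundle)
    assert d.matches == (("c0", "a_good"),)


def test_cmt_tie_breaks_by_earliest_arrival(standard_cfg, bundle):
    # identical feature bundles => identical utilities
    c_late = make_caller("c_late", arrival=40.0)
    c_early = make_caller("c_early", arrival=10.0)
    state = _state_with(standard_cfg, [c_late, c_early], [make_agent("a0")])
    assert CmtPolicy().decide(state, bundle).matches == (("c_early", "a0"),)


def test_cmt_greedy_equals_bruteforce_on_small_instance(standard_cfg, bundle, rng):
    """Greedy pair selection replicates explicit repeated-argmax enumeration."""
    callers = [make_caller(f"c{i}", arrival=float(i), trait=tuple(rng.normal(size=2))) for i in range(3)]
    agents = [make_agent(f"a{j}", style=tuple(rng.normal(size=2))) for j in range(2)]
    state = _state_with(standard_cfg, callers, agents)
    got = CmtPolicy().decide(state, bundle).matches

    remaining_c, remaining_a, expected = list(callers), list(agents), []
    while remaining_c and remaining_a:
        scored = []
        for c, a in itertools.product(remaining_c, remaining_a):
            d_est, q_est = bundle.predict_pre_chat(c, a)
            u = cmt_utility(q_est, d_est, bundle.predict_patience(c))
            scored.append((-u, c.arrival_time, c.caller_id, a.agent_id, c, a))
        scored.sort(key=lambda t: t[:4])
        _, _, _, _, c, a = scored[0]
        expected.append((c.caller_id, a.agent_id))
        remaining_c.remove(c)
        remaining_a.remove(a)
    assert got == tuple(expected)


def test_cmt_prioritizes_impatient_callers(standard_cfg, bundle):
    """Identical callers except patience: the low-patience one is matched."""
    impatient = make_caller("c_imp", device="mobile")
    patient = make_caller("c_pat", device="desktop")  # longer patience mean
    state = _state_with(standard_cfg, [patient, impatient], [make_agent("a0")])
    assert CmtPolicy().decide(state, bundle).matches == (("c_imp", "a0"),)


# ---------------------------------------------------------------- MCTS
def test_mcts_single_rollout_returns_feasible_decision(heavy_cfg):
    """Anytime contract: a valid decision after one rollout."""
    bundle = PredictorBundle(heavy_cfg)
    mc = MctsConfig(n_rollouts=1, horizon_s=600.0)
    scen = generate_scenario(heavy_cfg.scenario, 21)
    metrics, _ = run_shift(scen, make_policy("mcts", heavy_cfg, mc), bundle, np.random.default_rng(0))
    assert metrics.n_served + metrics.n_abandoned + metrics.n_waiting_at_end == metrics.n_arrived


def test_mcts_emits_single_feasible_matches(heavy_cfg):
    """Every MCTS decision passes the engine's feasibility contract."""
    bundle = PredictorBundle(heavy_cfg)
    mc = MctsConfig(n_rollouts=15, horizon_s=900.0)
    inner = make_policy("mcts", heavy_cfg, mc)

    class Checked:
        name = "mcts"

        def decide(self, state, predictors, rng):
            d = inner.decide(state, predictors, rng)
            apply_decision(state, d)  # raises if infeasible
            assert len(d.matches) <= 1
            return d

    scen = generate_scenario(heavy_cfg.scenario, 8)
    run_shift(scen, Checked(), bundle, np.random.default_rng(3))


def test_time_budget_is_honored(heavy_cfg):
    import time

    bundle = PredictorBundle(heavy_cfg)
    mc = MctsConfig(n_rollouts=100_000, horizon_s=1800.0, time_budget_ms=50.0)
    scen = generate_scenario(heavy_cfg.scenario, 4)
    pol = make_policy("mcts", heavy_cfg, mc)
    start = time.monotonic()
    run_shift(scen, pol, bundle, np.random.default_rng(0))
    # dozens of decisions, each capped at 50 ms: the run stays bounded
    assert time.monotonic() - start < 60.0


def test_make_policy_rejects_unknown(heavy_cfg):
    with pytest.raises(ValueError):
        make_policy("lifo", heavy_cfg)
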