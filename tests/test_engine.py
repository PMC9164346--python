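"""Discrete-event engine: event ordering, conservation, contracts, replay."""

from dataclasses import replace

import numpy as np
import pytest

from mhcc_sim.config import MctsConfig, SimConfig, make_setting
from mhcc_sim.domain import ChatOutcome
from mhcc_sim.engine import (
    InfeasibleDecisionError,
    PolicyDecision,
    apply_decision,
    run_shift,
)
from mhcc_sim.policies import CmtPolicy, FcfsPolicy, make_policy
from mhcc_sim.predictors import PredictorBundle
from mhcc_sim.scenario import generate_scenario
from conftest import make_agent, make_caller, manual_scenario


def _one_agent_cfg() -> SimConfig:
    return SimConfig(scenario=replace(make_setting("standard"), n_agents=1))


def test_empty_scenario_uses_empty_shift_convention(standard_cfg):
    scen = manual_scenario(standard_cfg, [make_agent()], [])
    metrics, _ = run_shift(scen, FcfsPolicy(), PredictorBundle(standard_cfg))
    assert metrics.n_arrived == 0
    assert metrics.quantity == 1.0
    assert not metrics.quality_defined


def test_single_caller_is_served_without_waiting(standard_cfg):
    cfg = _one_agent_cfg()
    caller = make_caller("c0", arrival=10.0, patience=300.0)
    scen = manual_scenario(
        cfg, [make_agent()], [caller],
        outcomes={("c0", "a0"): ChatOutcome(900.0, 4, 0.75)},
    )
    metrics, trace = run_shift(scen, FcfsPolicy(), PredictorBundle(cfg))
    assert metrics.n_served == 1 and metrics.quantity == 1.0
    assert metrics.quality == 0.75
    assert trace.calls["c0"]["wait_s"] == 0.0


def test_hand_traced_fcfs_abandonment():
    """One agent; A (t=0, 600 s chat) blocks B (t=100, patience 400 s):
    B abandons at t=500 and the shift ends at Quantity 1/2."""
    cfg = _one_agent_cfg()
    a_caller = make_caller("cA", arrival=0.0, patience=9999.0)
    b_caller = make_caller("cB", arrival=100.0, patience=400.0)
    scen = manual_scenario(
        cfg, [make_agent()], [a_caller, b_caller],
        outcomes={
            ("cA", "a0"): ChatOutcome(600.0, 5, 1.0),
            ("cB", "a0"): ChatOutcome(700.0, 3, 0.5),
        },
    )
    metrics, trace = run_shift(scen, FcfsPolicy(), PredictorBundle(cfg))
    assert metrics.n_served == 1 and metrics.n_abandoned == 1
    assert metrics.quantity == 0.5
    assert trace.calls["cB"]["abandoned_s"] == pytest.approx(500.0)
    assert trace.calls["cA"]["start_s"] == 0.0
    kinds = [(e["time"], e["kind"]) for e in trace.events]
    assert (500.0, "abandonment") in kinds


def test_ongoing_chat_completes_after_shift_end():
    cfg = _one_agent_cfg()
    horizon = cfg.scenario.horizon_s
    late = make_caller("c0", arrival=horizon - 60.0, patience=1e6)
    scen = manual_scenario(
        cfg, [make_agent()], [late],
        outcomes={("c0", "a0"): ChatOutcome(1800.0, 4, 0.75)},
    )
    metrics, trace = run_shift(scen, FcfsPolicy(), PredictorBundle(cfg))
    assert metrics.n_served == 1  # started before shift end, runs to completion
    end_events = [e for e in trace.events if e["kind"] == "chat_end"]
    assert end_events[0]["time"] > horizon


def test_waiting_at_shift_end_counts_as_not_served():
    cfg = _one_agent_cfg()
    horizon = cfg.scenario.horizon_s
    first = make_caller("c0", arrival=horizon - 120.0, patience=1e6)
    second = make_caller("c1", arrival=horizon - 60.0, patience=1e6)
    scen = manual_scenario(
        cfg, [make_agent()], [first, second],
        outcomes={("c0", "a0"): ChatOutcome(600.0, 4, 0.75)},
    )
    metrics, _ = run_shift(scen, FcfsPolicy(), PredictorBundle(cfg))
    assert metrics.n_served == 1
    assert metrics.n_waiting_at_end == 1
    assert metrics.quantity == 0.5


@pytest.mark.parametrize("policy_name", ["fcfs", "cmt"])
def test_conservation_on_random_shifts(policy_name, heavy_cfg):
    bundle = PredictorBundle(heavy_cfg)
    pol = make_policy(policy_name, heavy_cfg)
    for seed in range(25):
        scen = generate_scenario(heavy_cfg.scenario, 1000 + seed)
        m, _ = run_shift(scen, pol, bundle, np.random.default_rng(seed))
        assert m.n_served + m.n_abandoned + m.n_waiting_at_end == m.n_arrived


def test_infinite_patience_and_spare_capacity_serve_everyone():
    scen_cfg = replace(
        make_setting("standard"), base_rate_per_h=2.0, n_agents=4, patience_scale=1e6
    )
    cfg = SimConfig(scenario=scen_cfg)
    bundle = PredictorBundle(cfg)
    for seed in (5, 6, 7):
        scen = generate_scenario(cfg.scenario, seed)
        m, _ = run_shift(scen, FcfsPolicy(), bundle)
        assert m.n_abandoned == 0
        assert m.quantity == 1.0  # shift-end completion is allowed


def test_non_preemption_and_no_anachronism(heavy_cfg):
    bundle = PredictorBundle(heavy_cfg)
    scen = generate_scenario(heavy_cfg.scenario, 77)
    patience = {c.caller_id: c.true_patience for c in scen.callers}
    arrival = {c.caller_id: c.arrival_time for c in scen.callers}
    _, trace = run_shift(scen, CmtPolicy(), bundle)
    ends = {e["caller_id"]: e["time"] for e in trace.events if e["kind"] == "chat_end"}
    for cid, rec in trace.calls.items():
        if rec["served"]:
            # chat started strictly before the abandonment deadline
            assert rec["start_s"] < arrival[cid] + patience[cid] + 1e-9
            if cid in ends:  # chat end = start + realized duration, exactly
                assert ends[cid] == pytest.approx(rec["start_s"] + rec["duration_s"])
        elif rec.get("abandoned"):
            assert rec["abandoned_s"] == pytest.approx(arrival[cid] + patience[cid])


def test_identical_inputs_give_bit_identical_traces(heavy_cfg):
    bundle = PredictorBundle(heavy_cfg)
    mc = MctsConfig(n_rollouts=10, horizon_s=900.0)
    traces = []
    for _ in range(2):
        scen = generate_scenario(heavy_cfg.scenario, 31)
        pol = make_policy("mcts", heavy_cfg, mc)
        _, tr = run_shift(scen, pol, bundle, np.random.default_rng(5))
        traces.append(tr.events)
    assert traces[0] == traces[1]


def test_trace_replay_reproduces_metrics(heavy_cfg):
    bundle = PredictorBundle(heavy_cfg)
    scen = generate_scenario(heavy_cfg.scenario, 13)
    metrics, trace = run_shift(scen, FcfsPolicy(), bundle)
    replayed = trace.recompute_metrics()
    assert replayed == metrics


def test_fcfs_work_conservation(heavy_cfg):
    """FCFS never leaves an agent free while a caller waits at a decision."""
    bundle = PredictorBundle(heavy_cfg)

    class CheckedFcfs(FcfsPolicy):
        def decide(self, state, predictors, rng=None):
            d = super().decide(state, predictors, rng)
            assert len(d.matches) == min(len(state.waiting), len(state.free_agents))
            return d

    for seed in range(10):
        scen = generate_scenario(heavy_cfg.scenario, 500 + seed)
        run_shift(scen, CheckedFcfs(), bundle)


# ------------------------------------------------------- decision contract
def _small_state(standard_cfg):
    scen = manual_scenario(
        standard_cfg,
        [make_agent("a0"), make_agent("a1")],
        [make_caller("c0", arrival=0.0), make_caller("c1", arrival=1.0)],
    )
    bundle = PredictorBundle(standard_cfg)

    class Grab:
        name = "grab"
        state = None

        def decide(self, state, predictors, rng=None):
            if self.state is None:
                self.state = state
            return PolicyDecision()

    g = Grab()
    run_shift(scen, g, bundle)
    return g.state


def test_apply_decision_null_is_identity(standard_cfg):
    state = _small_state(standard_cfg)
    assert apply_decision(state, PolicyDecision()) == state


def test_apply_decision_moves_pair_out_of_pools(standard_cfg):
    state = _small_state(standard_cfg)
    new = apply_decision(state, PolicyDecision(matches=(("c0", "a0"),)))
    assert all(c.caller_id != "c0" for c in new.waiting)
    assert all(a.agent_id != "a0" for a in new.free_agents)
    assert len(new.busy) == len(state.busy) + 1


@pytest.mark.parametrize(
    "matches",
    [
        (("c0", "zz"),),  # unknown agent
        (("zz", "a0"),),  # unknown caller
        (("c0", "a0"), ("c0", "a1")),  # caller matched twice
        (("c0", "a0"), ("c1", "a0")),  # agent matched twice
    ],
)
def test_apply_decision_rejects_infeasible(standard_cfg, matches):
    state = _small_state(standard_cfg)
    with pytest.raises(InfeasibleDecisionError):
        apply_decision(state, PolicyDecision(matches=matches))
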