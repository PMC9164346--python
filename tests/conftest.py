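"""Shared fixtures: configs, tiny scenarios, and planning micro-instances."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mhcc_sim.config import MctsConfig, SimConfig, make_setting
from mhcc_sim.domain import AgentProfile, CallerProfile
from mhcc_sim.engine import CallerView
from mhcc_sim.planning import PlanCaller, PlanState, RoutingPlanningProcess
from mhcc_sim.predictors import PredictorBundle
from mhcc_sim.scenario import ShiftScenario, ArrivalIntensity


@pytest.fixture
def standard_cfg() -> SimConfig:
    return SimConfig(scenario=make_setting("standard"))


@pytest.fixture
def heavy_cfg() -> SimConfig:
    return SimConfig(scenario=make_setting("heavy"))


@pytest.fixture
def bundle(heavy_cfg) -> PredictorBundle:
    return PredictorBundle(heavy_cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_agent(agent_id="a0", age=40.0, experience=5.0, style=(0.0, 0.0)) -> AgentProfile:
    return AgentProfile(
        agent_id=agent_id,
        age=age,
        gender="f",
        experience_years=experience,
        style=tuple(style),
        hist_avg_feedback=4.2,
        hist_avg_duration=1500.0,
    )


def make_caller(
    caller_id="c0",
    arrival=0.0,
    device="mobile",
    age_group="18-35",
    trait=(0.0, 0.0),
    patience=600.0,
) -> CallerProfile:
    return CallerProfile(
        caller_id=caller_id,
        arrival_time=arrival,
        age_group=age_group,
        device=device,
        is_returning=False,
        trait=tuple(trait),
        true_patience=patience,
    )


def manual_scenario(cfg: SimConfig, agents, callers, outcomes=None, seed=0) -> ShiftScenario:
    """Scenario with hand-picked hidden ground truths.

    ``outcomes`` maps (caller_id, agent_id) -> ChatOutcome and is installed
    into the memoization cache, so the engine realizes exactly these values.
    """
    scen = ShiftScenario(
        config=cfg.scenario,
        seed=seed,
        agents=list(agents),
        callers=list(callers),
        intensity=ArrivalIntensity(cfg.scenario.base_rate_per_h, cfg.scenario.rate_profile),
    )
    if outcomes:
        by_id = {c.caller_id: c for c in scen.callers}
        for (cid, aid), out in outcomes.items():
            by_id[cid].true_outcomes[aid] = out
    return scen


def micro_process(
    cfg: SimConfig,
    n_agents: int,
    plan_end: float = 3600.0,
    duration_noise: str = "none",
    shift_end: float | None = None,
):
    """Planning process for tiny exhaustive instances: no future arrivals,
    deterministic patience, pruning off (every action stays in play)."""
    from dataclasses import replace

    scen = cfg.scenario
    if shift_end is not None:
        cfg = replace(cfg, scenario=replace(scen, horizon_s=shift_end))
    agents = [make_agent(f"a{i}") for i in range(n_agents)]
    return RoutingPlanningProcess(
        agents=agents,
        bundle=PredictorBundle(cfg),
        sim_cfg=cfg,
        plan_start=0.0,
        plan_end=plan_end,
        duration_noise=duration_noise,
        patience_mode="deterministic",
        arrivals=False,
        prune_dominated=False,
    )


def micro_caller(
    cid: str,
    uid: int,
    n_agents: int,
    q,
    d,
    patience: float,
    arrival: float = 0.0,
) -> PlanCaller:
    q = tuple(q) if not np.isscalar(q) else (float(q),) * n_agents
    d = tuple(d) if not np.isscalar(d) else (float(d),) * n_agents
    return PlanCaller(
        cid=cid,
        uid=uid,
        arrival=arrival,
        pmean=patience,
        abandon_t=arrival + patience,
        q_est=q,
        d_est=d,
        q_util=q,
    )


def micro_root(callers, n_agents: int, busy=()) -> PlanState:
    busy_agents = {b.agent for b in busy}
    return PlanState(
        t=0.0,
        waiting=tuple(callers),
        free=tuple(i for i in range(n_agents) if i not in busy_agents),
        busy=tuple(busy),
        n_abandoned=0,
        n_matched=len(busy),
        served_w=float(len(busy)),
        qual_sum=sum(b.q_est for b in busy),
        arrivals_seen=0,
    )


def exhaustive_mcts_cfg(n_rollouts: int = 4000) -> MctsConfig:
    """Search settings that let UCT resolve a tiny tree completely."""
    return MctsConfig(
        n_rollouts=n_rollouts,
        uct_c=math.sqrt(2.0),
        max_depth=64,
        horizon_s=None,
        prune_dominated=False,
        action_widening_k=50.0,
        widening_k=50.0,
        null_margin=0.0,
        match_margin=0.0,
        final_select_z=0.0,
    )
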