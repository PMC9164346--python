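"""The three routing policies: FCFS, CMT, and MCTS.

FCFS is the incumbent heuristic in contact centers: the longest-waiting
caller gets the next free agent, no predictions involved.

CMT is a greedy index rule descended from the classical c-mu/theta priority
rule for queues with impatient customers: a (caller, agent) pair scores

    utility = quality_est / (duration_est * patience_mean_est)

so it prefers matches promising high feedback per unit of agent time, and
prioritizes impatient callers (small predicted patience) because their
service opportunity is the most perishable.

MCTS plans ahead: at each decision point it runs UCT over the predictor-
built belief model (sampled future arrivals, abandonments, chat ends) and
picks the root action — a single match or the explicit null action of
deferring — with the most visits.  It is the only policy that can rationally
leave an agent idle while a caller waits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import MctsConfig, SimConfig
from .engine import PolicyDecision, SimState
from .mcts import SearchStats, expectimax, uct_search
from .planning import PlanState, RoutingPlanningProcess
from .predictors import PredictorBundle

log = logging.getLogger(__name__)

__all__ = [
    "cmt_utility",
    "FcfsPolicy",
    "CmtPolicy",
    "MctsPolicy",
    "make_policy",
    "expectimax_oracle",
]


def cmt_utility(quality_est: float, duration_est: float, patience_mean_est: float) -> float:
    """Greedy matching index: predicted quality per (duration x patience)."""
    if not 0.0 <= quality_est <= 1.0:
        raise ValueError("quality_est must lie in [0, 1]")
    if duration_est <= 0:
        raise ValueError("duration_est must be > 0")
    if patience_mean_est <= 0:
        raise ValueError("patience_mean_est must be > 0")
    return quality_est / (duration_est * patience_mean_est)


class FcfsPolicy:
    """First-come-first-served: earliest arrival to the lowest-id free agent."""

    name = "fcfs"

    def decide(
        self,
        state: SimState,
        predictors: PredictorBundle,
        rng: Optional[np.random.Generator] = None,
    ) -> PolicyDecision:
        queue = sorted(state.waiting, key=lambda c: (c.arrival_time, c.caller_id))
        agents = sorted(state.free_agents, key=lambda a: a.agent_id)
        matches = tuple(
            (c.caller_id, a.agent_id) for c, a in zip(queue, agents)
        )
        return PolicyDecision(matches=matches)


class CmtPolicy:
    """Greedy utility matching; never defers while a feasible match exists.

    Repeatedly picks the feasible pair with the highest ``cmt_utility``,
    breaking ties by earliest arrival and then ascending agent id.
    """

    name = "cmt"

    def decide(
        self,
        state: SimState,
        predictors: PredictorBundle,
        rng: Optional[np.random.Generator] = None,
    ) -> PolicyDecision:
        waiting = list(state.waiting)
        free = sorted(state.free_agents, key=lambda a: a.agent_id)
        matches: list[tuple[str, str]] = []
        while waiting and free:
            best_key = None
            best = None
            for c in waiting:
                patience = predictors.predict_patience(c)
                for a in free:
                    d, q = predictors.predict_pre_chat(c, a)
                    u = cmt_utility(q, d, patience)
                    key = (-u, c.arrival_time, c.caller_id, a.agent_id)
                    if best_key is None or key < best_key:
                        best_key, best = key, (c, a)
            c, a = best
            matches.append((c.caller_id, a.agent_id))
            waiting.remove(c)
            free.remove(a)
        return PolicyDecision(matches=tuple(matches))


@dataclass
class MctsPolicy:
    """UCT lookahead over the predictor-built belief model.

    Returns at most one match per invocation; the engine re-invokes the
    policy at the same clock while matches remain feasible, so multiple free
    agents are filled by consecutive decisions.  An empty decision is the
    deliberate null action.
    """

    sim_cfg: SimConfig
    cfg: MctsConfig = field(default_factory=MctsConfig)
    name: str = "mcts"
    last_stats: Optional[SearchStats] = None

    def decide(
        self,
        state: SimState,
        predictors: PredictorBundle,
        rng: Optional[np.random.Generator] = None,
    ) -> PolicyDecision:
        if not state.waiting or not state.free_agents:
            return PolicyDecision()
        rng = rng if rng is not None else np.random.default_rng()
        agents = sorted(
            list(state.free_agents) + [b.agent for b in state.busy],
            key=lambda a: a.agent_id,
        )
        if self.cfg.horizon_s is None:
            plan_end = state.shift_horizon_s
        else:
            plan_end = min(state.shift_horizon_s, state.clock + self.cfg.horizon_s)
        process = RoutingPlanningProcess(
            agents=agents,
            bundle=predictors,
            sim_cfg=self.sim_cfg,
            plan_start=state.clock,
            plan_end=plan_end,
            duration_noise=self.cfg.plan_duration_noise,
            prune_dominated=self.cfg.prune_dominated,
            rollout_policy=self.cfg.rollout_policy,
            future_callers=self.cfg.plan_future_callers,
            pool_seed=int(rng.integers(1 << 31)),
        )
        root = process.root_from_sim_state(state)
        stats = uct_search(process, root, self.cfg, rng)
        self.last_stats = stats
        action = stats.best_action
        if action[0] != "match" and self.cfg.null_margin > 0:
            # deferral needs clear evidence: its estimated value must beat
            # the best match by the configured margin, else serve someone
            match_vals = {
                a: v for a, v in stats.action_values.items() if a[0] == "match"
            }
            null_val = stats.action_values.get(action)
            if match_vals and (
                null_val is None
                or null_val < max(match_vals.values()) + self.cfg.null_margin
            ):
                action = max(match_vals, key=lambda a: match_vals[a])
        if self.cfg.match_margin > 0 and action[0] == "match":
            # trust region around the greedy match (first in the process's
            # utility-ordered action list): deviate only on clear evidence —
            # at small rollout budgets the argmax estimate is biased upward
            # by residual unpaired noise (optimizer's curse)
            greedy = process.actions(root)[0]
            if (
                action != greedy
                and greedy[0] == "match"
                and greedy in stats.action_values
                and stats.action_values[action]
                < stats.action_values[greedy] + self.cfg.match_margin
            ):
                action = greedy
        if log.isEnabledFor(logging.DEBUG):
            log.debug(
                "mcts t=%.1f waiting=%d free=%d rollouts=%d action=%s visits=%s",
                state.clock, len(state.waiting), len(state.free_agents),
                stats.n_rollouts, action, stats.action_visits,
            )
        if action[0] == "match":
            _, cid, agent_idx = action
            return PolicyDecision(matches=((cid, agents[agent_idx].agent_id),))
        return PolicyDecision()


def make_policy(name: str, sim_cfg: SimConfig, mcts_cfg: Optional[MctsConfig] = None):
    """Policy factory used by the experiment harness and the CLI."""
    if name == "fcfs":
        return FcfsPolicy()
    if name == "cmt":
        return CmtPolicy()
    if name == "mcts":
        return MctsPolicy(sim_cfg=sim_cfg, cfg=mcts_cfg or sim_cfg.mcts)
    raise ValueError(f"unknown policy {name!r}")


def expectimax_oracle(
    process: RoutingPlanningProcess,
    root: PlanState,
    max_depth: int = 64,
):
    """Exact expectimax over a tiny planning instance (test oracle).

    Enumeration explodes combinatorially, so the instance is guarded: at
    most 4 waiting callers, 3 agents, and finite chance support (arrivals
    off, deterministic patience, 'none' or 'two_point' duration noise).
    """
    if len(root.waiting) > 4:
        raise ValueError("expectimax oracle limited to <= 4 waiting callers")
    if len(process.agents) > 3:
        raise ValueError("expectimax oracle limited to <= 3 agents")
    return expectimax(process, root, max_depth=max_depth)
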