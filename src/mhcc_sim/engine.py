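"""Event-driven simulator of one contact-center shift.

The engine owns the hidden ground truth (patience draws, realized chat
outcomes) and exposes to the routing policy only an observable projection of
the state: waiting callers' public features, free agents, and
predictor-derived remaining-time estimates for ongoing chats.

Mechanics:

* events are processed from a binary heap in time order with a deterministic
  tie order (shift-end, then chat-end, then arrival, then abandonment;
  within a kind, by subject id) so a run is bit-reproducible;
* the policy is invoked at every arrival and chat-end event (the decision
  triggers) and may return the null action — an empty match set — to defer;
* a waiting caller abandons exactly when their wait exceeds their hidden
  patience; callers never abandon mid-chat;
* chats are non-preemptive and one-per-agent; chats still running at the
  shift end complete and count as served, callers still waiting count as
  not served.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from typing import Optional, Protocol

import numpy as np

from .domain import AgentProfile, ShiftMetrics, make_shift_metrics
from .predictors import PredictorBundle
from .scenario import ShiftScenario

__all__ = [
    "CallerView",
    "BusyChat",
    "SimState",
    "PolicyDecision",
    "ShiftTrace",
    "RoutingPolicy",
    "InfeasibleDecisionError",
    "apply_decision",
    "run_shift",
]

# event-kind tie priorities at equal timestamps
_P_SHIFT_END = 0
_P_CHAT_END = 1
_P_ARRIVAL = 2
_P_ABANDON = 3


@dataclass(frozen=True)
class CallerView:
    """Observable projection of a caller: public features only.

    Deliberately omits ``true_patience`` and ``true_outcomes`` — policies
    must work from predictions, not ground truth.
    """

    caller_id: str
    arrival_time: float
    age_group: str
    device: str
    is_returning: bool
    trait: tuple[float, ...]


@dataclass(frozen=True)
class BusyChat:
    """An ongoing conversation as the policy sees it."""

    agent: AgentProfile
    caller: CallerView
    elapsed: float
    base_duration_est: float
    remaining_est: float
    p_end_within_k: float


@dataclass(frozen=True)
class SimState:
    """Instantaneous observable state handed to routing policies.

    ``n_completed`` and ``sum_quality_completed`` summarize the shift so
    far (feedback becomes observable when a chat ends); lookahead policies
    use them to score candidate decisions on the same quality/quantity
    exchange rate the whole shift is judged by.
    """

    clock: float
    shift_horizon_s: float
    waiting: tuple[CallerView, ...]
    free_agents: tuple[AgentProfile, ...]
    busy: tuple[BusyChat, ...]
    n_served: int
    n_abandoned: int
    n_completed: int = 0
    sum_quality_completed: float = 0.0


@dataclass(frozen=True)
class PolicyDecision:
    """A set of (caller_id, agent_id) matches; empty means the null action."""

    matches: tuple[tuple[str, str], ...] = ()


class InfeasibleDecisionError(RuntimeError):
    """A policy proposed a match that violates the state's constraints."""


class RoutingPolicy(Protocol):
    name: str

    def decide(
        self,
        state: SimState,
        predictors: PredictorBundle,
        rng: Optional[np.random.Generator],
    ) -> PolicyDecision: ...


def _validate_decision(state: SimState, decision: PolicyDecision) -> None:
    waiting_ids = {c.caller_id for c in state.waiting}
    free_ids = {a.agent_id for a in state.free_agents}
    seen_c: set[str] = set()
    seen_a: set[str] = set()
    for cid, aid in decision.matches:
        if cid not in waiting_ids:
            raise InfeasibleDecisionError(f"caller {cid!r} is not waiting")
        if aid not in free_ids:
            raise InfeasibleDecisionError(f"agent {aid!r} is not free")
        if cid in seen_c:
            raise InfeasibleDecisionError(f"caller {cid!r} matched twice")
        if aid in seen_a:
            raise InfeasibleDecisionError(f"agent {aid!r} matched twice")
        seen_c.add(cid)
        seen_a.add(aid)


def apply_decision(state: SimState, decision: PolicyDecision) -> SimState:
    """Apply a decision to an observable state, enforcing feasibility.

    Matched callers leave the queue and matched agents move to busy (elapsed
    0, estimates left at the pre-chat duration).  The engine uses the same
    validation internally; this pure version exists for contract tests and
    for policies that want to reason about post-decision states.
    """
    _validate_decision(state, decision)
    if not decision.matches:
        return state
    matched_c = {cid for cid, _ in decision.matches}
    matched_a = {aid for _, aid in decision.matches}
    caller_by_id = {c.caller_id: c for c in state.waiting}
    agent_by_id = {a.agent_id: a for a in state.free_agents}
    new_busy = list(state.busy)
    for cid, aid in decision.matches:
        new_busy.append(
            BusyChat(
                agent=agent_by_id[aid],
                caller=caller_by_id[cid],
                elapsed=0.0,
                base_duration_est=float("nan"),
                remaining_est=float("nan"),
                p_end_within_k=float("nan"),
            )
        )
    return SimState(
        clock=state.clock,
        shift_horizon_s=state.shift_horizon_s,
        waiting=tuple(c for c in state.waiting if c.caller_id not in matched_c),
        free_agents=tuple(a for a in state.free_agents if a.agent_id not in matched_a),
        busy=tuple(new_busy),
        n_served=state.n_served + len(decision.matches),
        n_abandoned=state.n_abandoned,
    )


@dataclass
class ShiftTrace:
    """Replayable event log plus per-call summary records."""

    events: list[dict] = field(default_factory=list)
    calls: dict[str, dict] = field(default_factory=dict)

    def log(self, time: float, kind: str, subject: str, **payload) -> None:
        self.events.append({"time": time, "kind": kind, "subject": subject, **payload})

    def to_jsonl(self, path: str) -> None:
        with open(path, "w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev) + "\n")

    def calls_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [{"caller_id": cid, **rec} for cid, rec in sorted(self.calls.items())]
        )

    def recompute_metrics(self) -> ShiftMetrics:
        """Re-derive the shift metrics from the per-call records alone."""
        n_arrived = len(self.calls)
        served = [r for r in self.calls.values() if r["served"]]
        n_abandoned = sum(1 for r in self.calls.values() if r.get("abandoned"))
        n_waiting = n_arrived - len(served) - n_abandoned
        return make_shift_metrics(
            n_arrived,
            len(served),
            n_abandoned,
            n_waiting,
            [r["quality"] for r in served],
        )


def _caller_view(c) -> CallerView:
    return CallerView(
        caller_id=c.caller_id,
        arrival_time=c.arrival_time,
        age_group=c.age_group,
        device=c.device,
        is_returning=c.is_returning,
        trait=c.trait,
    )


def run_shift(
    scenario: ShiftScenario,
    policy: RoutingPolicy,
    predictors: PredictorBundle,
    policy_rng: Optional[np.random.Generator] = None,
) -> tuple[ShiftMetrics, ShiftTrace]:
    """Simulate one shift under a routing policy.

    The environment is fully determined by the scenario (hidden patiences
    and memoized realized outcomes); ``policy_rng`` feeds only the policy's
    own stochasticity (e.g. MCTS rollouts), so planning noise never perturbs
    the simulated world.
    """
    horizon = scenario.horizon
    trace = ShiftTrace()

    callers = {c.caller_id: c for c in scenario.callers}
    agents = {a.agent_id: a for a in scenario.agents}
    waiting: dict[str, object] = {}  # caller_id -> CallerProfile, insertion-ordered
    free: dict[str, AgentProfile] = dict(sorted(agents.items()))
    # agent_id -> (caller_profile, start_time, outcome)
    in_chat: dict[str, tuple] = {}
    served_q: list[float] = []
    n_served = n_abandoned = 0
    n_completed = 0
    sum_quality_completed = 0.0
    intake_open = True

    heap: list[tuple[float, int, str]] = [(horizon, _P_SHIFT_END, "")]
    for c in scenario.callers:
        heapq.heappush(heap, (c.arrival_time, _P_ARRIVAL, c.caller_id))
        heapq.heappush(
            heap, (c.arrival_time + c.true_patience, _P_ABANDON, c.caller_id)
        )

    def observable(clock: float) -> SimState:
        busy = []
        for aid in sorted(in_chat):
            caller, start, _outcome = in_chat[aid]
            elapsed = clock - start
            view = _caller_view(caller)
            base = predictors.remaining_base_duration(caller, agents[aid])
            rem, p_end = predictors.predict_remaining(caller, agents[aid], elapsed)
            busy.append(
                BusyChat(
                    agent=agents[aid],
                    caller=view,
                    elapsed=elapsed,
                    base_duration_est=base,
                    remaining_est=rem,
                    p_end_within_k=p_end,
                )
            )
        return SimState(
            clock=clock,
            shift_horizon_s=horizon,
            waiting=tuple(
                _caller_view(c)
                for c in sorted(waiting.values(), key=lambda c: (c.arrival_time, c.caller_id))
            ),
            free_agents=tuple(free[a] for a in sorted(free)),
            busy=tuple(busy),
            n_served=n_served,
            n_abandoned=n_abandoned,
            n_completed=n_completed,
            sum_quality_completed=sum_quality_completed,
        )

    def start_chat(clock: float, cid: str, aid: str) -> None:
        nonlocal n_served
        caller = waiting.pop(cid)
        agent = free.pop(aid)
        outcome = scenario.realized_outcome(caller, agent)
        in_chat[aid] = (caller, clock, outcome)
        n_served += 1
        served_q.append(outcome.quality)
        heapq.heappush(heap, (clock + outcome.duration, _P_CHAT_END, aid))
        rec = trace.calls[cid]
        rec.update(
            served=True,
            agent_id=aid,
            wait_s=clock - caller.arrival_time,
            start_s=clock,
            duration_s=outcome.duration,
            feedback=outcome.feedback,
            quality=outcome.quality,
        )
        trace.log(clock, "chat_start", cid, agent_id=aid)

    def routing_round(clock: float) -> None:
        """Invoke the policy until it passes (null action) or nothing is feasible."""
        while intake_open and waiting and free:
            state = observable(clock)
            decision = policy.decide(state, predictors, policy_rng)
            _validate_decision(state, decision)
            if not decision.matches:
                trace.log(clock, "null_action", policy.name)
                return
            for cid, aid in decision.matches:
                start_chat(clock, cid, aid)

    while heap:
        time, prio, subject = heapq.heappop(heap)
        if prio == _P_SHIFT_END:
            intake_open = False
            for cid in list(waiting):
                trace.calls[cid].update(served=False, abandoned=False)
            trace.log(time, "shift_end", "")
            # ongoing chats drain via their chat_end events
        elif prio == _P_ARRIVAL:
            caller = callers[subject]
            waiting[subject] = caller
            trace.calls[subject] = {"arrival_s": caller.arrival_time, "served": False}
            trace.log(time, "arrival", subject)
            routing_round(time)
        elif prio == _P_CHAT_END:
            if subject not in in_chat:
                continue
            caller, start, outcome = in_chat.pop(subject)
            free[subject] = agents[subject]
            free = dict(sorted(free.items()))
            n_completed += 1
            sum_quality_completed += outcome.quality
            trace.log(time, "chat_end", subject, caller_id=caller.caller_id)
            if intake_open:
                routing_round(time)
        else:  # abandonment
            if subject in waiting and intake_open:
                caller = waiting.pop(subject)
                n_abandoned += 1
                trace.calls[subject].update(
                    served=False,
                    abandoned=True,
                    abandoned_s=time,
                    wait_s=time - caller.arrival_time,
                )
                trace.log(time, "abandonment", subject)

    n_waiting_end = len(scenario.callers) - n_served - n_abandoned
    metrics = make_shift_metrics(
        len(scenario.callers), n_served, n_abandoned, n_waiting_end, served_q
    )
    return metrics, trace
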