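"""Generic Monte Carlo tree search (UCT) and an exact expectimax oracle.

Both operate on a small *decision process* protocol so the same machinery
drives the routing lookahead and the tiny test instances:

* ``actions(s)`` — ordered feasible actions at a decision state;
* ``step(s, a, rng)`` — sample the next decision state (stochastic);
* ``is_terminal(s)`` / ``terminal_value(s)`` — episode end and its value
  in [0, 1];
* ``rollout_value(s, rng)`` — heuristic playout to the end, returning the
  terminal value;
* ``chance_outcomes(s, a)`` — optional exact enumeration of (probability,
  next state) pairs; only processes with finite outcome support provide it,
  and only the expectimax oracle needs it.

Chance after an action is handled with progressive widening: the number of
sampled child states kept under an action edge grows like
``ceil(k * visits^a)``; revisits re-use stored children in proportion to how
often they were drawn, which keeps the tree finite under continuous noise
while remaining exact for deterministic transitions (children are keyed by
state, so a deterministic step always maps to a single child).
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Any, Hashable, Optional, Protocol, Sequence

import numpy as np

from .config import MctsConfig

__all__ = ["DecisionProcess", "SearchStats", "uct_search", "expectimax"]


class DecisionProcess(Protocol):
    def actions(self, state) -> Sequence[Hashable]: ...

    def is_terminal(self, state) -> bool: ...

    def step(self, state, action, rng: np.random.Generator): ...

    def terminal_value(self, state) -> float: ...

    def rollout_value(self, state, rng: np.random.Generator) -> float: ...


class _Edge:
    __slots__ = ("visits", "total", "total_sq", "children", "draws")

    def __init__(self) -> None:
        self.visits = 0
        self.total = 0.0
        self.total_sq = 0.0
        self.children: dict[Any, "_Node"] = {}
        self.draws: dict[Any, int] = {}

    @property
    def mean(self) -> float:
        return self.total / self.visits if self.visits else 0.0

    def lcb(self, z: float) -> float:
        """Mean minus z standard errors (conservative final-selection score)."""
        if self.visits == 0:
            return -math.inf
        if self.visits == 1:
            return self.mean - z * 0.25
        var = max(0.0, self.total_sq / self.visits - self.mean**2)
        return self.mean - z * math.sqrt(var / self.visits)


class _Node:
    __slots__ = ("visits", "total", "edges", "actions")

    def __init__(self) -> None:
        self.visits = 0
        self.total = 0.0
        self.edges: dict[Hashable, _Edge] = {}
        self.actions: Optional[list] = None

    @property
    def mean(self) -> float:
        return self.total / self.visits if self.visits else 0.0


@dataclass
class SearchStats:
    """Root-level summary of one UCT search."""

    n_rollouts: int
    best_action: Hashable
    root_value: float
    action_visits: dict = field(default_factory=dict)
    action_values: dict = field(default_factory=dict)


def uct_search(
    process: DecisionProcess,
    root_state,
    cfg: MctsConfig,
    rng: np.random.Generator,
) -> SearchStats:
    """Run UCT from ``root_state`` and return the most-visited root action.

    Honors the anytime contract: after any number of completed iterations
    >= 1 (or when ``cfg.time_budget_ms`` expires) the returned action is a
    feasible member of ``process.actions(root_state)``.
    """
    root_actions = list(process.actions(root_state))
    if not root_actions:
        raise ValueError("no feasible action at the root")
    if len(root_actions) == 1:
        return SearchStats(0, root_actions[0], 0.0, {root_actions[0]: 0}, {})

    root = _Node()
    deadline = (
        time.monotonic() + cfg.time_budget_ms / 1000.0
        if cfg.time_budget_ms is not None
        else None
    )
    c = cfg.uct_c
    # Common random numbers across sibling root actions: the v-th visit of
    # every root action replays the same chance stream, so differences of
    # action means cancel the shared future-world noise instead of competing
    # against it.  crn_base ties the streams to the caller-provided rng.
    crn_base = int(rng.integers(0, 2**31))
    crn_capable = hasattr(process, "begin_iteration")
    root_paired = cfg.root_paired and crn_capable

    for it in range(cfg.n_rollouts):
        if deadline is not None and it > 0 and time.monotonic() > deadline:
            break
        node, state = root, root_state
        path: list[_Edge] = []
        path_nodes: list[_Node] = [root]
        depth = 0
        sim_rng = rng
        value: Optional[float] = None
        while True:
            if process.is_terminal(state) or depth >= cfg.max_depth:
                value = process.terminal_value(state)
                break
            if node.visits == 0 and node is not root:
                value = process.rollout_value(state, sim_rng)
                break
            if node.actions is None:
                node.actions = list(process.actions(state))
            if depth == 0 and root_paired:
                # exactly paired root evaluation: world v (the CRN stream
                # seeded by the edge's visit count) is played through every
                # root action once before any action sees world v+1
                action = node.actions[it % len(node.actions)]
            else:
                limit_a = max(
                    1,
                    math.ceil(
                        cfg.action_widening_k
                        * (node.visits + 1) ** cfg.action_widening_a
                    ),
                )
                acts = node.actions[:limit_a]
                # pick an untried action first (in listed order), else max UCB
                action = None
                for a in acts:
                    e = node.edges.get(a)
                    if e is None or e.visits == 0:
                        action = a
                        break
                if action is None:
                    log_n = math.log(node.visits + 1)
                    best_ucb = -math.inf
                    for a in acts:
                        e = node.edges[a]
                        ucb = e.mean + c * math.sqrt(log_n / e.visits)
                        if ucb > best_ucb:
                            best_ucb = ucb
                            action = a
            edge = node.edges.get(action)
            if edge is None:
                edge = node.edges[action] = _Edge()
            if depth == 0:
                if crn_capable:
                    # entity-keyed common random worlds: the v-th visit of
                    # every root action shares one sampled future
                    process.begin_iteration(
                        (crn_base * 0x9E3779B1 + edge.visits) & 0xFFFFFFFFFFFFFFFF
                    )
                else:
                    sim_rng = np.random.default_rng((crn_base, edge.visits))
            # chance node: progressive widening over sampled next states
            limit = max(1, math.ceil(cfg.widening_k * (edge.visits + 1) ** cfg.widening_a))
            if len(edge.children) < limit:
                child_state = process.step(state, action, sim_rng)
                child = edge.children.get(child_state)
                if child is None:
                    child = edge.children[child_state] = _Node()
                    edge.draws[child_state] = 0
            else:
                keys = list(edge.children)
                weights = np.array([edge.draws[k] + 1.0 for k in keys])
                child_state = keys[sim_rng.choice(len(keys), p=weights / weights.sum())]
                child = edge.children[child_state]
            edge.draws[child_state] += 1
            path.append(edge)
            path_nodes.append(child)
            node, state = child, child_state
            depth += 1
        for e in path:
            e.visits += 1
            e.total += value
            e.total_sq += value * value
        for n in path_nodes:
            n.visits += 1
            n.total += value

    visited = {a: e.visits for a, e in root.edges.items()}
    # Root value via max-backup over the built tree: running means are
    # dragged down by early suboptimal subtree play, so back values up with
    # a Bellman max at decision nodes and draw-weighted averaging at chance
    # nodes instead.
    root_value = _backup_value(root)
    # Conservative final selection: maximize the lower confidence bound of
    # the action mean, so a challenger must beat the front-runner by more
    # than its own estimation noise (guards against the optimizer's curse
    # at small rollout budgets).  Ties resolve to the earliest action in the
    # process's (utility-ordered) action list.
    scored = [
        (root.edges[a].lcb(cfg.final_select_z), -i, a)
        for i, a in enumerate(root_actions)
        if a in root.edges and root.edges[a].visits > 0
    ]
    best = max(scored)[2] if scored else root_actions[0]
    values = {a: e.mean for a, e in root.edges.items() if e.visits > 0}
    return SearchStats(
        n_rollouts=it + 1,
        best_action=best,
        root_value=root_value,
        action_visits=visited,
        action_values=values,
    )


def _backup_value(node: _Node) -> float:
    visited = [(a, e) for a, e in node.edges.items() if e.visits > 0]
    if not visited:
        return node.mean
    best = -math.inf
    for _a, e in visited:
        total_draws = sum(e.draws.values())
        if total_draws == 0:
            continue
        v = sum(
            (e.draws[k] / total_draws) * _backup_value(child)
            for k, child in e.children.items()
            if e.draws.get(k, 0) > 0
        )
        best = max(best, v)
    return best if best > -math.inf else node.mean


def expectimax(
    process,
    state,
    max_depth: int = 64,
    max_states: int = 200_000,
) -> tuple[float, Optional[Hashable]]:
    """Exact expectimax value by full enumeration of action and chance branches.

    Requires the process to implement ``chance_outcomes(state, action)``
    (finite support).  Refuses instances whose enumeration exceeds
    ``max_states`` expanded nodes — this is a test oracle for tiny problems,
    not a solver.
    """
    cache: dict[tuple[Any, int], tuple[float, Optional[Hashable]]] = {}
    expanded = [0]

    def value(s, depth: int) -> tuple[float, Optional[Hashable]]:
        if process.is_terminal(s) or depth >= max_depth:
            return process.terminal_value(s), None
        key = (s, depth)
        hit = cache.get(key)
        if hit is not None:
            return hit
        expanded[0] += 1
        if expanded[0] > max_states:
            raise ValueError(
                f"instance too large for exhaustive expectimax (> {max_states} states)"
            )
        best_v, best_a = -math.inf, None
        for a in process.actions(s):
            ev = 0.0
            for p, s2 in process.chance_outcomes(s, a):
                ev += p * value(s2, depth + 1)[0]
            if ev > best_v + 1e-12:
                best_v, best_a = ev, a
        cache[key] = (best_v, best_a)
        return best_v, best_a

    return value(state, 0)
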