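"""Lookahead model of the routing problem for Monte Carlo tree search.

The planner cannot see ground truth, so it searches a *belief* model built
entirely from the four predictors and the known scenario parameters:

* future arrivals are sampled from the shift's arrival intensity;
* waiting callers abandon after exponential times with the predicted
  patience mean (memorylessness lets the clock restart at the root);
* a match resolves the chat's planned duration immediately: the pre-chat
  duration estimate plus a draw from the Normal inaccuracy-error model;
* chats already in progress at the root end at a truncated-Normal time
  implied by the remaining-time predictor, conditioned on having survived
  to the root.

**Common random worlds.** Every search iteration carries a seed, and all
exogenous draws are deterministic functions of (iteration seed, entity):
caller 7's patience, the duration noise of caller 7's chat, agent 2's
inherited chat end, the n-th future arrival time.  Competing root actions
are therefore evaluated against *identical* sampled futures and their value
estimates differ only through the consequences of the decision — the
common-random-numbers device that makes paired policy comparison feasible
at small rollout budgets.  Each caller chats at most once per lookahead, so
sharing one duration-noise draw per caller across candidate agents
preserves the marginal outcome law.

A lookahead episode runs to the planning horizon and then *runs down*:
arrivals stop, but the continuation policy keeps serving (or losing) the
remaining waiting callers until every fate is decided — except at the true
shift end, where intake closes and waiting callers count as lost, exactly
as in the shift engine.  The episode is scored with the shift objective:
matches credit their predicted quality in expected-realized-feedback
currency, abandonments count in full, and the tallies are seeded with the
shift's own history (completed chats at their realized qualities, ongoing
chats at predictions) so the window's marginal quality/quantity exchange
rate equals the shift metric's.  Chats inherited from before the root only
occupy agents; their credited quality belongs to decisions already taken.

Noise modes: ``normal`` (the real planner), ``none`` and ``two_point``
(finite support, enumerable by the expectimax test oracle together with
``deterministic`` patience and arrivals switched off).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.special import ndtri


def ndtr(x: float) -> float:
    """Standard normal CDF (scalar, via math.erf for speed)."""
    return 0.5 * (1.0 + math.erf(x * 0.7071067811865476))

from .config import SimConfig
from .domain import AGE_GROUPS, AgentProfile
from .engine import CallerView, SimState
from .predictors import PredictorBundle

__all__ = ["PlanCaller", "PlanBusy", "PlanState", "RoutingPlanningProcess"]

_NULL = ("null",)
_M64 = 0xFFFFFFFFFFFFFFFF


def _splitmix_u(seed: int, code: int) -> float:
    """Deterministic uniform in (0, 1) from (iteration seed, entity code)."""
    x = (seed ^ (code * 0x9E3779B97F4A7C15)) & _M64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _M64
    x ^= x >> 31
    return ((x >> 11) + 0.5) / 9007199254740992.0


class PlanCaller(NamedTuple):
    cid: str
    uid: int  # entity key for common-random-world draws
    arrival: float
    pmean: float  # predicted mean patience (s)
    abandon_t: float  # fixed abandon time (deterministic patience mode only)
    q_est: tuple[float, ...]  # expected realized quality per agent index
    d_est: tuple[float, ...]  # predicted duration per agent index
    q_util: tuple[float, ...]  # raw predicted quality, for utility ordering


class PlanBusy(NamedTuple):
    agent: int
    base_dur: float  # duration mean the end-time model conditions on
    start: float
    q_est: float
    counted: bool  # True for matches made inside the lookahead window
    end: float  # resolved end time; +inf -> inherited, drawn per world


class PlanState(NamedTuple):
    t: float
    waiting: tuple[PlanCaller, ...]
    free: tuple[int, ...]
    busy: tuple[PlanBusy, ...]
    n_abandoned: int
    n_matched: int
    served_w: float
    qual_sum: float
    arrivals_seen: int


@dataclass
class RoutingPlanningProcess:
    """Belief-model decision process for one routing decision point."""

    agents: Sequence[AgentProfile]
    bundle: PredictorBundle
    sim_cfg: SimConfig
    plan_start: float
    plan_end: float
    duration_noise: str = "normal"  # normal | none | two_point
    patience_mode: str = "exponential"  # exponential | deterministic
    arrivals: bool = True
    prune_dominated: bool = True
    rollout_policy: str = "cmt"  # cmt | fcfs
    #: how imagined future arrivals are represented: "mean" plugs in the
    #: population-average predictions (low-variance, slightly biased),
    #: "sampled" draws caller features and predicts per pair
    future_callers: str = "mean"
    #: optional gate: offer the null action only when some ongoing chat is
    #: predicted to end within k minutes with at least this probability.
    #: 0 (default) keeps deferral always on the menu — the planner's
    #: anticipation of chat ends and abandonments is what makes deferral
    #: pay, and it is priced by the search itself
    null_gate_p_end: float = 0.0
    #: at the root decision epoch, restrict match actions to the agent in
    #: the greedy-best pair: the engine re-invokes the policy for remaining
    #: free agents at the same clock, so one search need only settle one
    #: agent's assignment, and a small rollout budget divides over far
    #: fewer actions.  Deeper (same-clock) decision nodes are unrestricted.
    root_focus_agent: bool = True
    #: particle pool for sampled future callers: features (and their
    #: per-agent predictions) are drawn once per decision and worlds index
    #: into the pool, which keeps the caller distribution honest while
    #: avoiding a fresh surrogate evaluation per sampled arrival
    future_pool_size: int = 16
    pool_seed: int = 12345

    _iter_seed: Optional[int] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.duration_noise not in ("normal", "none", "two_point"):
            raise ValueError(f"unknown duration_noise {self.duration_noise!r}")
        if self.patience_mode not in ("exponential", "deterministic"):
            raise ValueError(f"unknown patience_mode {self.patience_mode!r}")
        if self.future_callers not in ("mean", "sampled"):
            raise ValueError(f"unknown future_callers mode {self.future_callers!r}")
        scen = self.sim_cfg.scenario
        self._shift_end = scen.horizon_s
        self._sigma_d = scen.sigma_d
        self._sigma_q = scen.sigma_q
        self._floor = scen.duration_floor_s
        self._lam_max = scen.base_rate_per_h * max(m for _, m in scen.rate_profile) / 3600.0
        self._rate_flat = len(scen.rate_profile) == 1
        self._age_cum = np.cumsum(scen.age_group_probs)
        self._uid_ctr = 0
        self._root_n_matched = -1  # set by root_from_sim_state
        # per-iteration world caches (entity -> realized value)
        self._pat: dict[int, float] = {}
        self._durn: dict[int, float] = {}
        self._endt: dict[int, float] = {}
        self._arr: list[float] = []
        self._arr_draws = 0
        self._future_cache: dict[int, PlanCaller] = {}
        self._mean_future: Optional[tuple] = None
        self._pool: Optional[list[PlanCaller]] = None
        if self.future_callers == "sampled":
            rng = np.random.default_rng(self.pool_seed)
            self._pool = [
                self.plan_caller(self._draw_caller_view(f"~p{i}", 0.0, rng), uid=-1)
                for i in range(self.future_pool_size)
            ]
        if self.future_callers == "mean":
            # population-average predictions per agent, estimated once from a
            # fixed caller sample (deterministic; respects predictor wiring)
            rng = np.random.default_rng(12345)
            views = [self._draw_caller_view("~pop", 0.0, rng) for _ in range(64)]
            q = np.zeros(len(self.agents))
            d = np.zeros(len(self.agents))
            qr = np.zeros(len(self.agents))
            p = 0.0
            for v in views:
                p += self.bundle.predict_patience(v)
                for j, ag in enumerate(self.agents):
                    dur, qual = self.bundle.predict_pre_chat(v, ag)
                    d[j] += dur
                    q[j] += self.expected_realized_quality(qual)
                    qr[j] += qual
            self._mean_future = (
                tuple(q / len(views)),
                tuple(d / len(views)),
                p / len(views),
                tuple(qr / len(views)),
            )

    # -- common-random-world plumbing ------------------------------------
    def begin_iteration(self, seed: int) -> None:
        """Start a fresh sampled world: clear all realized-draw caches."""
        self._iter_seed = seed & _M64
        self._pat.clear()
        self._durn.clear()
        self._endt.clear()
        self._arr.clear()
        self._arr_draws = 0
        self._future_cache.clear()

    def _ensure_world(self, rng: Optional[np.random.Generator]) -> None:
        if self._iter_seed is None:
            seed = int(rng.integers(0, 2**62)) if rng is not None else 0
            self.begin_iteration(seed)

    def _u(self, code: int) -> float:
        return _splitmix_u(self._iter_seed, code)

    def _abandon_time(self, c: PlanCaller) -> float:
        """This world's abandonment time for a waiting caller.

        Exponential patience is memoryless, so a caller already waiting at
        the root restarts their clock there; future arrivals anchor at their
        arrival time.
        """
        if self.patience_mode == "deterministic":
            return c.abandon_t
        t = self._pat.get(c.uid)
        if t is None:
            anchor = c.arrival if c.arrival > self.plan_start else self.plan_start
            t = anchor - c.pmean * math.log(1.0 - self._u(c.uid * 8 + 1))
            self._pat[c.uid] = t
        return t

    def _duration_noise(self, uid: int) -> float:
        if self.duration_noise == "none" or self._sigma_d <= 0:
            return 0.0
        eps = self._durn.get(uid)
        if eps is None:
            u = self._u(uid * 8 + 2)
            if self.duration_noise == "two_point":
                eps = self._sigma_d if u < 0.5 else -self._sigma_d
            else:
                eps = self._sigma_d * float(ndtri(u))
            self._durn[uid] = eps
        return eps

    def _inherited_end(self, b: PlanBusy) -> float:
        """This world's end time of a chat already running at the root."""
        e = self._endt.get(b.agent)
        if e is None:
            elapsed = self.plan_start - b.start
            if self._sigma_d <= 0:
                e = b.start + max(b.base_dur, elapsed)
            else:
                a = float(ndtr((elapsed - b.base_dur) / self._sigma_d))
                if a >= 1.0 - 1e-15:
                    e = self.plan_start  # hopelessly overdue
                else:
                    u = a + self._u(b.agent * 8 + 3) * (1.0 - a)
                    e = b.start + b.base_dur + self._sigma_d * float(ndtri(u))
            self._endt[b.agent] = e
        return e

    def _arrival_time(self, n: int) -> float:
        """This world's n-th future arrival time (inf when beyond horizon)."""
        scen = self.sim_cfg.scenario
        while len(self._arr) <= n:
            if self._arr and self._arr[-1] == math.inf:
                self._arr.append(math.inf)
                continue
            t = self._arr[-1] if self._arr else self.plan_start
            while True:
                k = self._arr_draws
                self._arr_draws += 1
                t -= math.log(1.0 - self._u(k * 8 + 4)) / self._lam_max
                if t >= self.plan_end or t >= scen.horizon_s:
                    t = math.inf
                    break
                if self._rate_flat:
                    break
                rate = scen.base_rate_per_h / 3600.0
                mult = scen.rate_profile[0][1]
                for start, m in scen.rate_profile:
                    if t >= start:
                        mult = m
                if self._u(k * 8 + 5) * self._lam_max <= rate * mult:
                    break
            self._arr.append(t)
        return self._arr[n]

    # -- state construction ---------------------------------------------
    def expected_realized_quality(self, q_est: float) -> float:
        """Expected normalized feedback given the predicted quality.

        The environment rounds the noisy latent score 1 + 4 q + eps to the
        1-5 Likert scale, which attenuates predicted quality differences
        near the scale ends; planning in this expected-realized currency
        keeps the lookahead's quality/quantity exchange rate honest.
        """
        if self._sigma_q <= 0:
            return round(1.0 + 4.0 * q_est) / 4.0 - 0.25
        latent = 1.0 + 4.0 * q_est
        # P(feedback <= f) = P(latent + eps < f + 0.5)
        prev = 0.0
        exp_q = 0.0
        for f in range(1, 5):
            c = float(ndtr((f + 0.5 - latent) / self._sigma_q))
            exp_q += (f - 1) / 4.0 * (c - prev)
            prev = c
        exp_q += 1.0 * (1.0 - prev)
        return exp_q

    def plan_caller(self, view: CallerView, uid: Optional[int] = None) -> PlanCaller:
        pmean = self.bundle.predict_patience(view)
        q, d, qraw = [], [], []
        for ag in self.agents:
            dur, qual = self.bundle.predict_pre_chat(view, ag)
            q.append(self.expected_realized_quality(qual))
            d.append(dur)
            qraw.append(qual)
        if uid is None:
            uid = self._uid_ctr
            self._uid_ctr += 1
        abandon_t = (
            view.arrival_time + pmean if self.patience_mode == "deterministic" else math.inf
        )
        return PlanCaller(
            cid=view.caller_id,
            uid=uid,
            arrival=view.arrival_time,
            pmean=pmean,
            abandon_t=abandon_t,
            q_est=tuple(q),
            d_est=tuple(d),
            q_util=tuple(qraw),
        )

    def root_from_sim_state(self, state: SimState) -> PlanState:
        """Build the planning root, seeding tallies with the shift so far.

        Completed chats enter with their realized qualities and ongoing
        chats with their predicted qualities, so the window's marginal
        quality/quantity exchange rate equals the shift-level metric's at
        this point of the shift — without the history a small window
        overweights quality (its quality pool is far smaller than the
        shift's) and the search drifts quality-ward at quantity's expense.
        History terms are constants across root actions, so paired
        comparisons are unaffected; only the marginals change.
        """
        agent_idx = {a.agent_id: i for i, a in enumerate(self.agents)}
        busy = []
        qual_sum = state.sum_quality_completed
        for b in state.busy:
            _, qual = self.bundle.predict_pre_chat(b.caller, b.agent)
            qual_sum += self.expected_realized_quality(qual)
            busy.append(
                PlanBusy(
                    agent=agent_idx[b.agent.agent_id],
                    base_dur=b.base_duration_est,
                    start=state.clock - b.elapsed,
                    q_est=0.0,
                    counted=False,
                    end=math.inf,
                )
            )
        self._uid_ctr = 0
        waiting = tuple(self.plan_caller(c) for c in state.waiting)
        n_hist = state.n_completed + len(state.busy)
        self._root_n_matched = n_hist
        return PlanState(
            t=state.clock,
            waiting=waiting,
            free=tuple(sorted(agent_idx[a.agent_id] for a in state.free_agents)),
            busy=tuple(busy),
            n_abandoned=state.n_abandoned,
            n_matched=n_hist,
            served_w=float(n_hist),
            qual_sum=qual_sum,
            arrivals_seen=0,
        )

    # -- decision-process protocol --------------------------------------
    def is_terminal(self, s: PlanState) -> bool:
        # run-down evaluation: the window stops admitting arrivals at the
        # horizon but keeps simulating until every waiting caller's fate is
        # decided (served by the continuation policy or abandoned), so no
        # caller is scored as an ambiguous "still waiting".  At the shift's
        # end intake closes for good: anyone still waiting there is lost,
        # exactly as in the shift engine.
        if s.t >= self._shift_end:
            return s.t >= self.plan_end
        return s.t >= self.plan_end and not s.waiting

    def actions(self, s: PlanState):
        if not s.waiting or not s.free or s.t >= self._shift_end:
            return [_NULL]
        pairs = [(c, a) for c in s.waiting for a in s.free]
        if (
            self.root_focus_agent
            and self.prune_dominated
            and len(s.free) > 1
            and s.t == self.plan_start
            and s.n_matched == self._root_n_matched
        ):
            best = max(
                pairs,
                key=lambda ca: ca[0].q_util[ca[1]] / (ca[0].d_est[ca[1]] * ca[0].pmean),
            )
            pairs = [(c, a) for c, a in pairs if a == best[1]]
        if self.prune_dominated:
            pairs = self._prune(pairs)
        # order by greedy utility so untried-action expansion (and the
        # final-selection tie-break) starts from the most promising matches
        pairs.sort(
            key=lambda ca: (
                -ca[0].q_util[ca[1]] / (ca[0].d_est[ca[1]] * ca[0].pmean),
                ca[0].arrival,
                ca[0].cid,
                ca[1],
            )
        )
        acts = [("match", c.cid, a) for c, a in pairs]
        if not self.prune_dominated or self._null_worth_considering(s):
            acts.append(_NULL)
        return acts

    def _null_worth_considering(self, s: PlanState) -> bool:
        """Optional null gate: defer only if an agent may free up soon."""
        if self.null_gate_p_end <= 0.0:
            return True
        k_s = 60.0 * self.bundle.k_min
        thr = self.null_gate_p_end
        for b in s.busy:
            if b.end != math.inf:
                if b.end - s.t <= k_s:
                    return True
                continue
            if self._sigma_d <= 0:
                if b.start + b.base_dur - s.t <= k_s:
                    return True
                continue
            a = ndtr((s.t - b.start - b.base_dur) / self._sigma_d)
            bb = ndtr((s.t + k_s - b.start - b.base_dur) / self._sigma_d)
            if 1.0 - a > 1e-12 and (bb - a) / (1.0 - a) >= thr:
                return True
        return False

    def _prune(self, pairs):
        """Drop pairs dominated for the same agent in (quality, duration, patience)."""
        keep = []
        for c, a in pairs:
            dominated = False
            for c2, a2 in pairs:
                if a2 != a or c2.cid == c.cid:
                    continue
                ge_q = c2.q_util[a] >= c.q_util[a]
                le_d = c2.d_est[a] <= c.d_est[a]
                le_p = c2.pmean <= c.pmean
                strict = (
                    c2.q_util[a] > c.q_util[a]
                    or c2.d_est[a] < c.d_est[a]
                    or c2.pmean < c.pmean
                )
                if ge_q and le_d and le_p and strict:
                    dominated = True
                    break
                if ge_q and le_d and le_p and (c2.arrival, c2.cid) < (c.arrival, c.cid):
                    dominated = True  # exact tie: keep the earlier arrival
                    break
            if not dominated:
                keep.append((c, a))
        return keep

    def step(self, s: PlanState, action, rng: Optional[np.random.Generator] = None) -> PlanState:
        self._ensure_world(rng)
        if action[0] == "match":
            return self._apply_match(s, action[1], action[2])
        return self._advance(s)

    def chance_outcomes(self, s: PlanState, action):
        """Finite-support enumeration; valid only in enumerable modes."""
        if self.arrivals or self.patience_mode != "deterministic":
            raise ValueError(
                "chance_outcomes requires arrivals off and deterministic patience"
            )
        if action[0] == "match":
            if self.duration_noise == "none":
                return [(1.0, self._apply_match(s, action[1], action[2], noise=0.0))]
            if self.duration_noise == "two_point":
                lo = self._apply_match(s, action[1], action[2], noise=-self._sigma_d)
                hi = self._apply_match(s, action[1], action[2], noise=+self._sigma_d)
                if lo == hi:
                    return [(1.0, lo)]
                return [(0.5, lo), (0.5, hi)]
            raise ValueError("normal duration noise is not enumerable")
        return [(1.0, self._advance(s))]

    # -- transitions -----------------------------------------------------
    def _apply_match(
        self, s: PlanState, cid: str, agent: int, noise: Optional[float] = None
    ) -> PlanState:
        caller = next(c for c in s.waiting if c.cid == cid)
        dur = caller.d_est[agent]
        dur += self._duration_noise(caller.uid) if noise is None else noise
        dur = max(self._floor, dur)
        busy = s.busy + (
            PlanBusy(
                agent=agent,
                base_dur=caller.d_est[agent],
                start=s.t,
                q_est=caller.q_est[agent],
                counted=True,
                end=s.t + dur,
            ),
        )
        return s._replace(
            waiting=tuple(c for c in s.waiting if c.cid != cid),
            free=tuple(a for a in s.free if a != agent),
            busy=busy,
            n_matched=s.n_matched + 1,
        )

    def _advance(self, s: PlanState) -> PlanState:
        """Advance to the next event: a chat end, an arrival, or an abandonment.

        All candidate times are this world's realized values; the earliest
        fires (ties: chat end, then arrival, then abandonment).  A candidate
        in the past — possible when the tree replays a stored state under a
        different world — fires immediately.
        """
        t = s.t
        if t < self.plan_end:
            best_t, best = self.plan_end, ("horizon", -1)
        else:
            best_t, best = math.inf, ("horizon", -1)
        for i, b in enumerate(s.busy):
            e = b.end if b.end != math.inf else self._inherited_end(b)
            if e < t:
                e = t
            if e < best_t:
                best_t, best = e, ("end", i)
        if self.arrivals and self._lam_max > 0:
            ta = self._arrival_time(s.arrivals_seen)
            if ta < best_t:
                best_t, best = ta, ("arrival", -1)
        for i, c in enumerate(s.waiting):
            ab = self._abandon_time(c)
            if ab < t:
                ab = t
            if ab < best_t:
                best_t, best = ab, ("abandon", i)

        kind = best[0]
        if kind == "horizon":
            if best_t == math.inf:
                # no pending events at all: the episode is over
                return s._replace(t=max(t, self.plan_end))
            return s._replace(t=self.plan_end)
        if kind == "end":
            i = best[1]
            b = s.busy[i]
            served_w, qual_sum = s.served_w, s.qual_sum
            if b.counted:
                served_w += 1.0
                qual_sum += b.q_est
            return s._replace(
                t=best_t,
                busy=s.busy[:i] + s.busy[i + 1 :],
                free=tuple(sorted(s.free + (b.agent,))),
                served_w=served_w,
                qual_sum=qual_sum,
            )
        if kind == "arrival":
            newc = self._future_caller(best_t, s.arrivals_seen)
            return s._replace(
                t=best_t,
                waiting=s.waiting + (newc,),
                arrivals_seen=s.arrivals_seen + 1,
            )
        i = best[1]
        return s._replace(
            t=best_t,
            waiting=s.waiting[:i] + s.waiting[i + 1 :],
            n_abandoned=s.n_abandoned + 1,
        )

    def _draw_caller_view(
        self, cid: str, t: float, rng: np.random.Generator
    ) -> CallerView:
        scen = self.sim_cfg.scenario
        device = "mobile" if rng.random() < scen.p_mobile else "desktop"
        age_group = AGE_GROUPS[int(np.searchsorted(self._age_cum, rng.random()))]
        return CallerView(
            caller_id=cid,
            arrival_time=t,
            age_group=age_group,
            device=device,
            is_returning=bool(rng.random() < scen.p_returning),
            trait=tuple(float(x) for x in rng.standard_normal(scen.trait_dim)),
        )

    def _future_caller(self, t: float, n: int) -> PlanCaller:
        uid = 1_000_000 + n
        if self._mean_future is not None:
            q, d, pmean, qraw = self._mean_future
            return PlanCaller(
                cid=f"~f{n}", uid=uid, arrival=t, pmean=pmean,
                abandon_t=t + pmean if self.patience_mode == "deterministic" else math.inf,
                q_est=q, d_est=d, q_util=qraw,
            )
        cached = self._future_cache.get(n)
        if cached is None:
            idx = (self._iter_seed ^ (n * 0x9E3779B1)) % len(self._pool)
            cached = self._pool[idx]
            self._future_cache[n] = cached
        abandon_t = t + cached.pmean if self.patience_mode == "deterministic" else math.inf
        return cached._replace(cid=f"~f{n}", uid=uid, arrival=t, abandon_t=abandon_t)

    # -- evaluation ------------------------------------------------------
    def terminal_value(self, s: PlanState) -> float:
        # chats still running count as served in full, as at a shift's end
        served_w, qual_sum = s.served_w, s.qual_sum
        for b in s.busy:
            if b.counted:
                served_w += 1.0
                qual_sum += b.q_est
        n = s.n_abandoned + s.n_matched
        if s.t >= self._shift_end:
            n += len(s.waiting)  # intake closed: still-waiting callers are lost
        quantity = 1.0 if n == 0 else min(1.0, served_w / n)
        quality = qual_sum / served_w if served_w > 0 else 0.0
        return 0.5 * quantity + 0.5 * quality

    def rollout_value(
        self,
        s: PlanState,
        rng: Optional[np.random.Generator] = None,
        policy: Optional[str] = None,
    ) -> float:
        """Playout to the horizon under the greedy rollout policy.

        Implemented on mutable locals for speed; because every draw is a
        memoized function of (iteration seed, entity), the realized world is
        identical to what the state-based transitions would produce.
        """
        self._ensure_world(rng)
        policy = policy or self.rollout_policy
        cmt = policy == "cmt"
        plan_end, shift_end = self.plan_end, self._shift_end
        arrivals_on = self.arrivals and self._lam_max > 0
        t = s.t
        waiting = list(s.waiting)
        free = list(s.free)
        # busy entries: [end_time, q_est, counted, agent_idx]
        busy = [
            [b.end if b.end != math.inf else self._inherited_end(b), b.q_est, b.counted, b.agent]
            for b in s.busy
        ]
        n_abandoned, n_matched = s.n_abandoned, s.n_matched
        served_w, qual_sum = s.served_w, s.qual_sum
        arrivals_seen = s.arrivals_seen
        noise_on = self.duration_noise != "none" and self._sigma_d > 0

        while True:
            if waiting and free and t < shift_end:
                if cmt:
                    best_u, ci, agent = -1.0, 0, free[0]
                    for i, c in enumerate(waiting):
                        inv_p = 1.0 / c.pmean
                        q, d = c.q_util, c.d_est
                        for a in free:
                            u = q[a] / d[a] * inv_p
                            if u > best_u:
                                best_u, ci, agent = u, i, a
                else:
                    ci = min(range(len(waiting)), key=lambda i: (waiting[i].arrival, waiting[i].cid))
                    agent = free[0]
                c = waiting.pop(ci)
                free.remove(agent)
                dur = c.d_est[agent]
                if noise_on:
                    dur += self._duration_noise(c.uid)
                if dur < self._floor:
                    dur = self._floor
                busy.append([t + dur, c.q_est[agent], True, agent])
                n_matched += 1
                continue
            # advance to the next event
            if t < plan_end:
                best_t, kind, idx = plan_end, 0, -1  # kind 0=horizon 1=end 2=arrival 3=abandon
            else:
                if not waiting or t >= shift_end:
                    break
                best_t, kind, idx = math.inf, 0, -1
            for i, b in enumerate(busy):
                e = b[0]
                if e < t:
                    e = t
                if e < best_t:
                    best_t, kind, idx = e, 1, i
            if arrivals_on:
                ta = self._arrival_time(arrivals_seen)
                if ta < best_t:
                    best_t, kind, idx = ta, 2, -1
            for i, c in enumerate(waiting):
                ab = self._abandon_time(c)
                if ab < t:
                    ab = t
                if ab < best_t:
                    best_t, kind, idx = ab, 3, i
            if kind == 0:
                if best_t == math.inf:
                    break
                t = plan_end
                if not waiting or t >= shift_end:
                    break
                continue
            t = best_t
            if kind == 1:
                b = busy.pop(idx)
                if b[2]:
                    served_w += 1.0
                    qual_sum += b[1]
                free.append(b[3])
                free.sort()
                continue
            if kind == 2:
                waiting.append(self._future_caller(t, arrivals_seen))
                arrivals_seen += 1
                continue
            waiting.pop(idx)
            n_abandoned += 1

        n = n_abandoned + n_matched
        if t >= shift_end:
            n += len(waiting)
        quantity = 1.0 if n == 0 else min(1.0, served_w / n)
        quality = qual_sum / served_w if served_w > 0 else 0.0
        return 0.5 * quantity + 0.5 * quality
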