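# Methods

This note documents the models inside `mhcc_sim`: what the synthetic shift
generator emulates, how the routing policies work, the numerical choices in
the Monte Carlo tree search, and what the included experiments can and
cannot show.

## The shift model

A shift is a time interval `[0, H)` (default `H` = 4 h) with a fixed agent
roster. Callers arrive by a non-homogeneous Poisson process
(Lewis–Shedler thinning against the piecewise-constant intensity bound);
each caller either starts a chat, abandons when their waiting time exceeds
their hidden patience, or is still waiting when the shift's intake closes.
Chats are non-preemptive and one-per-agent; a chat still running at the
shift end completes and counts as served. Routing decisions are triggered
by arrivals and chat ends; the policy may match any set of waiting callers
to free agents or defer (the null action).

Shift outcome: `Quantity` = served/arrived (1.0 for an empty shift),
`Quality` = mean normalized Likert feedback over served calls (abandoned
callers are penalized through Quantity only, because only served calls
produce feedback), and the objective is their equal-weight mean. Shifts
with no served call report Quality 0.0 with an `undefined` flag and are
excluded from batch Quality averages.

Event ties resolve deterministically (shift end, chat end, arrival,
abandonment; then by subject id), so a run is bit-reproducible from
(scenario config, seed, policy config, policy seed).

## The synthetic caller population

Callers carry observable features — device (60% mobile), ordinal age group,
returning flag, and a latent 2-vector `trait` standing in for everything a
pre-chat survey and chat-history features reveal — plus hidden ground
truth: an exponential patience draw and, lazily materialized, the realized
outcome of every possible pairing.

**Patience.** Exponential with mean
`base(device) × mult(age) × exp(w_p · trait₁) × scale`. The device base
means are anchored to observed device-specific mean waits (desktop 402 s,
mobile 266 s). Two calibration choices matter:

* `scale` (default 4.0). Observed waits censor patience from below — a
  served caller's patience exceeds their wait — so raw wait means
  understate patience. The scale also controls whether queues ever form: at
  scale 1, callers abandon faster than agents free up, 96% of decision
  points see at most one waiting caller, and *no* routing rule can express
  a preference. At scale 4, heavy-flow decision points see two or more
  waiting callers about a quarter of the time, which is the regime a
  routing study needs.
* `w_p` (default 1.0) spreads patience across callers by roughly an order
  of magnitude: some callers must be served within minutes, others will
  wait out most of a busy period. The spread is driven by an observable
  feature, so the patience predictor genuinely knows who is urgent.

**Outcomes.** Each (caller, agent) pair has a deterministic surrogate
standing in for trained outcome predictors:

```
log duration = mu_d + a_dur·z(agent experience) + c_dur·trait₀ + w_d·⟨trait, style⟩
quality      = logistic(mu_q + w_q·⟨trait, style⟩ + c_q·trait₀ − penalty·age_effect)
```

with `age_effect` > 0 for older agents unless the caller is 65+ (older
callers are more accepting of older agents; agent age is the single
strongest quality feature). Key choices:

* `w_d = −0.15`: well-matched pairs resolve *sooner* as well as better.
  This couples the two objectives constructively — informed routing can
  gain Quality and Quantity simultaneously, which is what distinguishes the
  prediction-based policies from FCFS on both axes. With the sign flipped
  (good matches longer), quality-per-second routing would actively avoid
  good matches.
* `mu_d` sets the mean chat near 17 minutes. Together with the staffing
  (2 agents standard, 4 heavy) and arrival rates (7/h, 10/h) this places
  heavy flow at offered load ≈ 0.8 with ~8–15% abandonment, and the
  standard setting near saturation, where policy differences in Quantity
  are small — the operating regime the evaluation design assumes.
* `mu_q = 1.9`, `w_q = 1.2`, `σ_q = 0.4` give mean feedback ≈ 4.1 under
  FCFS with enough pair-level spread that matching quality is worth
  pursuing, while Likert rounding and clipping attenuate differences near
  the scale ends (a 0.1 predicted-quality edge realizes as ~0.06).

**Realized outcomes** add Normal "inaccuracy" error to the surrogate
(`σ_d` = 250 s on duration, floored at 60 s; `σ_q` = 0.4 Likert units on
the latent feedback score, then rounded half-up and clipped to 1–5). The
realized outcome of a pair is memoized under a seed derived from (scenario
seed, caller, agent), so replaying a scenario under a different policy
faces the identical counterfactual world — the paired-design property all
comparisons rely on.

## Predictors

Four slots — pre-chat duration, pre-chat quality, patience, remaining time
— each either *oracle* (the noiseless surrogate / segment mean, i.e. pure
functions of observable features and generator parameters) or *naive* (the
population average, for the ablation). The remaining-time model treats the
realized duration `D` of an ongoing chat as
`Normal(base, σ_d)` truncated at the elapsed time and reports
`E[D | D > elapsed] − elapsed` together with `P(D ≤ elapsed + 60k | D >
elapsed)` (`k` = 3 min) in closed form. Oracle predictors never read
realized outcomes or realized patience.

## Policies

**FCFS** matches the longest-waiting caller to the lowest-id free agent.
**CMT** greedily matches the pair maximizing
`quality_est / (duration_est × patience_mean_est)`, ties broken by earliest
arrival then agent id; like FCFS it never defers. **MCTS** runs UCT over a
belief model at every decision trigger and emits one match (or defers);
the engine re-invokes it while matches remain feasible.

### The lookahead model

The planner simulates forward from the observable state using only
predictions: future arrivals from the known intensity, abandonments as
exponential clocks at the predicted patience means (memorylessness lets
the clock restart at the root), planned-chat durations at their predicted
values (certainty-equivalent), and inherited chat ends from the
remaining-time model's truncated Normal. A lookahead episode ends at the
planning horizon (default: the time remaining in the shift; the batch
experiments in this repository use a 1800 s window as their search budget)
with a run-down: arrivals stop, but every waiting caller's fate is resolved
by the continuation policy, so nobody is scored as an ambiguous "still
waiting". At the true shift end the run-down instead counts waiting callers
as lost, exactly as the engine does. Episode value is the shift objective
over history plus window: tallies are seeded with the shift's completed
chats (realized qualities) and ongoing chats (predicted qualities), so the
window's marginal quality/quantity exchange rate equals the shift
metric's. Match quality is valued in *expected realized feedback* — the
expectation of the rounded, clipped Likert score given the prediction —
not raw predicted quality, which would overvalue near-ceiling matches.

### Search mechanics at small rollout budgets

Shift-level value differences between good actions are of order 0.01 while
a single rollout return varies by an order of magnitude more, so the search
is built around variance control rather than raw exploration:

* **Common random worlds.** Every iteration carries a seed, and every
  exogenous draw is a deterministic function of (seed, entity): caller 7's
  patience, caller 7's duration noise, agent 2's inherited chat end, the
  n-th arrival time. Sibling root actions are therefore evaluated on
  identical sampled futures.
* **Paired root allocation.** Root visits go round-robin, so world *v* is
  played through every root action before any action sees world *v+1* —
  an exactly paired comparison. UCB with `c = √2` drives selection below
  the root, with progressive widening over both sampled chance outcomes
  and the (utility-ordered) action list.
* **Trust region around the greedy incumbent.** The action list is ordered
  by the CMT utility (computed on raw predicted quality, so the incumbent
  is exactly CMT's pick); the search's choice must beat the incumbent by
  `match_margin` (0.005) — and the null action must beat the best match by
  `null_margin` (0.002) — in estimated value before the policy deviates.
  Argmax selection over noisy estimates is biased upward (optimizer's
  curse); the margins are sized to that bias.
* **Root agent focus.** With several free agents, one search settles the
  assignment of the agent in the greedy-best pair; the engine re-invokes
  the policy for the others at the same clock. This multiplies
  worlds-per-action by the number of free agents.
* **Future-caller particles.** Imagined arrivals draw their features from
  a per-decision pool of 16 pre-evaluated candidates rather than fresh
  samples, trading a small discretization bias for an order of magnitude
  fewer surrogate evaluations.
* **Dominated-pair pruning.** A pair worse than another pair for the same
  agent in predicted quality, duration, and patience is dropped. All
  pruning and margins switch off for the exhaustive-search tests.
* The reported root value uses Bellman max-backup over the built tree
  (running means are dragged by early exploratory play).

MCTS honors the anytime contract: any number of completed rollouts ≥ 1 (or
a wall-clock budget via `time_budget_ms`) yields a feasible decision.

## Experiments

`run_batch` derives scenario seed *i* from (base seed, *i*) with a stable
64-bit mix, so batches with equal base seeds form paired experiments across
policies and predictor bundles; `compare_policies` is accordingly a paired
two-sided t-test on per-shift differences (significance at p ≤ 0.01). The
ablation replaces exactly one predictor slot per arm with its naive variant
and reruns MCTS on the same worlds.

Experiment sizes in the test suite and `scripts/acceptance.py`: 200 paired
shifts per comparison with 50 rollouts / 1800 s lookahead per decision, and
30 rollouts / 1200 s for the five-arm ablation; exhaustive-search checks use
micro-instances of ≤ 3 callers × ≤ 2 agents solved exactly by expectimax.
The library defaults remain 300 rollouts with lookahead to the end of the
shift.

## What the synthetic study shows — and what it does not

Under the default generator, 200 paired heavy-flow shifts give a mean
weighted objective ordering MCTS > CMT > FCFS with the MCTS–FCFS difference
significant at p far below 0.01, while the standard setting shows only
small inter-policy Quantity differences; dropping the feedback, patience,
or remaining-time predictor lowers the MCTS objective. These are
reproductions of qualitative *patterns* inside a synthetic world whose
heterogeneity is generated, not learned: the generator has no real chat
transcripts, no Hebrew text features, no learned feature–outcome map, and
its predictors are exact oracles of its own surrogate rather than models
with structured errors. Passing tests therefore validate the simulator,
the policies, and the experiment design — not the magnitude of gains any
real contact center should expect.

Known limitations:

* The pre-chat duration predictor's marginal value is small here: because
  well-matched pairs are also shorter (`w_d < 0`), the feedback model
  carries most of the duration signal, and the duration ablation arm
  hovers near zero. Real deployments with independently trained models
  need not show this redundancy.
* The remaining-time model is derived from the same pre-chat surrogate as
  the duration model (a transcript-based mid-chat model would be strictly
  more informative); its ablation effect is correspondingly modest.
* Caller redial, mid-chat abandonment, agent breaks, multi-chat
  concurrency, and fairness constraints are all out of scope.
* The empty-shift and no-served-call conventions (Quantity 1.0; Quality
  flagged undefined) matter only at very low load.
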