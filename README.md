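# mhcc-sim

Discrete-event simulation and prediction-based call routing for
mental-health contact centers (MHCCs).

MHCCs — emotional-first-aid hotlines and chat services — face a routing
problem that ordinary call centers do not: callers disclose almost nothing
before the conversation starts, outcomes depend heavily on the particular
counselor–caller pairing, and callers abandon the queue quickly when left
waiting. Most services route first-come-first-served (FCFS). This package
simulates an MHCC shift and compares FCFS against two prediction-based
routing policies:

* **CMT** — a greedy index rule descended from the classical cμ/θ priority
  rule for queues with impatient customers. A candidate (caller *c*, agent
  *a*) match is scored

  ```
  utility(c, a) = quality(c, a) / (duration(c, a) × patience(c))
  ```

  and the highest-utility feasible pair is matched at every decision point.

* **MCTS** — Monte Carlo tree search (UCT) over a belief model built from
  four prediction models: pre-chat chat duration, pre-chat quality
  (post-chat feedback on a 1–5 Likert scale), caller patience, and the
  remaining time of ongoing chats. The planner samples future arrivals,
  abandonments and chat ends, and may deliberately choose the *null action*
  — leaving an agent idle to reserve it for a better upcoming match.

A shift is scored on two equally weighted axes (both in [0, 1]):
**Quantity**, the fraction of arrived callers actually served (the
complement of the abandonment rate), and **Quality**, the mean normalized
feedback of served calls:

```
Obj = ½ · Quantity + ½ · Quality
```

Everything runs on synthetic shifts generated by the package itself:
non-homogeneous Poisson arrivals, exponentially distributed caller patience
with feature-dependent means (anchored to device-specific waiting-time
statistics: desktop 402 s vs mobile 266 s), and realized chat outcomes
equal to a deterministic caller×agent outcome surrogate plus fitted Normal
"inaccuracy" error. Routing policies only ever see predictions; the hidden
ground truth belongs to the simulation engine.

## Worked example

```python
from mhcc_sim import SimConfig, make_setting, run_batch, compare_policies, render_results_table
from mhcc_sim.config import MctsConfig

cfg = SimConfig(scenario=make_setting("heavy"))       # 10 calls/h, 4 agents
mcts = MctsConfig(n_rollouts=50, horizon_s=1800.0)    # desk-scale search budget
results = [run_batch(cfg, p, n_sims=200, base_seed=1, mcts_cfg=mcts)
           for p in ("fcfs", "cmt", "mcts")]
print(render_results_table(results))

by = {r.policy: r.table for r in results}
print(compare_policies(by["fcfs"]["objective"], by["mcts"]["objective"]))
```

Output (200 paired heavy-flow shifts, seed 1):

```
               fcfs    cmt   mcts
Quality       0.772  0.847  0.879
Quantity      0.923  0.941  0.926
Weighted sum  0.847  0.894  0.903
ComparisonResult(mean_diff=0.05531425681561736, p_value=2.749901221642489e-57, significant=True)
```

Reading: under heavy call flow, prediction-based routing raises served-call
quality from 0.77 to 0.85 (CMT) and 0.88 (MCTS) while serving at least as
many callers as FCFS; the weighted objective improves by ~0.05–0.06, and
the paired difference between MCTS and FCFS is significant far beyond
p ≤ 0.01. Because scenario seeds are shared, all three policies face
identical worlds — same arrivals, same hidden patiences, same
counterfactual outcome tables — so the contrast isolates the routing
decisions themselves.

The same machinery runs from a shell:

```bash
mhcc-sim compare --setting heavy --n 200 --seed 1 --rollouts 50 --out table.csv
mhcc-sim ablate  --n 200 --seed 1 --rollouts 30 --out ablation.csv
mhcc-sim run --setting standard --policy cmt --n 1000 --seed 7 --out shifts.csv
```

A YAML config file (`--config`) can override any scenario, predictor, or
search parameter; see `examples/config.yaml`.

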