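"""Batch experiment harness: replicated shifts, policy comparison, ablation.

The evaluation design is paired: within one comparison every policy faces
the *same* simulated worlds (identical arrival times, caller features,
hidden patiences, and realized outcome tables), because scenario seeds are
derived deterministically from (base_seed, replicate index).  Pairing
removes between-world variance from policy contrasts, which is why the
significance test is a paired t-test on per-shift differences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import MctsConfig, PredictorConfig, SimConfig
from .engine import run_shift
from .policies import make_policy
from .predictors import PredictorBundle
from .scenario import generate_scenario

__all__ = [
    "BatchResult",
    "AblationArm",
    "ComparisonResult",
    "scenario_seed",
    "run_batch",
    "run_ablation",
    "compare_policies",
    "render_results_table",
    "ABLATION_ARMS",
]

#: predictor slots in ablation order; "feedback" is the quality model
ABLATION_ARMS = ("none", "feedback", "duration", "patience", "remaining_time")

_ARM_TO_SLOT = {
    "feedback": "quality",
    "duration": "duration",
    "patience": "patience",
    "remaining_time": "remaining",
}


def scenario_seed(base_seed: int, i: int) -> int:
    """Stable 64-bit mix of (base_seed, replicate index) -> scenario seed."""
    return int(np.random.SeedSequence((base_seed, i)).generate_state(1, np.uint64)[0] % (1 << 31))


@dataclass
class BatchResult:
    """Per-shift metrics table plus summary statistics for one policy run."""

    setting: str
    policy: str
    n_sims: int
    table: pd.DataFrame

    def summary(self) -> dict[str, tuple[float, float]]:
        """(mean, sd) per metric; Quality averages skip no-served-call shifts."""
        t = self.table
        out = {}
        for metric in ("quantity", "objective"):
            out[metric] = (float(t[metric].mean()), float(t[metric].std(ddof=1)))
        q = t.loc[t["quality_defined"], "quality"]
        out["quality"] = (
            (float(q.mean()), float(q.std(ddof=1))) if len(q) else (float("nan"),) * 2
        )
        return out


@dataclass
class AblationArm:
    dropped: str
    result: BatchResult


@dataclass(frozen=True)
class ComparisonResult:
    mean_diff: float
    p_value: float
    significant: bool


def run_batch(
    sim_cfg: SimConfig,
    policy: str,
    n_sims: int,
    base_seed: int,
    mcts_cfg: Optional[MctsConfig] = None,
) -> BatchResult:
    """Simulate ``n_sims`` independent shifts under one policy.

    Scenario seed i depends only on (base_seed, i), so batches run with the
    same base_seed but different policies form a paired experiment.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    bundle = PredictorBundle(sim_cfg)
    pol = make_policy(policy, sim_cfg, mcts_cfg)
    rows = []
    for i in range(n_sims):
        seed = scenario_seed(base_seed, i)
        scenario = generate_scenario(sim_cfg.scenario, seed)
        policy_rng = np.random.default_rng(np.random.SeedSequence((base_seed, i, 0xA11CE)))
        metrics, _ = run_shift(scenario, pol, bundle, policy_rng)
        rows.append(
            {
                "replicate": i,
                "seed": seed,
                "n_arrived": metrics.n_arrived,
                "n_served": metrics.n_served,
                "n_abandoned": metrics.n_abandoned,
                "n_waiting_at_end": metrics.n_waiting_at_end,
                "quantity": metrics.quantity,
                "quality": metrics.quality,
                "objective": metrics.objective,
                "quality_defined": metrics.quality_defined,
            }
        )
    return BatchResult(
        setting=sim_cfg.scenario.setting,
        policy=policy,
        n_sims=n_sims,
        table=pd.DataFrame(rows),
    )


def run_ablation(
    sim_cfg: SimConfig,
    base_seed: int,
    n_sims: int,
    mcts_cfg: Optional[MctsConfig] = None,
) -> list[AblationArm]:
    """The predictor ablation: MCTS with one predictor slot made naive.

    Five arms share scenario seeds; arm "none" is the full-predictor
    baseline, every other arm replaces exactly one of the four models with
    the constant population-average predictor.
    """
    arms = []
    for dropped in ABLATION_ARMS:
        if dropped == "none":
            cfg = sim_cfg
        else:
            slot = _ARM_TO_SLOT[dropped]
            cfg = replace(
                sim_cfg, predictors=replace(sim_cfg.predictors, **{slot: "naive"})
            )
        arms.append(
            AblationArm(dropped=dropped, result=run_batch(cfg, "mcts", n_sims, base_seed, mcts_cfg))
        )
    return arms


def compare_policies(
    per_shift_a: Sequence[float],
    per_shift_b: Sequence[float],
    alpha: float = 0.01,
) -> ComparisonResult:
    """Paired two-sided t-test on per-shift metric differences (b - a)."""
    a = np.asarray(per_shift_a, dtype=float)
    b = np.asarray(per_shift_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired shifts")
    d = b - a
    mean_diff = float(d.mean())
    if np.all(d == d[0]):
        # zero-variance differences: identical vectors are a perfect null,
        # a constant nonzero shift is evidence beyond any finite t
        p = 1.0 if d[0] == 0.0 else 0.0
    else:
        p = float(stats.ttest_rel(b, a).pvalue)
    return ComparisonResult(mean_diff=mean_diff, p_value=p, significant=p <= alpha)


def render_results_table(results: Sequence[BatchResult]) -> pd.DataFrame:
    """Metrics-by-policy summary table (means to 3 decimals).

    Rows: Quality, Quantity, Weighted sum; one column per policy, in the
    order given.  All results must come from the same setting.
    """
    settings = {r.setting for r in results}
    if len(settings) > 1:
        raise ValueError(f"mixed settings in one table: {sorted(settings)}")
    cols = {}
    for r in results:
        s = r.summary()
        cols[r.policy] = {
            "Quality": round(s["quality"][0], 3),
            "Quantity": round(s["quantity"][0], 3),
            "Weighted sum": round(s["objective"][0], 3),
        }
    return pd.DataFrame(cols).reindex(["Quality", "Quantity", "Weighted sum"])
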