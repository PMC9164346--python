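"""Configuration schema for scenarios, predictors and policies.

Every knob the simulator exposes lives in one of the dataclasses below, so a
whole experiment is reproducible from (config, seed).  Configs load from a
plain YAML key-value file whose top-level sections mirror the dataclass
names (``scenario:``, ``predictors:``, ``mcts:``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Any

import yaml

__all__ = [
    "ScenarioConfig",
    "PredictorConfig",
    "MctsConfig",
    "SimConfig",
    "load_config",
    "make_setting",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative parameters of a synthetic shift.

    Defaults emulate the operating regime of a national emotional-first-aid
    chat service: ~7 calls/hour in a standard shift with 2 agents (heavy
    flow: 10/h, 4 agents), a 4-hour horizon, mean feedback around 4.1 on
    the 1–5 Likert scale under first-come-first-served routing, and a mean
    chat duration of ~17 minutes, placing heavy flow at offered load ~0.8
    where queues form but most callers are served.  Patience means are
    anchored to the device-specific waiting-time statistics (desktop 402 s,
    mobile 266 s) with a censoring-correction scale.
    """

    setting: str = "standard"
    horizon_s: float = 4 * 3600.0
    n_agents: int = 2
    base_rate_per_h: float = 7.0
    #: piecewise-constant intensity multipliers: sorted (start_s, multiplier)
    rate_profile: tuple[tuple[float, float], ...] = ((0.0, 1.0),)

    # caller feature distributions
    p_mobile: float = 0.6
    p_returning: float = 0.4
    age_group_probs: tuple[float, ...] = (0.10, 0.45, 0.35, 0.10)
    trait_dim: int = 2

    # patience model: exponential with device-dependent mean (seconds)
    patience_desktop_s: float = 402.0
    patience_mobile_s: float = 266.0
    patience_age_mult: tuple[float, ...] = (0.8, 1.0, 1.1, 1.3)
    #: patience means are anchored to observed mean waits, which censor
    #: patience from below (a served caller's patience exceeds their wait);
    #: the scale corrects for that censoring
    patience_scale: float = 4.0
    #: caller-level patience heterogeneity: the segment mean is scaled by
    #: exp(patience_trait_w * trait[-1]); patience varies widely between
    #: callers and the variation is predictable from pre-chat features
    patience_trait_w: float = 1.0

    # outcome-surrogate model (stands in for trained outcome predictors)
    mu_d: float = math.log(1200.0) - 0.22  # log-seconds; mean duration ~17 min
    a_dur: float = -0.05  # agent-experience effect on log-duration
    c_dur: float = 0.3  # caller trait[0] effect on log-duration
    w_d: float = -0.15  # affinity effect on log-duration: good matches resolve sooner
    mu_q: float = 1.9  # logit of baseline quality -> mean feedback ~4.1 under FCFS
    w_q: float = 1.2  # affinity effect on quality logit
    #: caller-level quality-duration coupling (0 = a caller's chat length
    #: carries no information about the feedback they will give)
    c_q: float = 0.0
    age_penalty: float = 0.8  # older-agent quality penalty (waived for 65+ callers)

    # inaccuracy-error model: realized outcome = surrogate + Normal noise
    sigma_d: float = 250.0  # seconds
    sigma_q: float = 0.4  # Likert units on the latent feedback score
    duration_floor_s: float = 60.0

    # agent roster distributions
    agent_age_mean: float = 45.0
    agent_age_sd: float = 12.0
    agent_exp_mean: float = 5.0

    def __post_init__(self) -> None:
        if self.horizon_s <= 0:
            raise ValueError("horizon_s must be > 0")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.base_rate_per_h < 0:
            raise ValueError("base_rate_per_h must be >= 0")
        if self.patience_desktop_s <= 0 or self.patience_mobile_s <= 0:
            raise ValueError("patience means must be > 0")
        if self.sigma_d < 0 or self.sigma_q < 0:
            raise ValueError("error sigmas must be >= 0")
        if abs(sum(self.age_group_probs) - 1.0) > 1e-9:
            raise ValueError("age_group_probs must sum to 1")

    @property
    def mean_patience_s(self) -> float:
        """Population mean patience, used by the naive patience predictor."""
        trait_factor = math.exp(self.patience_trait_w**2 / 2.0)  # E[exp(wZ)]
        return self.patience_scale * trait_factor * (
            self.p_mobile * self.patience_mobile_s
            + (1 - self.p_mobile) * self.patience_desktop_s
        )


@dataclass(frozen=True)
class PredictorConfig:
    """Which implementation fills each of the four predictor slots.

    ``oracle`` means the predictor returns the noiseless outcome surrogate
    (the quantity the environment perturbs with Normal error); ``naive``
    returns a population average regardless of the pair — the ablation
    substitute.
    """

    duration: str = "oracle"
    quality: str = "oracle"
    patience: str = "oracle"
    remaining: str = "oracle"
    remaining_floor_s: float = 30.0
    k_min: float = 3.0  # "ends within k minutes" classifier horizon

    def __post_init__(self) -> None:
        for slot in ("duration", "quality", "patience", "remaining"):
            v = getattr(self, slot)
            if v not in ("oracle", "naive"):
                raise ValueError(f"predictor.{slot} must be 'oracle' or 'naive'")


@dataclass(frozen=True)
class MctsConfig:
    """Monte Carlo tree search parameters (UCT with progressive widening)."""

    n_rollouts: int = 300
    uct_c: float = math.sqrt(2.0)
    max_depth: int = 200
    rollout_policy: str = "cmt"
    horizon_s: float | None = None  # None -> time remaining in the shift
    widening_k: float = 1.0
    widening_a: float = 0.5
    #: progressive widening over the (utility-ordered) action list: a node
    #: with v visits considers only the first ceil(k * v^a) actions, so small
    #: budgets concentrate on the most promising matches and the null action
    #: (ordered last) competes once the node is well visited
    action_widening_k: float = 2.0
    action_widening_a: float = 0.5
    prune_dominated: bool = True
    #: z in the lower-confidence-bound score used to pick the final root
    #: action (0 reproduces plain highest-mean selection)
    final_select_z: float = 0.0
    #: allocate root visits round-robin so every root action is evaluated on
    #: the same common-random worlds (exactly paired comparison); UCB still
    #: drives selection below the root
    root_paired: bool = True
    #: duration model for matches made inside the lookahead: "none" plans on
    #: the expected duration (certainty-equivalent; removes the one noise
    #: source common-random worlds cannot pair), "normal" samples the
    #: inaccuracy error
    plan_duration_noise: str = "none"
    #: evidence margin (objective units) the null action must beat the best
    #: match by before the policy defers: idling an agent while callers wait
    #: is the one decision whose cost compounds across re-decisions, so it
    #: needs more than a paired-noise edge
    null_margin: float = 0.002
    #: trust-region margin around the greedy (highest-utility) match: any
    #: other action must beat it by this much estimated value before the
    #: policy deviates — at small rollout budgets unguarded argmax selection
    #: suffers the optimizer's curse and deviations regress to the mean
    match_margin: float = 0.005
    #: representation of imagined future arrivals in the lookahead:
    #: "sampled" draws caller features per world (unbiased; the draws are
    #: paired across sibling actions), "mean" plugs in population averages
    plan_future_callers: str = "sampled"
    time_budget_ms: float | None = None

    def __post_init__(self) -> None:
        if self.n_rollouts < 1:
            raise ValueError("n_rollouts must be >= 1")
        if self.uct_c < 0:
            raise ValueError("uct_c must be >= 0")
        if self.rollout_policy not in ("cmt", "fcfs"):
            raise ValueError("rollout_policy must be 'cmt' or 'fcfs'")


@dataclass(frozen=True)
class SimConfig:
    """Top-level bundle: scenario + predictor wiring + MCTS parameters."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    predictors: PredictorConfig = field(default_factory=PredictorConfig)
    mcts: MctsConfig = field(default_factory=MctsConfig)


def make_setting(name: str, **overrides: Any) -> ScenarioConfig:
    """Return the scenario config for a named evaluation setting.

    ``standard``: ~7 calls/hour, 2 agents (morning staffing).
    ``heavy``: 10 calls/hour, 4 agents (evening staffing).
    Both default to a 4-hour shift with a flat intensity profile.
    """
    if name == "standard":
        base = ScenarioConfig(setting="standard", base_rate_per_h=7.0, n_agents=2)
    elif name == "heavy":
        base = ScenarioConfig(setting="heavy", base_rate_per_h=10.0, n_agents=4)
    else:
        raise ValueError(f"unknown setting {name!r}; expected 'standard' or 'heavy'")
    return replace(base, **overrides) if overrides else base


def _build(cls, section: dict[str, Any]):
    names = {f.name for f in fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {}
    for k, v in section.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        coerced[k] = v
    return cls(**coerced)


def load_config(path: str) -> SimConfig:
    """Load a SimConfig from a YAML file with scenario/predictors/mcts sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scen = dict(raw.get("scenario", {}))
    setting = scen.pop("setting", None)
    if setting in ("standard", "heavy"):
        scenario = replace(make_setting(setting), **_coerce(ScenarioConfig, scen))
    else:
        if setting is not None:
            scen["setting"] = setting
        scenario = _build(ScenarioConfig, scen)
    return SimConfig(
        scenario=scenario,
        predictors=_build(PredictorConfig, raw.get("predictors", {})),
        mcts=_build(MctsConfig, raw.get("mcts", {})),
    )


def _coerce(cls, section: dict[str, Any]) -> dict[str, Any]:
    names = {f.name for f in fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    out = {}
    for k, v in section.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        out[k] = v
    return out
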