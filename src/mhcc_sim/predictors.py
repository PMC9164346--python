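"""The four-predictor architecture behind routing decisions.

Routing consumes four estimates per decision point: pre-chat duration,
pre-chat quality, caller patience, and the remaining time of ongoing chats.
Each slot can be filled by an *oracle* implementation — the noiseless
outcome surrogate, i.e. exactly the quantity the environment perturbs with
Normal error — or by a *naive* implementation that returns a population
average for every input.  Swapping a single slot to naive reproduces one arm
of the predictor-ablation experiment.

The remaining-time model treats the realized duration D of an ongoing chat
as Normal(base_duration, sigma_d) truncated below at the elapsed time, which
yields both outputs the routing algorithm wants in closed form:

    remaining_est  = E[D | D > elapsed] - elapsed
    p_end_within_k = P(D <= elapsed + 60 k | D > elapsed)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import SimConfig
from .domain import AgentProfile, CallerProfile
from .scenario import outcome_surrogate, patience_mean

__all__ = [
    "PredictionSet",
    "ErrorModel",
    "PredictorBundle",
    "truncated_normal_remaining",
    "fit_error_model",
]


@dataclass(frozen=True)
class PredictionSet:
    """Pre-chat estimates for one (caller, agent) pairing."""

    duration_est: float
    quality_est: float
    patience_mean_est: float

    def __post_init__(self) -> None:
        if self.duration_est <= 0:
            raise ValueError("duration_est must be > 0")
        if not 0.0 <= self.quality_est <= 1.0:
            raise ValueError("quality_est must lie in [0, 1]")
        if self.patience_mean_est <= 0:
            raise ValueError("patience_mean_est must be > 0")


@dataclass(frozen=True)
class ErrorModel:
    """Normal inaccuracy-error distribution fitted from prediction residuals."""

    mu: float
    sigma: float
    normality_p: float
    nonnormal_warning: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def fit_error_model(residuals) -> ErrorModel:
    """Fit the Normal error model used to perturb predictions.

    ``mu`` and ``sigma`` are the sample mean and (ddof=1) standard deviation;
    normality is checked with the Shapiro-Wilk test and flagged when
    p < 0.05.  All-identical residuals give sigma 0 with a degenerate flag
    (the normality test is undefined there).
    """
    x = np.asarray(list(residuals), dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 residuals to fit an error model")
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=1))
    if sigma == 0.0:
        return ErrorModel(mu=mu, sigma=0.0, normality_p=0.0, degenerate=True)
    p = float(stats.shapiro(x).pvalue)
    return ErrorModel(mu=mu, sigma=sigma, normality_p=p, nonnormal_warning=p < 0.05)


def truncated_normal_remaining(
    base_duration: float,
    sigma: float,
    elapsed: float,
    k_min: float,
    floor: float,
) -> tuple[float, float]:
    """Closed-form remaining time and end-within-k probability.

    D ~ Normal(base_duration, sigma) conditioned on D > elapsed.  The
    sigma = 0 limit treats D as the point mass at base_duration; an overdue
    chat (base_duration <= elapsed) then reports the floor and certainty of
    ending within any positive k.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if elapsed < 0:
        raise ValueError("elapsed must be >= 0")
    horizon = elapsed + 60.0 * k_min
    if sigma == 0.0:
        if base_duration <= elapsed:
            return floor, 1.0
        return max(floor, base_duration - elapsed), 1.0 if base_duration <= horizon else 0.0
    a = (elapsed - base_duration) / sigma
    sf_a = stats.norm.sf(a)
    if sf_a <= 1e-300:
        # deep in the upper tail: Mills-ratio asymptotics, chat is overdue
        return floor, 1.0
    # E[D | D > elapsed] = mu + sigma * phi(a) / sf(a)
    cond_mean = base_duration + sigma * stats.norm.pdf(a) / sf_a
    remaining = max(floor, cond_mean - elapsed)
    b = (horizon - base_duration) / sigma
    p_end = float(np.clip((stats.norm.sf(a) - stats.norm.sf(b)) / sf_a, 0.0, 1.0))
    return float(remaining), p_end


class PredictorBundle:
    """The four predictor slots, each wired to oracle or naive per config.

    Oracle predictors are pure functions of observable features plus the
    scenario's generative parameters; they never see realized (noisy)
    outcomes or realized patience draws.
    """

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        scen = cfg.scenario
        pc = cfg.predictors
        self._oracle_duration = pc.duration == "oracle"
        self._oracle_quality = pc.quality == "oracle"
        self._oracle_patience = pc.patience == "oracle"
        self._oracle_remaining = pc.remaining == "oracle"
        # population averages the naive variants return for every input
        self.naive_duration_s = math.exp(scen.mu_d)
        self.naive_quality = 1.0 / (1.0 + math.exp(-scen.mu_q))
        self.naive_patience_s = scen.mean_patience_s
        self.sigma_d = scen.sigma_d
        self.remaining_floor_s = pc.remaining_floor_s
        self.k_min = pc.k_min

    # -- pre-chat models -------------------------------------------------
    def predict_pre_chat(
        self, caller: CallerProfile, agent: AgentProfile
    ) -> tuple[float, float]:
        """(duration_est seconds, quality_est in [0,1]) for a potential match."""
        if self._oracle_duration or self._oracle_quality:
            s = outcome_surrogate(caller, agent, self.cfg.scenario)
            d = s.base_duration if self._oracle_duration else self.naive_duration_s
            q = s.base_quality if self._oracle_quality else self.naive_quality
        else:
            d, q = self.naive_duration_s, self.naive_quality
        return d, q

    def predict_patience(self, caller: CallerProfile) -> float:
        """Estimated mean patience (seconds); never the realized draw."""
        if self._oracle_patience:
            return patience_mean(caller, self.cfg.scenario)
        return self.naive_patience_s

    def prediction_set(self, caller: CallerProfile, agent: AgentProfile) -> PredictionSet:
        d, q = self.predict_pre_chat(caller, agent)
        return PredictionSet(d, q, self.predict_patience(caller))

    # -- mid-chat model --------------------------------------------------
    def remaining_base_duration(self, caller: CallerProfile, agent: AgentProfile) -> float:
        """The duration mean the remaining-time model conditions on."""
        if self._oracle_remaining:
            return outcome_surrogate(caller, agent, self.cfg.scenario).base_duration
        return self.naive_duration_s

    def predict_remaining(
        self, caller: CallerProfile, agent: AgentProfile, elapsed: float
    ) -> tuple[float, float]:
        """(remaining_est seconds, P(chat ends within k minutes)) mid-chat."""
        base = self.remaining_base_duration(caller, agent)
        return truncated_normal_remaining(
            base, self.sigma_d, elapsed, self.k_min, self.remaining_floor_s
        )
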