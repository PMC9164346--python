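"""Core domain types and shift-level outcome metrics.

A mental-health contact center (MHCC) shift is judged on two axes:

* **Quantity** — the fraction of callers who arrived during the shift and
  were actually served (the complement of the abandonment rate).
* **Quality** — the mean post-chat satisfaction of the served callers,
  reported on a 1–5 Likert scale and rescaled to [0, 1].

The routing objective is the equally weighted mean of the two, so a policy
cannot buy throughput with uniformly bad conversations or vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "CallerProfile",
    "AgentProfile",
    "ChatOutcome",
    "ShiftMetrics",
    "normalize_feedback",
    "compute_quantity",
    "compute_quality",
    "weighted_objective",
    "AGE_GROUPS",
]

#: Ordinal age bands collected by the pre-chat survey.
AGE_GROUPS = ("<18", "18-35", "36-65", "65+")


@dataclass(frozen=True)
class AgentProfile:
    """A counselling agent on the shift roster.

    ``style`` is a latent vector in the same space as the caller ``trait``;
    their inner product drives how well a particular pairing tends to go.
    """

    agent_id: str
    age: float
    gender: str
    experience_years: float
    style: tuple[float, ...]
    hist_avg_feedback: float
    hist_avg_duration: float

    def __post_init__(self) -> None:
        if self.experience_years < 0:
            raise ValueError("experience_years must be >= 0")
        if not 1.0 <= self.hist_avg_feedback <= 5.0:
            raise ValueError("hist_avg_feedback must lie in [1, 5]")
        if self.hist_avg_duration <= 0:
            raise ValueError("hist_avg_duration must be > 0")


@dataclass
class CallerProfile:
    """One incoming call and the person behind it.

    ``true_patience`` (seconds the caller will wait before abandoning) and
    ``true_outcomes`` (the realized chat each agent *would* have produced)
    are hidden ground truth: the simulation engine uses them, routing
    policies only ever see the observable projection of the state.
    """

    caller_id: str
    arrival_time: float
    age_group: str
    device: str  # "mobile" | "desktop"
    is_returning: bool
    trait: tuple[float, ...]
    true_patience: float
    true_outcomes: dict[str, "ChatOutcome"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arrival_time < 0:
            raise ValueError("arrival_time must be >= 0")
        if self.true_patience <= 0:
            raise ValueError("true_patience must be > 0")
        if self.device not in ("mobile", "desktop"):
            raise ValueError(f"unknown device {self.device!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age_group {self.age_group!r}")


@dataclass(frozen=True)
class ChatOutcome:
    """Realized result of one caller-agent conversation."""

    duration: float
    feedback: int
    quality: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        expected = normalize_feedback(self.feedback)
        if abs(self.quality - expected) > 1e-12:
            raise ValueError("quality must equal (feedback - 1) / 4")


@dataclass(frozen=True)
class ShiftMetrics:
    """Aggregate outcome of one simulated shift.

    ``quality_defined`` is False when no call was served (Quality is then
    reported as the neutral 0.0 but flagged so batch summaries can exclude
    the shift from Quality averages).
    """

    n_arrived: int
    n_served: int
    n_abandoned: int
    n_waiting_at_end: int
    quantity: float
    quality: float
    objective: float
    quality_defined: bool = True

    def __post_init__(self) -> None:
        if self.n_served + self.n_abandoned + self.n_waiting_at_end != self.n_arrived:
            raise ValueError(
                "conservation violated: served + abandoned + waiting != arrived"
            )


def normalize_feedback(feedback: int) -> float:
    """Map a 1–5 Likert feedback score onto the unit interval.

    5 -> 1.0, 1 -> 0.0, linear in between.
    """
    if not isinstance(feedback, (int,)) or isinstance(feedback, bool):
        raise ValueError("feedback must be an integer")
    if not 1 <= feedback <= 5:
        raise ValueError(f"feedback must be in [1, 5], got {feedback}")
    return (feedback - 1) / 4


def compute_quantity(n_served: int, n_arrived: int) -> float:
    """Fraction of arrived calls that were served.

    An empty shift (no arrivals) counts as a perfect 1.0 by convention:
    nothing was lost.
    """
    if n_served < 0 or n_arrived < 0:
        raise ValueError("counts must be non-negative")
    if n_served > n_arrived:
        raise ValueError("n_served cannot exceed n_arrived")
    if n_arrived == 0:
        return 1.0
    return n_served / n_arrived


def compute_quality(served_qualities: Sequence[float]) -> tuple[float, bool]:
    """Mean normalized feedback over served calls.

    Returns ``(mean, defined)``; for an empty list the mean is the neutral
    0.0 and ``defined`` is False.  Abandoned callers do not enter Quality:
    they are penalized through Quantity instead, because only served calls
    produce post-chat feedback.
    """
    for q in served_qualities:
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"quality value {q} outside [0, 1]")
    if len(served_qualities) == 0:
        return 0.0, False
    return float(sum(served_qualities) / len(served_qualities)), True


def weighted_objective(quantity: float, quality: float) -> float:
    """Equally weighted mean of Quantity and Quality, the routing objective."""
    if not 0.0 <= quantity <= 1.0:
        raise ValueError(f"quantity {quantity} outside [0, 1]")
    if not 0.0 <= quality <= 1.0:
        raise ValueError(f"quality {quality} outside [0, 1]")
    return 0.5 * quantity + 0.5 * quality


def make_shift_metrics(
    n_arrived: int,
    n_served: int,
    n_abandoned: int,
    n_waiting_at_end: int,
    served_qualities: Sequence[float],
) -> ShiftMetrics:
    """Assemble ShiftMetrics from raw tallies, applying the metric conventions."""
    quantity = compute_quantity(n_served, n_arrived)
    quality, defined = compute_quality(served_qualities)
    return ShiftMetrics(
        n_arrived=n_arrived,
        n_served=n_served,
        n_abandoned=n_abandoned,
        n_waiting_at_end=n_waiting_at_end,
        quantity=quantity,
        quality=quality,
        objective=weighted_objective(quantity, quality),
        quality_defined=defined,
    )
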