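"""Generative rules of the advance-bid Balloon Analogue Risk Task (BART).

On each trial the player sees a per-pump point value (uniform on 1..100),
commits in advance to a number of pumps (1..12), and a hidden safe limit
(discrete uniform on the 13 integers 0..12) decides the outcome: pumping
strictly beyond the limit bursts the balloon and yields zero points,
otherwise the player banks ``n_pumps * pump_value``.  After the outcome the
player may pay a cost -- nothing, points, physical effort (a Bernoulli
success gate standing in for a key-press threshold), or waiting time,
depending on the experiment variant -- to see the limit, i.e. to learn how
much they could have won (the "missed opportunity").

Because the limit is discrete uniform with strict exceedance, the task has
closed-form properties: ``P(bank | n) = (13 - n) / 13``, expected banked
pumps ``n (13 - n) / 13``, and a tied optimum at 6 or 7 pumps.  A limit
drawn from a *continuous* uniform would instead give a unique optimum at
6 and a different bank rate, which is why the discrete form is used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple

import numpy as np

__all__ = [
    "Outcome",
    "CostType",
    "TrialRecord",
    "ExperimentConfig",
    "CostResult",
    "N_LIMITS",
    "PUMP_MIN",
    "PUMP_MAX",
    "LIMIT_MIN",
    "LIMIT_MAX",
    "VALUE_MIN",
    "VALUE_MAX",
    "draw_trial_params",
    "resolve_trial",
    "bank_probability",
    "expected_points",
    "optimal_pumps",
    "missed_opportunity",
    "apply_cost",
]

PUMP_MIN, PUMP_MAX = 1, 12
LIMIT_MIN, LIMIT_MAX = 0, 12
N_LIMITS = LIMIT_MAX - LIMIT_MIN + 1  # 13 equiprobable safe limits
VALUE_MIN, VALUE_MAX = 1, 100
RATING_MIN, RATING_MAX = -200.0, 200.0


class Outcome(str, Enum):
    BANK = "bank"
    BUST = "bust"


class CostType(str, Enum):
    NONE = "none"
    MONEY = "money"
    EFFORT = "effort"
    TIME = "time"


@dataclass
class TrialRecord:
    """One BART trial: choices, resolution, ratings, information seeking.

    ``outcome_rating`` and ``emotion_change`` live on the task's visual
    analogue scale, -200..200.  ``info_received`` can be false while
    ``info_sought`` is true only on effort-cost "try harder" trials.
    """

    participant_id: str
    experiment_id: str
    trial_index: int
    pump_value: int
    n_pumps: int
    limit: int
    outcome: Outcome
    points: int
    info_sought: bool
    info_received: bool
    outcome_rating: float
    emotion_change: float
    is_practice: bool = False
    try_harder: bool = False
    cost_type: CostType = CostType.NONE
    time_penalty_s: float = 0.0

    def __post_init__(self) -> None:
        self.outcome = Outcome(self.outcome)
        self.cost_type = CostType(self.cost_type)
        if not (VALUE_MIN <= self.pump_value <= VALUE_MAX):
            raise ValueError(f"pump_value {self.pump_value} outside {VALUE_MIN}..{VALUE_MAX}")
        if not (PUMP_MIN <= self.n_pumps <= PUMP_MAX):
            raise ValueError(f"n_pumps {self.n_pumps} outside {PUMP_MIN}..{PUMP_MAX}")
        if not (LIMIT_MIN <= self.limit <= LIMIT_MAX):
            raise ValueError(f"limit {self.limit} outside {LIMIT_MIN}..{LIMIT_MAX}")
        if self.trial_index < 1:
            raise ValueError("trial_index is 1-based")
        expected_outcome = Outcome.BUST if self.n_pumps > self.limit else Outcome.BANK
        if self.outcome is not expected_outcome:
            raise ValueError("outcome inconsistent with n_pumps vs limit")
        expected_points = self.n_pumps * self.pump_value if self.outcome is Outcome.BANK else 0
        if self.points != expected_points:
            raise ValueError("points inconsistent with the banking rule")
        if self.info_received and not self.info_sought:
            raise ValueError("info_received implies info_sought")
        for name in ("outcome_rating", "emotion_change"):
            v = getattr(self, name)
            if not (RATING_MIN <= v <= RATING_MAX):
                raise ValueError(f"{name} {v} outside the -200..200 scale")


@dataclass
class ExperimentConfig:
    """Cost manipulation and cohort shape for one experiment variant.

    The five multi-trial variants are: free information, 5-point money
    cost, physical effort with ~0.88 / ~0.92 success probability, and a
    5 s time cost.  ``one_shot`` selects the replication design: 10
    practice trials without an information option, then a single critical
    trial at a fixed 20-per-pump value with a 30 s time cost.
    """

    experiment_id: str = "exp"
    cost_type: CostType = CostType.NONE
    cost_amount: float = 0.0  # points (money) or seconds (time)
    effort_success_prob: float = 1.0
    bonus: bool = False
    n_participants: int = 30
    n_trials: int = 60
    n_practice: int = 2
    one_shot: bool = False
    pump_value_fixed: int | None = None  # one-shot: 20 (pence per pump)
    currency: str | None = None

    def __post_init__(self) -> None:
        self.cost_type = CostType(self.cost_type)
        if not (0.0 <= self.effort_success_prob <= 1.0):
            raise ValueError("effort_success_prob must be a probability")
        if self.n_participants < 1 or self.n_trials < 1:
            raise ValueError("cohort sizes must be positive")
        if self.one_shot and self.n_trials != 1:
            raise ValueError("one_shot designs have exactly 1 critical trial")


class CostResult(NamedTuple):
    info_received: bool
    cumulative_points: float
    time_penalty_s: float


def draw_trial_params(rng: np.random.Generator) -> tuple[int, int]:
    """Draw (pump_value, limit) for one trial.

    pump_value is uniform on 1..100; the safe limit is uniform on the 13
    integers 0..12 (limit 0: any pump bursts; limit 12: no pump count can).
    """
    pump_value = int(rng.integers(VALUE_MIN, VALUE_MAX + 1))
    limit = int(rng.integers(LIMIT_MIN, LIMIT_MAX + 1))
    return pump_value, limit


def resolve_trial(n_pumps: int, limit: int, pump_value: int) -> tuple[Outcome, int]:
    """Resolve one trial: bust iff pumps strictly exceed the limit."""
    if not (PUMP_MIN <= n_pumps <= PUMP_MAX):
        raise ValueError(f"n_pumps {n_pumps} outside {PUMP_MIN}..{PUMP_MAX}")
    if not (LIMIT_MIN <= limit <= LIMIT_MAX):
        raise ValueError(f"limit {limit} outside {LIMIT_MIN}..{LIMIT_MAX}")
    if not (VALUE_MIN <= pump_value <= VALUE_MAX):
        raise ValueError(f"pump_value {pump_value} outside {VALUE_MIN}..{VALUE_MAX}")
    if n_pumps > limit:
        return Outcome.BUST, 0
    return Outcome.BANK, n_pumps * pump_value


def bank_probability(n_pumps: int) -> float:
    """P(bank | n pumps) = (13 - n) / 13 under the discrete-uniform limit."""
    if not (PUMP_MIN <= n_pumps <= PUMP_MAX):
        raise ValueError(f"n_pumps {n_pumps} outside {PUMP_MIN}..{PUMP_MAX}")
    return (N_LIMITS - n_pumps) / N_LIMITS


def expected_points(n_pumps: int) -> float:
    """Expected banked pumps (value-normalized): n (13 - n) / 13."""
    return n_pumps * bank_probability(n_pumps)


def optimal_pumps() -> set[int]:
    """Maximizer set of expected points, by exhaustive search over 1..12."""
    values = {n: expected_points(n) for n in range(PUMP_MIN, PUMP_MAX + 1)}
    best = max(values.values())
    return {n for n, v in values.items() if v == best}


def missed_opportunity(limit: int, n_pumps: int) -> int:
    """limit - n_pumps: how much further the balloon could have been pumped.

    Non-negative on bank trials (0 is the "just right" case); negative on
    bust trials, where small magnitudes are near misses.
    """
    if not (PUMP_MIN <= n_pumps <= PUMP_MAX):
        raise ValueError(f"n_pumps {n_pumps} outside {PUMP_MIN}..{PUMP_MAX}")
    if not (LIMIT_MIN <= limit <= LIMIT_MAX):
        raise ValueError(f"limit {limit} outside {LIMIT_MIN}..{LIMIT_MAX}")
    return limit - n_pumps


def apply_cost(
    config: ExperimentConfig,
    cumulative_points: float,
    rng: np.random.Generator,
) -> CostResult:
    """Apply the experiment's information cost after the player sought info.

    money: the fee (5 points in the money-cost variant) is deducted from the
    cumulative banked score; a negative balance is permitted.  effort: the
    information is delivered with probability ``effort_success_prob`` ("try
    harder" otherwise).  time: a waiting penalty in seconds is recorded as
    metadata; points are untouched.  none: identity.
    """
    if config.cost_type is CostType.MONEY:
        return CostResult(True, cumulative_points - config.cost_amount, 0.0)
    if config.cost_type is CostType.EFFORT:
        received = bool(rng.random() < config.effort_success_prob)
        return CostResult(received, cumulative_points, 0.0)
    if config.cost_type is CostType.TIME:
        return CostResult(True, cumulative_points, float(config.cost_amount))
    return CostResult(True, cumulative_points, 0.0)


def config_to_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cost_type"] = config.cost_type.value
    return d
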