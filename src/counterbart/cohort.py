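"""Synthetic participant cohorts with plantable effects for the full pipeline.

The generator mirrors, in generative direction, the statistical structure
the analysis stages assume: participants carry a pump policy (a clamped
discrete-Gaussian bid around a participant mean), seek limit information
with a participant-specific logit around a per-condition base rate, and
produce emotion-change ratings from a linear model in the same covariates
the analysis codes -- effect-coded information seeking, standardized pump
value, centered missed opportunity -- plus uncorrelated participant random
effects and residual noise.  The felt emotion then feeds back on the next
trial's bid (feel worse -> pump more) through an adjustment coefficient,
closing the loop the path model estimates.

Planting a coefficient means the fitting pipeline should recover it:
fixed effects are applied to population-centered covariates (pump value
standardized by its known uniform(1..100) moments; missed opportunity
centered at the participant-level constant (12 - policy_mean)/2), which
differ from the analysis's empirical within-participant centering only by
participant-level constants -- terms the random intercept and slopes
absorb, so planted slopes come back without bias.  The residual SD is
auto-calibrated so the analyzed-row outcome variance is ~1, keeping
planted values on the standardized-outcome scale the analyses report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import task
from .task import CostType, ExperimentConfig, Outcome

__all__ = [
    "GeneratorSpec",
    "default_study_configs",
    "generate_experiment",
    "generate_study",
    "generate_replication",
]

#: moments of the discrete uniform pump value on 1..100
_PV_MEAN = 50.5
_PV_SD = float(np.sqrt((100.0**2 - 1.0) / 12.0))

#: visual-analogue-scale points per standardized emotion unit
RATING_SCALE = 60.0


@dataclass
class GeneratorSpec:
    """Population parameters of the synthetic data-generating process.

    Defaults are calibrated to the integrated descriptives of the original
    five-experiment study (mean bid 4.97, bank rate ~.62, per-condition
    seek rates .67/.18/.56/.46/.44) and plant the Step-2 trial-level model
    coefficients on the standardized emotion-change scale.  ``gamma_adjust``
    is the emotion -> next-bid feedback in pumps per SD of emotion change.
    """

    # information seeking
    seek_rates: tuple[float, ...] = (0.67, 0.18, 0.56, 0.46, 0.44)
    seek_logit_sd: float = 1.0
    seek_rate_one_shot: float = 0.71
    # pump policy (pumps)
    pump_mean: float = 4.97
    pump_between_sd: float = 1.26  # SE x sqrt(N) from the integrated descriptives
    pump_within_sd: float = 1.5
    # fixed effects (standardized emotion-change units)
    beta_is: float = -0.173
    beta_pv: float = 0.0
    beta_mo: float = -0.163
    beta_is_pv: float = -0.125
    beta_is_mo: float = -0.144
    # random-effect SDs (intercept + one per slope, mutually uncorrelated)
    re_sd: float = 0.1
    # residual SD; None -> auto-calibrated for unit analyzed-row variance
    residual_sd: float | None = None
    # emotion -> next-trial bid feedback (pumps per SD) and extra bid noise
    gamma_adjust: float = -0.089
    adjust_noise_sd: float = 0.0
    # cohort shape defaults
    n_participants: int = 30
    n_trials: int = 60

    def validate(self) -> None:
        for p in (*self.seek_rates, self.seek_rate_one_shot):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"seek rate {p} is not a probability")
        for name in ("seek_logit_sd", "pump_between_sd", "pump_within_sd", "re_sd", "adjust_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.residual_sd is not None and self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if self.n_participants < 1 or self.n_trials < 1:
            raise ValueError("cohort sizes must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_study_configs(spec: GeneratorSpec | None = None) -> list[ExperimentConfig]:
    """The five cost variants of the multi-trial study.

    Free information; 5-point money cost; physical effort at success
    probabilities 0.88 and 0.92 (the complements of the observed 12% / 8%
    try-harder rates); 5 s time cost.  Bonus flags follow the recruitment
    design of each variant.
    """
    spec = spec or GeneratorSpec()
    common = dict(n_participants=spec.n_participants, n_trials=spec.n_trials, n_practice=2)
    return [
        ExperimentConfig("exp1", CostType.NONE, 0.0, 1.0, bonus=False, **common),
        ExperimentConfig("exp2", CostType.MONEY, 5.0, 1.0, bonus=True, **common),
        ExperimentConfig("exp3", CostType.EFFORT, 0.0, 0.88, bonus=False, **common),
        ExperimentConfig("exp4", CostType.EFFORT, 0.0, 0.92, bonus=True, **common),
        ExperimentConfig("exp5", CostType.TIME, 5.0, 1.0, bonus=True, **common),
    ]


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1.0 - 1e-9)
    return float(np.log(p / (1.0 - p)))


def _clamp_bid(x: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(x), task.PUMP_MIN, task.PUMP_MAX).astype(np.int64)


def _seek_rate_for(spec: GeneratorSpec, config: ExperimentConfig) -> float:
    """Seek base rate for a config: positional match into the default five."""
    if config.one_shot:
        return spec.seek_rate_one_shot
    for i, c in enumerate(default_study_configs(spec)):
        if c.experiment_id == config.experiment_id and i < len(spec.seek_rates):
            return spec.seek_rates[i]
    return spec.seek_rates[min(len(spec.seek_rates) - 1, 0)] if spec.seek_rates else 0.5


def _systematic_emotion(
    spec: GeneratorSpec,
    s: np.ndarray,
    pv_c: np.ndarray,
    mo_c: np.ndarray,
    re: dict[str, np.ndarray],
) -> np.ndarray:
    """Fixed-effect + random-effect part of the emotion-change model."""
    return (
        spec.beta_is * s
        + spec.beta_pv * pv_c
        + spec.beta_mo * mo_c
        + spec.beta_is_pv * s * pv_c
        + spec.beta_is_mo * s * mo_c
        + re["intercept"]
        + re["is"] * s
        + re["pv"] * pv_c
        + re["mo"] * mo_c
        + re["is_pv"] * s * pv_c
        + re["is_mo"] * s * mo_c
    )


def _draw_random_effects(spec: GeneratorSpec, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    names = ("intercept", "is", "pv", "mo", "is_pv", "is_mo")
    return {k: rng.normal(0.0, spec.re_sd, size=n) for k in names}


def _calibrate_residual_sd(
    spec: GeneratorSpec,
    config: ExperimentConfig,
    seed: int,
    n_participants: int = 2000,
) -> float:
    """Residual SD making analyzed-row emotion variance ~1.

    A short feedback-free Monte Carlo of the experiment's covariate
    structure (bank, non-try-harder rows) measures the systematic variance;
    the residual makes up the difference to 1 (floored at 0.2).
    """
    rng = np.random.default_rng(seed)
    n_p, n_t = n_participants, config.n_trials
    policy_mean = rng.normal(spec.pump_mean, spec.pump_between_sd, size=n_p)
    seek_logit = _logit(_seek_rate_for(spec, config)) + rng.normal(0.0, spec.seek_logit_sd, size=n_p)
    seek_p = 1.0 / (1.0 + np.exp(-seek_logit))
    re = _draw_random_effects(spec, n_p, rng)
    bids = _clamp_bid(rng.normal(policy_mean[:, None], spec.pump_within_sd, size=(n_p, n_t)))
    limits = rng.integers(task.LIMIT_MIN, task.LIMIT_MAX + 1, size=(n_p, n_t))
    bank = bids <= limits
    sought = rng.random(size=(n_p, n_t)) < seek_p[:, None]
    received = sought.copy()
    if config.cost_type is CostType.EFFORT:
        received &= rng.random(size=(n_p, n_t)) < config.effort_success_prob
    keep = bank & ~(sought & ~received)
    s = np.where(received, 1.0, -1.0)
    pv = rng.integers(task.VALUE_MIN, task.VALUE_MAX + 1, size=(n_p, n_t))
    pv_c = (pv - _PV_MEAN) / _PV_SD
    mo_c = (limits - bids) - (task.LIMIT_MAX - policy_mean[:, None]) / 2.0
    sys = _systematic_emotion(
        spec, s, pv_c, mo_c, {k: v[:, None] for k, v in re.items()}
    )
    var_sys = float(np.var(sys[keep]))
    return float(np.sqrt(max(1.0 - var_sys, 0.04)))


def generate_experiment(
    spec: GeneratorSpec,
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate one experiment's tidy trial table.

    Trials are generated sequentially per cohort so the previous trial's
    felt emotion can shift the next bid by ``gamma_adjust`` pumps per SD.
    Practice trials are produced (flagged, no information option) and
    excluded downstream.
    """
    spec.validate()
    if config.one_shot:
        raise ValueError("use generate_replication for one-shot designs")
    resid_sd = spec.residual_sd
    if resid_sd is None:
        resid_sd = _calibrate_residual_sd(spec, config, seed=int(rng.integers(2**31)))
    n_p = config.n_participants
    policy_mean = rng.normal(spec.pump_mean, spec.pump_between_sd, size=n_p)
    seek_logit = _logit(_seek_rate_for(spec, config)) + rng.normal(0.0, spec.seek_logit_sd, size=n_p)
    seek_p = 1.0 / (1.0 + np.exp(-seek_logit))
    re = _draw_random_effects(spec, n_p, rng)
    mo_center = (task.LIMIT_MAX - policy_mean) / 2.0

    participant_ids = np.array([f"{config.experiment_id}_p{i + 1:03d}" for i in range(n_p)])
    n_total = config.n_practice + config.n_trials
    rows: list[dict] = []
    prev_emotion = np.zeros(n_p)  # standardized units, 0 before the first trial
    cumulative = np.zeros(n_p)
    for t in range(1, n_total + 1):
        practice = t <= config.n_practice
        base = rng.normal(policy_mean, spec.pump_within_sd, size=n_p)
        shift = spec.gamma_adjust * prev_emotion
        if spec.adjust_noise_sd > 0:
            shift = shift + rng.normal(0.0, spec.adjust_noise_sd, size=n_p)
        bids = _clamp_bid(base + shift)
        pv = rng.integers(task.VALUE_MIN, task.VALUE_MAX + 1, size=n_p)
        limits = rng.integers(task.LIMIT_MIN, task.LIMIT_MAX + 1, size=n_p)
        bank = bids <= limits
        points = np.where(bank, bids * pv, 0)
        cumulative = cumulative + points
        if practice:
            sought = np.zeros(n_p, dtype=bool)
        else:
            sought = rng.random(n_p) < seek_p
        received = sought.copy()
        time_pen = np.zeros(n_p)
        if config.cost_type is CostType.MONEY:
            cumulative = cumulative - np.where(sought, config.cost_amount, 0.0)
        elif config.cost_type is CostType.EFFORT:
            received &= rng.random(n_p) < config.effort_success_prob
        elif config.cost_type is CostType.TIME:
            time_pen = np.where(sought, config.cost_amount, 0.0)
        try_harder = sought & ~received

        s = np.where(received, 1.0, -1.0)
        pv_c = (pv - _PV_MEAN) / _PV_SD
        mo_c = (limits - bids) - mo_center
        emotion = _systematic_emotion(spec, s, pv_c, mo_c, re) + rng.normal(0.0, resid_sd, size=n_p)
        prev_emotion = emotion

        # cosmetic ratings on the -200..200 visual analogue scale
        outcome_rating = np.clip(
            np.where(bank, points / 6.0 - 40.0, -80.0) + rng.normal(0.0, 40.0, size=n_p),
            -200.0,
            200.0,
        )
        emotion_rating = np.clip(emotion * RATING_SCALE, -200.0, 200.0)
        for i in range(n_p):
            rows.append(
                {
                    "participant_id": participant_ids[i],
                    "experiment_id": config.experiment_id,
                    "trial_index": t,
                    "is_practice": bool(practice),
                    "pump_value": int(pv[i]),
                    "n_pumps": int(bids[i]),
                    "limit": int(limits[i]),
                    "outcome": Outcome.BANK.value if bank[i] else Outcome.BUST.value,
                    "points": int(points[i]),
                    "info_sought": bool(sought[i]),
                    "info_received": bool(received[i]),
                    "try_harder": bool(try_harder[i]),
                    "outcome_rating": float(outcome_rating[i]),
                    "emotion_change": float(emotion_rating[i]),
                    "cost_type": config.cost_type.value,
                    "cost_amount": float(config.cost_amount),
                    "time_penalty_s": float(time_pen[i]),
                }
            )
    return pd.DataFrame(rows)


def generate_study(
    spec: GeneratorSpec,
    configs: list[ExperimentConfig] | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Generate the five-experiment study; returns (tables, manifest).

    The manifest records the generator spec, its hash, and the child seed
    used for each experiment so any single table can be regenerated.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    configs = configs or default_study_configs(spec)
    tables: dict[str, pd.DataFrame] = {}
    manifest: dict = {
        "spec": spec.to_dict(),
        "spec_hash": spec.content_hash(),
        "experiments": {},
    }
    for config in configs:
        child_seed = int(rng.integers(2**31))
        tables[config.experiment_id] = generate_experiment(
            spec, config, np.random.default_rng(child_seed)
        )
        manifest["experiments"][config.experiment_id] = {
            "seed": child_seed,
            "config": task.config_to_dict(config),
        }
    return tables, manifest


def generate_replication(
    spec: GeneratorSpec,
    n: int = 361,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """One-shot replication cohort: 10 practice trials, 1 critical trial.

    The critical trial's pump value is fixed at 20 (pence per pump).  Only
    participants who bank are offered the information, at a 30 s time cost;
    their emotion is rated before and after the information window and the
    change score carries the planted seek and missed-opportunity effects.
    """
    spec.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    config = ExperimentConfig(
        "replication",
        CostType.TIME,
        cost_amount=30.0,
        n_participants=n,
        n_trials=1,
        n_practice=10,
        one_shot=True,
        pump_value_fixed=20,
        currency="GBP_pence",
    )
    policy_mean = rng.normal(spec.pump_mean, spec.pump_between_sd, size=n)
    rows: list[dict] = []
    pids = [f"rep_p{i + 1:04d}" for i in range(n)]
    # practice block: free-standing BART trials, no information option
    for t in range(1, config.n_practice + 1):
        bids = _clamp_bid(rng.normal(policy_mean, spec.pump_within_sd))
        pv = rng.integers(task.VALUE_MIN, task.VALUE_MAX + 1, size=n)
        limits = rng.integers(task.LIMIT_MIN, task.LIMIT_MAX + 1, size=n)
        bank = bids <= limits
        points = np.where(bank, bids * pv, 0)
        outcome_rating = np.clip(
            np.where(bank, points / 6.0 - 40.0, -80.0) + rng.normal(0.0, 40.0, size=n), -200, 200
        )
        for i in range(n):
            rows.append(
                {
                    "participant_id": pids[i],
                    "experiment_id": config.experiment_id,
                    "trial_index": t,
                    "is_practice": True,
                    "pump_value": int(pv[i]),
                    "n_pumps": int(bids[i]),
                    "limit": int(limits[i]),
                    "outcome": Outcome.BANK.value if bank[i] else Outcome.BUST.value,
                    "points": int(points[i]),
                    "info_sought": False,
                    "info_received": False,
                    "try_harder": False,
                    "outcome_rating": float(outcome_rating[i]),
                    "emotion_change": 0.0,
                    "cost_type": config.cost_type.value,
                    "cost_amount": float(config.cost_amount),
                    "time_penalty_s": 0.0,
                }
            )
    # critical trial
    bids = _clamp_bid(rng.normal(policy_mean, spec.pump_within_sd))
    pv_fixed = int(config.pump_value_fixed)
    limits = rng.integers(task.LIMIT_MIN, task.LIMIT_MAX + 1, size=n)
    bank = bids <= limits
    points = np.where(bank, bids * pv_fixed, 0)
    sought = bank & (rng.random(n) < spec.seek_rate_one_shot)
    mo = limits - bids
    mo_center = (task.LIMIT_MAX - spec.pump_mean) / 2.0
    s = np.where(sought, 1.0, -1.0)
    sys = spec.beta_is * s + spec.beta_mo * (mo - mo_center) + spec.beta_is_mo * s * (mo - mo_center)
    resid_sd = spec.residual_sd
    if resid_sd is None:
        var_sys = float(np.var(sys[bank])) if bank.any() else 0.0
        resid_sd = float(np.sqrt(max(1.0 - var_sys, 0.04)))
    emotion = np.where(bank, sys + rng.normal(0.0, resid_sd, size=n), rng.normal(0.0, 1.0, size=n))
    outcome_rating = np.clip(
        np.where(bank, points / 1.5 - 40.0, -80.0) + rng.normal(0.0, 40.0, size=n), -200, 200
    )
    emotion_rating = np.clip(emotion * RATING_SCALE, -200.0, 200.0)
    for i in range(n):
        rows.append(
            {
                "participant_id": pids[i],
                "experiment_id": config.experiment_id,
                "trial_index": config.n_practice + 1,
                "is_practice": False,
                "pump_value": pv_fixed,
                "n_pumps": int(bids[i]),
                "limit": int(limits[i]),
                "outcome": Outcome.BANK.value if bank[i] else Outcome.BUST.value,
                "points": int(points[i]),
                "info_sought": bool(sought[i]),
                "info_received": bool(sought[i]),
                "try_harder": False,
                "outcome_rating": float(outcome_rating[i]),
                "emotion_change": float(emotion_rating[i]),
                "cost_type": config.cost_type.value,
                "cost_amount": float(config.cost_amount),
                "time_penalty_s": float(config.cost_amount if sought[i] else 0.0),
            }
        )
    return pd.DataFrame(rows)
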