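"""Interactive landslide microworld.

A participant (human or model) repeatedly decides what fraction of their
per-round income to invest in landslide mitigation.  The probability that a
landslide occurs in a round blends two terms: a human-factor probability that
decreases with the cumulative fraction of income invested so far, and an
environmental probability covering rainfall and terrain susceptibility, which
is supplied directly as a configured constant (or per-round series).  When a
landslide occurs it may independently cause property damage (property wealth
halved), injury (income reduced by 10%) and fatality (income reduced by 20%),
and the resulting monetary win/loss feedback is what the learning models
observe.

All currency amounts are in "Electronic Currency" (EC), a fictitious unit
with 1 EC = 1 INR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ILSConfig",
    "ILSState",
    "LandslideOutcome",
    "RoundFeedback",
    "load_config",
    "builtin_config",
    "prob_investment",
    "total_probability",
    "sample_landslide_and_damages",
    "apply_damages",
    "step_round",
    "initial_state",
]

_CONFIG_DIR = Path(__file__).parent / "configs"


@dataclass(frozen=True)
class ILSConfig:
    """Condition parameters of the landslide microworld.

    ``p_env`` is the environmental (physical-factor) landslide probability.
    It subsumes the rainfall and spatial-susceptibility components, which are
    never given separate values; it may be a scalar or a per-round sequence.
    ``mitigation_return_M`` sets the floor ``1 - M`` of the investment-driven
    landslide probability: even full investment cannot push it below ``1 - M``.
    """

    condition_id: str = "custom"
    initial_income: float = 292.0
    initial_property_wealth: float = 20_000_000.0
    weight_We: float = 0.7
    mitigation_return_M: float = 0.9
    p_env: float | Sequence[float] = 0.3
    p_property_damage: float = 0.3
    p_injury: float = 0.9
    p_fatality: float = 0.09
    property_loss_fraction: float = 0.5
    injury_income_fraction: float = 0.10
    fatality_income_fraction: float = 0.20
    n_rounds: int = 30
    n_participants: int = 23

    def __post_init__(self) -> None:
        probs = {
            "weight_We": self.weight_We,
            "mitigation_return_M": self.mitigation_return_M,
            "p_property_damage": self.p_property_damage,
            "p_injury": self.p_injury,
            "p_fatality": self.p_fatality,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for p in np.atleast_1d(np.asarray(self.p_env, dtype=float)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_env values must be in [0, 1], got {p}")
        for name in ("property_loss_fraction", "injury_income_fraction",
                     "fatality_income_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")

    def p_env_at(self, round_t: int) -> float:
        """Environmental probability for 1-based round ``round_t``."""
        if np.isscalar(self.p_env):
            return float(self.p_env)
        seq = np.asarray(self.p_env, dtype=float)
        if not 1 <= round_t <= len(seq):
            raise ValueError(f"round {round_t} outside p_env series of length {len(seq)}")
        return float(seq[round_t - 1])

    def with_overrides(self, **kwargs) -> "ILSConfig":
        return replace(self, **kwargs)


@dataclass
class ILSState:
    """Evolving per-participant state: round counter, income, wealth, budget."""

    round_t: int = 1
    income: float = 292.0
    property_wealth: float = 20_000_000.0
    cum_investment: float = 0.0
    cum_budget: float = 0.0
    total_wealth: float = 20_000_000.0
    #: running sum of un-invested income; total_wealth = this + property_wealth
    retained_income: float = field(default=0.0, repr=False)


@dataclass(frozen=True)
class LandslideOutcome:
    occurred: bool
    property_damage: bool = False
    injury: bool = False
    fatality: bool = False

    @property
    def benign(self) -> bool:
        """A landslide that triggered none of the three damage types."""
        return self.occurred and not (self.property_damage or self.injury or self.fatality)

    def __post_init__(self) -> None:
        if not self.occurred and (self.property_damage or self.injury or self.fatality):
            raise ValueError("damage flags require an occurred landslide")


@dataclass(frozen=True)
class RoundFeedback:
    """What the decision maker observes after a round.

    ``win_W`` is income kept (income minus investment); ``loss_L`` is the
    non-negative loss magnitude: property damage amount plus the drop in
    per-round income caused by injury/fatality this round.
    """

    win_W: float
    loss_L: float
    property_damage_amount_PD: float
    income_drop: float

    def __post_init__(self) -> None:
        if self.loss_L < 0 or self.income_drop < 0:
            raise ValueError("losses must be non-negative magnitudes")


def initial_state(config: ILSConfig) -> ILSState:
    return ILSState(
        round_t=1,
        income=config.initial_income,
        property_wealth=config.initial_property_wealth,
        cum_investment=0.0,
        cum_budget=0.0,
        total_wealth=config.initial_property_wealth,
        retained_income=0.0,
    )


def prob_investment(cum_investment: float, cum_budget: float, M: float) -> float:
    """Landslide probability due to human investments.

    ``1 - M * (cumulative investment / cumulative budget)``: directly
    proportional to the fraction of available income invested so far, with
    floor ``1 - M`` at full investment.
    """
    if cum_budget <= 0:
        raise ValueError("cumulative budget must be positive")
    if not 0 <= cum_investment <= cum_budget:
        raise ValueError("cumulative investment must lie in [0, cumulative budget]")
    if not 0 <= M <= 1:
        raise ValueError("M must be in [0, 1]")
    return 1.0 - M * (cum_investment / cum_budget)


def total_probability(p_inv: float, p_env: float, We: float) -> float:
    """Convex combination ``We * P(I) + (1 - We) * P(E)`` of the human-factor
    and environmental landslide probabilities."""
    for name, v in (("p_inv", p_inv), ("p_env", p_env), ("We", We)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return We * p_inv + (1.0 - We) * p_env


def sample_landslide_and_damages(
    p_total: float, config: ILSConfig, rng: np.random.Generator
) -> LandslideOutcome:
    """Sample a round's landslide event and its damage triggers.

    One uniform decides occurrence (``u <= p_total``); if the landslide
    occurs, three further independent uniforms decide property damage,
    injury and fatality.  Exactly 4 draws are consumed when the landslide
    occurs and 1 otherwise, so trajectories replay bit-exactly from a seed.
    """
    if not 0 <= p_total <= 1:
        raise ValueError(f"p_total must be in [0, 1], got {p_total}")
    occurred = bool(rng.uniform() <= p_total)
    if not occurred:
        return LandslideOutcome(occurred=False)
    return LandslideOutcome(
        occurred=True,
        property_damage=bool(rng.uniform() <= config.p_property_damage),
        injury=bool(rng.uniform() <= config.p_injury),
        fatality=bool(rng.uniform() <= config.p_fatality),
    )


def apply_damages(
    state: ILSState, outcome: LandslideOutcome, config: ILSConfig
) -> tuple[ILSState, float, float]:
    """Apply an outcome's damages to the state.

    Returns ``(new_state, property_damage_amount, income_drop)``.  Property
    damage halves property wealth; injury and fatality multiply income by
    0.90 and 0.80 respectively (both applied multiplicatively if both
    trigger).  There is no recovery mechanism: income only ever decreases.
    """
    pd_amount = 0.0
    prior_income = state.income
    new_wealth = state.property_wealth
    new_income = state.income
    if outcome.property_damage:
        pd_amount = state.property_wealth * config.property_loss_fraction
        new_wealth = state.property_wealth - pd_amount
    if outcome.injury:
        new_income *= 1.0 - config.injury_income_fraction
    if outcome.fatality:
        new_income *= 1.0 - config.fatality_income_fraction
    income_drop = prior_income - new_income
    new_state = replace(state, property_wealth=new_wealth, income=new_income)
    return new_state, pd_amount, income_drop


def step_round(
    state: ILSState,
    investment_ratio: float,
    config: ILSConfig,
    rng: np.random.Generator,
) -> tuple[ILSState, LandslideOutcome, RoundFeedback]:
    """One full round transition.

    Order of operations: observe income -> invest ``ratio * income`` (the
    round's budget is the current income) -> compute landslide probability
    -> sample landslide and damages -> apply damages -> emit feedback.
    Damages sampled in round t therefore reduce income from round t+1 on,
    and the income drop is reported in this round's loss.
    """
    if not 0 <= investment_ratio <= 1:
        raise ValueError(f"investment_ratio must be in [0, 1], got {investment_ratio}")
    income_t = state.income
    invest_t = investment_ratio * income_t
    cum_investment = state.cum_investment + invest_t
    cum_budget = state.cum_budget + income_t

    p_inv = prob_investment(cum_investment, cum_budget, config.mitigation_return_M)
    p_total = total_probability(p_inv, config.p_env_at(state.round_t), config.weight_We)
    outcome = sample_landslide_and_damages(p_total, config, rng)

    interim = replace(state, cum_investment=cum_investment, cum_budget=cum_budget)
    damaged, pd_amount, income_drop = apply_damages(interim, outcome, config)

    win = income_t - invest_t
    feedback = RoundFeedback(
        win_W=win,
        loss_L=pd_amount + income_drop,
        property_damage_amount_PD=pd_amount,
        income_drop=income_drop,
    )
    retained = state.retained_income + win
    new_state = replace(
        damaged,
        round_t=state.round_t + 1,
        retained_income=retained,
        total_wealth=retained + damaged.property_wealth,
    )
    return new_state, outcome, feedback


def load_config(path: str | Path) -> ILSConfig:
    """Read a condition configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"malformed config file: {path}")
    return ILSConfig(**raw)


def builtin_config(condition_id: str) -> ILSConfig:
    """Load one of the packaged condition fixtures: low, high or medium."""
    path = _CONFIG_DIR / f"{condition_id}.yaml"
    if not path.exists():
        raise ValueError(f"unknown condition {condition_id!r}; expected one of low/high/medium")
    return load_config(path)
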