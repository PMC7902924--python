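"""Cohort trajectory generation and I/O.

Two generators produce the per-participant, per-round investment-ratio data
the calibration and evaluation stages consume:

* ``model_ground_truth`` — runs independent model agents through the
  landslide microworld, giving cohorts whose generating parameters are known
  exactly (the substrate for parameter-recovery checks).
* ``stylized_human`` — noise around target mean curves that mimic the
  qualitative human patterns: a flat, low curve in the low damage-feedback
  condition (overall mean 0.38), a rising curve in the high condition
  (overall mean 0.67), and an intermediate flat curve for the medium
  condition.  These curves are synthetic stand-ins; the per-round human
  means were never published as numbers.

Trajectories round-trip through a plain CSV schema, one row per
participant-round.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import ils_env, rl_agents
from .ils_env import ILSConfig
from .rl_agents import ModelParams

__all__ = [
    "CONDITION_N",
    "CohortSpec",
    "CohortTrajectories",
    "stylized_target_curve",
    "generate_model_cohort",
    "generate_stylized_human_cohort",
    "generate_cohort",
    "simulate_model_cohort_fast",
    "write_cohort",
    "read_cohort",
]

#: default cohort sizes per condition
CONDITION_N = {"low": 20, "high": 23, "medium": 30}

_EVENT_COLUMNS = [
    "participant_id", "round", "investment_ratio", "income", "property_wealth",
    "occurred", "property_damage", "injury", "fatality", "W", "L",
]


@dataclass
class CohortSpec:
    """What cohort to generate: condition, size, generator mode and seed."""

    condition_id: str
    generator_mode: str = "stylized_human"  # or "model_ground_truth"
    n_participants: int | None = None
    n_rounds: int = 30
    model_id: str | None = None
    generator_params: ModelParams = None
    target_mean_curve: np.ndarray | None = None
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition_id not in CONDITION_N:
            raise ValueError(f"unknown condition {self.condition_id!r}")
        if self.generator_mode not in ("model_ground_truth", "stylized_human"):
            raise ValueError(f"unknown generator_mode {self.generator_mode!r}")
        if self.n_participants is None:
            self.n_participants = CONDITION_N[self.condition_id]
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CohortTrajectories:
    """Investment ratios (participants x rounds) plus an optional per-round
    environment event log (absent for stylized cohorts)."""

    ratios: np.ndarray
    condition_id: str = "custom"
    events: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.ndim != 2:
            raise ValueError("ratios must be a participants x rounds matrix")
        if np.any((self.ratios < 0) | (self.ratios > 1)) or np.any(np.isnan(self.ratios)):
            raise ValueError("all investment ratios must lie in [0, 1]")

    @property
    def n_participants(self) -> int:
        return self.ratios.shape[0]

    @property
    def n_rounds(self) -> int:
        return self.ratios.shape[1]

    def mean_curve(self) -> np.ndarray:
        return self.ratios.mean(axis=0)

    def grand_mean(self) -> float:
        return float(self.ratios.mean())


def _logistic_high_curve(n_rounds: int, low: float = 0.3, high: float = 0.85,
                         scale: float = 4.0, target_mean: float = 0.67) -> np.ndarray:
    """Rising logistic curve from ``low`` to ``high`` whose overall mean is
    pinned to ``target_mean`` by solving for the midpoint round."""
    t = np.arange(1, n_rounds + 1)

    def mean_minus_target(t0: float) -> float:
        curve = low + (high - low) / (1.0 + np.exp(-(t - t0) / scale))
        return float(curve.mean()) - target_mean

    t0 = brentq(mean_minus_target, -n_rounds, 2 * n_rounds, xtol=1e-12)
    return low + (high - low) / (1.0 + np.exp(-(t - t0) / scale))


def stylized_target_curve(condition_id: str, n_rounds: int = 30) -> np.ndarray:
    """Default synthetic mean curve per condition.

    low: constant 0.38; medium: constant 0.52; high: logistic rise from 0.3
    toward 0.85 with overall mean 0.67.
    """
    if condition_id == "low":
        return np.full(n_rounds, 0.38)
    if condition_id == "medium":
        return np.full(n_rounds, 0.52)
    if condition_id == "high":
        return _logistic_high_curve(n_rounds)
    raise ValueError(f"unknown condition {condition_id!r}")


def generate_model_cohort(spec: CohortSpec, ils_config: ILSConfig) -> CohortTrajectories:
    """Run ``n_participants`` independent model agents through the microworld.

    Each participant gets its own spawned RNG stream, so the cohort is
    reproducible bit-exactly from ``spec.seed`` and individual trajectories
    do not depend on cohort size ordering.
    """
    if spec.generator_mode != "model_ground_truth":
        raise ValueError("spec.generator_mode must be 'model_ground_truth'")
    if spec.model_id is None:
        raise ValueError("model_id required for a model-ground-truth cohort")
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_participants)
    ratios = np.empty((spec.n_participants, spec.n_rounds))
    rows = []
    for i, child in enumerate(streams):
        rng = np.random.default_rng(child)
        state = ils_env.initial_state(ils_config)
        ev = rl_agents.initial_expectancies()
        feedback = None
        last_k = None
        for t in range(1, spec.n_rounds + 1):
            k, ratio, ev = rl_agents.agent_act(
                spec.model_id, spec.generator_params, ev, t, feedback, last_k, rng,
                scale_divisor=ils_config.initial_income)
            income_before = state.income
            wealth_before = state.property_wealth
            state, outcome, feedback = ils_env.step_round(state, ratio, ils_config, rng)
            last_k = k
            ratios[i, t - 1] = ratio
            rows.append((i, t, ratio, income_before, wealth_before,
                         outcome.occurred, outcome.property_damage, outcome.injury,
                         outcome.fatality, feedback.win_W, feedback.loss_L))
    events = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    return CohortTrajectories(ratios=ratios, condition_id=spec.condition_id, events=events)


def generate_stylized_human_cohort(spec: CohortSpec) -> CohortTrajectories:
    """Target mean curve plus independent Gaussian noise, clipped to [0, 1]."""
    if spec.generator_mode != "stylized_human":
        raise ValueError("spec.generator_mode must be 'stylized_human'")
    curve = (np.asarray(spec.target_mean_curve, dtype=float)
             if spec.target_mean_curve is not None
             else stylized_target_curve(spec.condition_id, spec.n_rounds))
    if len(curve) != spec.n_rounds:
        raise ValueError("target_mean_curve length must equal n_rounds")
    if np.any((curve < 0) | (curve > 1)):
        raise ValueError("target_mean_curve values must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_participants, spec.n_rounds))
    ratios = np.clip(curve[None, :] + noise, 0.0, 1.0)
    return CohortTrajectories(ratios=ratios, condition_id=spec.condition_id)


def generate_cohort(spec: CohortSpec, ils_config: ILSConfig | None = None) -> CohortTrajectories:
    """Dispatch on ``spec.generator_mode``."""
    if spec.generator_mode == "stylized_human":
        return generate_stylized_human_cohort(spec)
    if ils_config is None:
        ils_config = ils_env.builtin_config(spec.condition_id)
    return generate_model_cohort(spec, ils_config)


def simulate_model_cohort_fast(
    model_id: str,
    params: ModelParams,
    config: ILSConfig,
    n_participants: int,
    n_rounds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized simulation of a model cohort; returns ratios (B x T).

    Mathematically identical to the scalar agent/environment loop but
    evaluated across all participants at once with a single shared RNG.
    Batch draw order per round: choice uniforms, within-bin uniforms,
    landslide-occurrence uniforms, then a fixed block of three damage
    uniforms per participant (drawn whether or not the landslide occurred,
    to keep the draw count round-invariant).  Used by the calibration
    objective, where it is orders of magnitude faster than the scalar path.
    """
    rl_agents._check_model_id(model_id)
    rl_agents._check_params(model_id, params)
    B, T = n_participants, n_rounds
    divisor = config.initial_income
    M, We = config.mitigation_return_M, config.weight_We

    income = np.full(B, config.initial_income)
    wealth = np.full(B, config.initial_property_wealth)
    cum_inv = np.zeros(B)
    cum_budget = np.zeros(B)
    ev = np.full((B, rl_agents.N_OPTIONS), rl_agents.INITIAL_EXPECTANCY)
    last_idx = np.zeros(B, dtype=int)
    ratios = np.empty((B, T))
    scaled_win = scaled_loss = None
    rows = np.arange(B)

    for t in range(1, T + 1):
        if scaled_win is not None and model_id != "random":
            net = scaled_win - scaled_loss
            if model_id == "ev":
                v = (1.0 - params.loss_weight_w) * scaled_win - params.loss_weight_w * scaled_loss
                a = params.recency_a
                ev[rows, last_idx] = (1.0 - a) * ev[rows, last_idx] + a * v
            elif model_id == "evpu":
                u = np.where(net >= 0, np.abs(net) ** params.shape_alpha,
                             -params.loss_aversion_lambda * np.abs(net) ** params.shape_alpha)
                a = params.recency_A
                ev[rows, last_idx] = (1.0 - a) * ev[rows, last_idx] + a * u
            else:
                if model_id == "pvl":
                    u = np.where(net >= 0, np.abs(net) ** params.shape_alpha,
                                 -params.loss_aversion_lambda * np.abs(net) ** params.shape_alpha)
                else:  # pvl2
                    u = (scaled_win ** params.shape_alpha
                         - params.loss_aversion_lambda * scaled_loss ** params.shape_alpha)
                ev *= params.recency_A
                ev[rows, last_idx] += u

        if model_id == "random":
            k_idx = np.argmax(rng.uniform(size=(B, rl_agents.N_OPTIONS)), axis=1)
        else:
            theta = (rl_agents.ev_theta(t, params.consistency_c)
                     if model_id in ("ev", "evpu")
                     else rl_agents.pvl_theta(params.consistency_c))
            z = theta * ev
            z -= z.max(axis=1, keepdims=True)
            e = np.exp(z)
            cdf = np.cumsum(e, axis=1)
            u_choice = rng.uniform(size=B) * cdf[:, -1]
            k_idx = (cdf < u_choice[:, None]).sum(axis=1)
        last_idx = k_idx
        ratio = (k_idx + rng.uniform(size=B)) / rl_agents.N_OPTIONS
        ratios[:, t - 1] = ratio

        invest = ratio * income
        cum_inv += invest
        cum_budget += income
        p_inv = 1.0 - M * cum_inv / cum_budget
        p_total = We * p_inv + (1.0 - We) * config.p_env_at(t)
        occurred = rng.uniform(size=B) <= p_total
        dmg = rng.uniform(size=(B, 3))
        prop = occurred & (dmg[:, 0] <= config.p_property_damage)
        injury = occurred & (dmg[:, 1] <= config.p_injury)
        fatality = occurred & (dmg[:, 2] <= config.p_fatality)

        pd_amount = np.where(prop, wealth * config.property_loss_fraction, 0.0)
        wealth = wealth - pd_amount
        new_income = income.copy()
        new_income[injury] *= 1.0 - config.injury_income_fraction
        new_income[fatality] *= 1.0 - config.fatality_income_fraction
        income_drop = income - new_income
        scaled_win = (income - invest) / divisor
        scaled_loss = (pd_amount + income_drop) / divisor
        income = new_income

    return ratios


def write_cohort(cohort: CohortTrajectories, path: str | Path) -> None:
    """Write one row per participant-round; lossless for ratios at full
    float precision.  Event columns are included when an event log exists."""
    path = Path(path)
    if cohort.events is not None:
        df = cohort.events
    else:
        n, t = cohort.ratios.shape
        df = pd.DataFrame({
            "participant_id": np.repeat(np.arange(n), t),
            "round": np.tile(np.arange(1, t + 1), n),
            "investment_ratio": cohort.ratios.ravel(),
        })
    df = df.copy()
    df.insert(0, "condition_id", cohort.condition_id)
    df.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path: str | Path) -> CohortTrajectories:
    """Read a cohort CSV written by :func:`write_cohort`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty or malformed cohort file: {path}") from exc
    required = {"participant_id", "round", "investment_ratio"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort file {path} missing columns {sorted(required - set(df.columns))}")
    bad = df[(df["investment_ratio"] < 0) | (df["investment_ratio"] > 1)
             | df["investment_ratio"].isna()]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"invalid investment ratio {row['investment_ratio']!r} at participant "
            f"{row['participant_id']}, round {row['round']} in {path}")
    pivot = df.pivot(index="participant_id", columns="round", values="investment_ratio")
    if pivot.isna().any().any():
        raise ValueError(f"cohort file {path} has missing participant-round cells")
    condition = str(df["condition_id"].iloc[0]) if "condition_id" in df.columns else "custom"
    events = df if set(_EVENT_COLUMNS).issubset(df.columns) else None
    return CohortTrajectories(ratios=pivot.to_numpy(), condition_id=condition, events=events)
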