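"""Reinforcement-learning decision models over ten investment-ratio bins.

Five model families produce a continuous investment ratio each round by
first choosing one of ten 10%-wide bins and then drawing uniformly within
the chosen bin:

* ``ev``     — expectancy-valence: linear loss-weighted valence, delta-rule
  learning on the chosen option only, softmax choice with round-dependent
  sensitivity ``theta(t) = (t/10)**c``.
* ``pvl``    — prospect-valence learning: prospect utility of the net
  outcome, decay-reinforcement learning (all expectancies decay, the chosen
  option absorbs the utility), round-independent sensitivity ``3**c - 1``.
* ``evpu``   — prospect utility of the net outcome combined with the EV
  model's delta-rule learning and round-dependent sensitivity.
* ``pvl2``   — like ``pvl`` but with a utility that evaluates wins and
  losses separately: ``win**alpha - lambda * loss**alpha``.
* ``random`` — no learning; each round draws ten uniform expectancies and
  picks the argmax.

Expectancies start at 50 units for every bin, so the first choice of every
model is uniform over the ten bins.  Monetary feedback is divided by the
initial per-round income before entering utility space, keeping softmax
arguments on an O(1) scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .ils_env import RoundFeedback

__all__ = [
    "MODEL_IDS",
    "N_OPTIONS",
    "INITIAL_EXPECTANCY",
    "DEFAULT_SCALE_DIVISOR",
    "EVParams",
    "ProspectParams",
    "ModelParams",
    "ScaledOutcome",
    "params_from_dict",
    "param_bounds",
    "initial_expectancies",
    "scale_outcome",
    "ev_valence",
    "ev_update",
    "ev_theta",
    "pvl_theta",
    "softmax_probabilities",
    "softmax_choose",
    "prospect_utility",
    "pvl2_utility",
    "decay_update",
    "option_to_ratio",
    "random_model_choose",
    "agent_act",
]

MODEL_IDS = ("ev", "pvl", "evpu", "pvl2", "random")
N_OPTIONS = 10
INITIAL_EXPECTANCY = 50.0
#: initial per-round income in EC; W(1) = 1 in scaled units at zero investment
DEFAULT_SCALE_DIVISOR = 292.0


@dataclass(frozen=True)
class EVParams:
    """Expectancy-valence parameters: recency ``a``, loss weight ``w``,
    consistency ``c`` (negative = exploration, positive = exploitation)."""

    recency_a: float
    loss_weight_w: float
    consistency_c: float

    def __post_init__(self) -> None:
        if not 0 <= self.recency_a <= 1:
            raise ValueError("recency_a must be in [0, 1]")
        if not 0 <= self.loss_weight_w <= 1:
            raise ValueError("loss_weight_w must be in [0, 1]")
        if not -5 <= self.consistency_c <= 5:
            raise ValueError("consistency_c must be in [-5, 5]")


@dataclass(frozen=True)
class ProspectParams:
    """Prospect-family parameters: utility shape ``alpha``, loss aversion
    ``lambda``, recency ``A`` and consistency ``c``.

    ``consistency_c`` lives in [0, 5] for the pvl/pvl2 sensitivity
    ``3**c - 1`` and in [-5, 5] for the evpu model, which reuses the EV
    round-dependent sensitivity.
    """

    shape_alpha: float
    loss_aversion_lambda: float
    recency_A: float
    consistency_c: float
    ev_style_c: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.shape_alpha <= 1:
            raise ValueError("shape_alpha must be in [0, 1]")
        if not 0 <= self.loss_aversion_lambda <= 5:
            raise ValueError("loss_aversion_lambda must be in [0, 5]")
        if not 0 <= self.recency_A <= 1:
            raise ValueError("recency_A must be in [0, 1]")
        lo = -5.0 if self.ev_style_c else 0.0
        if not lo <= self.consistency_c <= 5:
            raise ValueError(f"consistency_c must be in [{lo}, 5]")


ModelParams = Union[EVParams, ProspectParams, None]


@dataclass(frozen=True)
class ScaledOutcome:
    """Round feedback in scaled utility units; ``net_x = win - loss``."""

    win: float
    loss: float

    @property
    def net_x(self) -> float:
        return self.win - self.loss


def params_from_dict(model_id: str, d: dict) -> ModelParams:
    """Build a parameter object for ``model_id`` from a plain mapping."""
    _check_model_id(model_id)
    if model_id == "random":
        if d:
            raise ValueError("the random model has no parameters")
        return None
    if model_id == "ev":
        return EVParams(**d)
    return ProspectParams(**d, ev_style_c=(model_id == "evpu"))


def param_bounds(model_id: str) -> dict[str, tuple[float, float]]:
    """Search bounds per parameter, as used by the genetic calibration."""
    _check_model_id(model_id)
    if model_id == "random":
        return {}
    if model_id == "ev":
        return {"recency_a": (0.0, 1.0), "loss_weight_w": (0.0, 1.0),
                "consistency_c": (-5.0, 5.0)}
    c_lo = -5.0 if model_id == "evpu" else 0.0
    return {"shape_alpha": (0.0, 1.0), "loss_aversion_lambda": (0.0, 5.0),
            "recency_A": (0.0, 1.0), "consistency_c": (c_lo, 5.0)}


def n_free_params(model_id: str) -> int:
    """Number of free parameters: 3 (ev), 4 (prospect family), 0 (random)."""
    return len(param_bounds(model_id))


def _check_model_id(model_id: str) -> None:
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}; expected one of {MODEL_IDS}")


def initial_expectancies() -> np.ndarray:
    return np.full(N_OPTIONS, INITIAL_EXPECTANCY)


def scale_outcome(feedback: RoundFeedback, scale_divisor: float = DEFAULT_SCALE_DIVISOR) -> ScaledOutcome:
    if scale_divisor <= 0:
        raise ValueError("scale_divisor must be positive")
    return ScaledOutcome(win=feedback.win_W / scale_divisor,
                         loss=feedback.loss_L / scale_divisor)


def ev_valence(win: float, loss: float, w: float) -> float:
    """Loss-weighted valence ``(1 - w) * win - w * loss``.

    ``loss`` is a non-negative magnitude and enters with negative sign, so
    larger ``w`` means losses punish harder.
    """
    if not 0 <= w <= 1:
        raise ValueError("w must be in [0, 1]")
    if loss < 0:
        raise ValueError("loss must be a non-negative magnitude")
    return (1.0 - w) * win - w * loss


def ev_update(ev_k: float, valence: float, a: float) -> float:
    """Delta-rule blend ``(1 - a) * ev_k + a * valence`` for the chosen
    option; unchosen options are left untouched by the caller."""
    if not 0 <= a <= 1:
        raise ValueError("a must be in [0, 1]")
    return (1.0 - a) * ev_k + a * valence


def ev_theta(round_t: int, c: float) -> float:
    """Round-dependent choice sensitivity ``(t / 10) ** c``."""
    if round_t < 1:
        raise ValueError("round_t must be >= 1")
    return (round_t / 10.0) ** c


def pvl_theta(c: float) -> float:
    """Round-independent choice sensitivity ``3 ** c - 1``."""
    if not 0 <= c <= 5:
        raise ValueError("c must be in [0, 5]")
    return 3.0 ** c - 1.0


def softmax_probabilities(expectancies: np.ndarray, theta: float) -> np.ndarray:
    """Overflow-safe softmax ``exp(theta * EV_k) / sum_j exp(theta * EV_j)``."""
    z = theta * np.asarray(expectancies, dtype=float)
    if np.any(np.isnan(z)) or not np.isfinite(theta):
        raise ValueError("expectancies and theta must be finite")
    z = z - np.max(z)
    e = np.exp(z)
    total = e.sum()
    if total == 0 or not np.isfinite(total):
        raise ValueError("degenerate expectancies: softmax undefined")
    return e / total


def softmax_choose(expectancies: np.ndarray, theta: float, rng: np.random.Generator) -> int:
    """Sample a 1-based option index from the softmax distribution.

    Consumes exactly one uniform draw (inverse-CDF against the cumulative
    probabilities).
    """
    probs = softmax_probabilities(expectancies, theta)
    u = rng.uniform()
    return int(np.searchsorted(np.cumsum(probs), u, side="right")) + 1


def prospect_utility(net_x: float, alpha: float, lam: float) -> float:
    """Prospect utility of a net outcome: ``x**alpha`` for gains,
    ``-lambda * |x|**alpha`` for losses."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if not 0 <= lam <= 5:
        raise ValueError("lambda must be in [0, 5]")
    if net_x >= 0:
        return net_x ** alpha
    return -lam * abs(net_x) ** alpha


def pvl2_utility(win: float, loss: float, alpha: float, lam: float) -> float:
    """Separate-evaluation prospect utility ``win**alpha - lambda * loss**alpha``.

    Unlike the net-outcome form, a simultaneous win and loss of equal size
    does not feel neutral unless ``lambda = 1``.
    """
    if win < 0 or loss < 0:
        raise ValueError("win and loss must be non-negative magnitudes")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if not 0 <= lam <= 5:
        raise ValueError("lambda must be in [0, 5]")
    return win ** alpha - lam * loss ** alpha


def decay_update(expectancies: np.ndarray, chosen_k: int, utility: float, A: float) -> np.ndarray:
    """Decay-reinforcement rule: every expectancy decays by factor ``A``;
    the chosen option then absorbs the current utility."""
    if not 0 <= A <= 1:
        raise ValueError("A must be in [0, 1]")
    if not 1 <= chosen_k <= N_OPTIONS:
        raise ValueError(f"chosen_k must be in 1..{N_OPTIONS}")
    out = A * np.asarray(expectancies, dtype=float)
    out[chosen_k - 1] += utility
    return out


def option_to_ratio(k: int, rng: np.random.Generator) -> float:
    """Map a 1-based bin index to a uniform draw in ``[(k-1)/10, k/10)``.

    Consumes exactly one uniform draw.
    """
    if not 1 <= k <= N_OPTIONS:
        raise ValueError(f"option index must be in 1..{N_OPTIONS}, got {k}")
    return (k - 1 + rng.uniform()) / N_OPTIONS


def random_model_choose(rng: np.random.Generator) -> int:
    """Baseline no-learning choice: ten iid uniform expectancies, argmax.

    Ties (measure zero) resolve to the lowest index.  Consumes exactly ten
    uniform draws.
    """
    return int(np.argmax(rng.uniform(size=N_OPTIONS))) + 1


def _utility_and_learn(
    model_id: str,
    params: ModelParams,
    expectancies: np.ndarray,
    scaled: ScaledOutcome,
    last_choice_k: int,
) -> np.ndarray:
    """Evaluate last round's outcome under the model's utility and update
    the expectancies.  Returns a new array; the input is not mutated."""
    ev = np.array(expectancies, dtype=float)
    if model_id == "ev":
        v = ev_valence(scaled.win, scaled.loss, params.loss_weight_w)
        ev[last_choice_k - 1] = ev_update(ev[last_choice_k - 1], v, params.recency_a)
    elif model_id == "evpu":
        u = prospect_utility(scaled.net_x, params.shape_alpha, params.loss_aversion_lambda)
        ev[last_choice_k - 1] = ev_update(ev[last_choice_k - 1], u, params.recency_A)
    elif model_id == "pvl":
        u = prospect_utility(scaled.net_x, params.shape_alpha, params.loss_aversion_lambda)
        ev = decay_update(ev, last_choice_k, u, params.recency_A)
    elif model_id == "pvl2":
        u = pvl2_utility(scaled.win, scaled.loss, params.shape_alpha, params.loss_aversion_lambda)
        ev = decay_update(ev, last_choice_k, u, params.recency_A)
    else:
        raise ValueError(f"model {model_id!r} does not learn")
    return ev


def agent_act(
    model_id: str,
    params: ModelParams,
    expectancies: np.ndarray,
    round_t: int,
    last_feedback: RoundFeedback | None,
    last_choice_k: int | None,
    rng: np.random.Generator,
    scale_divisor: float = DEFAULT_SCALE_DIVISOR,
) -> tuple[int, float, np.ndarray]:
    """One decision cycle: learn from last round's feedback, then choose.

    Returns ``(option index, investment ratio, updated expectancies)``.  On
    the first round (``last_feedback is None``) no update happens, and the
    equal initial expectancies make the choice uniform over the ten bins.
    Draw order per round: choice draw(s) first, then the within-bin draw.
    """
    _check_model_id(model_id)
    _check_params(model_id, params)
    ev = np.asarray(expectancies, dtype=float)
    if model_id != "random" and last_feedback is not None:
        if last_choice_k is None:
            raise ValueError("feedback supplied without the choice that produced it")
        scaled = scale_outcome(last_feedback, scale_divisor)
        ev = _utility_and_learn(model_id, params, ev, scaled, last_choice_k)

    if model_id == "random":
        k = random_model_choose(rng)
    else:
        if model_id in ("ev", "evpu"):
            theta = ev_theta(round_t, params.consistency_c)
        else:
            theta = pvl_theta(params.consistency_c)
        k = softmax_choose(ev, theta, rng)
    ratio = option_to_ratio(k, rng)
    return k, ratio, ev


def _check_params(model_id: str, params: ModelParams) -> None:
    if model_id == "random":
        if params is not None:
            raise ValueError("the random model takes params=None")
    elif model_id == "ev":
        if not isinstance(params, EVParams):
            raise ValueError("ev model requires EVParams")
    else:
        if not isinstance(params, ProspectParams):
            raise ValueError(f"{model_id} model requires ProspectParams")
        if (model_id == "evpu") != params.ev_style_c and params.consistency_c < 0:
            raise ValueError("negative consistency_c only valid for evpu")
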