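"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written with plain loops and ``math`` so it
shares no code path with the implementation under test.
"""

from __future__ import annotations

import math

N_OPTIONS = 10


def ssd1_brute(model_curve, human_curve) -> float:
    total = 0.0
    for m, h in zip(model_curve, human_curve, strict=True):
        total += (m - h) ** 2
    return total / len(model_curve)


def r_squared_brute(model_curve, human_curve) -> float:
    """Squared Pearson correlation via the raw product-moment formula."""
    n = len(model_curve)
    sm = sum(model_curve)
    sh = sum(human_curve)
    smh = sum(m * h for m, h in zip(model_curve, human_curve, strict=True))
    sm2 = sum(m * m for m in model_curve)
    sh2 = sum(h * h for h in human_curve)
    num = n * smh - sm * sh
    den = math.sqrt((n * sm2 - sm * sm) * (n * sh2 - sh * sh))
    r = num / den
    return r * r


def aic1_brute(ssd1_value: float, p: int, n_rounds: int = 30) -> float:
    return n_rounds * math.log(ssd1_value) + 2 * p


def ssd2_aic2_brute(xm: float, xh: float, p: int) -> tuple[float, float]:
    ssd2 = (xm - xh) ** 2
    return ssd2, math.log(ssd2) + 2 * p


def block_means_brute(curve) -> list[float]:
    out = []
    for start in range(0, len(curve), 5):
        out.append(sum(curve[start:start + 5]) / 5.0)
    return out


def softmax_brute(expectancies, theta) -> list[float]:
    m = max(theta * e for e in expectancies)
    ex = [math.exp(theta * e - m) for e in expectancies]
    s = sum(ex)
    return [e / s for e in ex]


# --- scripted 3-round trace (generator of tests/data/hand_trace.json) ------

TRACE_U_CHOICE = [0.25, 0.95, 0.5]
TRACE_FEEDBACK = [(1.0, 0.5), (0.2, 1.0)]  # scaled (win, loss) after rounds 1, 2


def _choose(probs, u) -> int:
    c = 0.0
    cums = []
    for p in probs:
        c += p
        cums.append(c)
    return 1 + sum(1 for cv in cums if cv <= u)


def _prospect_u(x, alpha, lam) -> float:
    return x ** alpha if x >= 0 else -lam * abs(x) ** alpha


def hand_trace(model: str) -> dict:
    """Recompute the scripted trace for one model with plain arithmetic."""
    a = w = 0.5
    alpha, lam, A, c_p = 0.5, 2.0, 0.5, 1.0
    c_ev = 0.0
    ev = [50.0] * N_OPTIONS
    out = {"expectancies": [], "probs": [], "chosen": []}
    last_k = None
    for t in (1, 2, 3):
        if t > 1:
            win, loss = TRACE_FEEDBACK[t - 2]
            if model == "ev":
                v = (1 - w) * win - w * loss
                ev[last_k - 1] = (1 - a) * ev[last_k - 1] + a * v
            elif model == "evpu":
                u = _prospect_u(win - loss, alpha, lam)
                ev[last_k - 1] = (1 - A) * ev[last_k - 1] + A * u
            elif model == "pvl":
                u = _prospect_u(win - loss, alpha, lam)
                ev = [A * e for e in ev]
                ev[last_k - 1] += u
            elif model == "pvl2":
                u = win ** alpha - lam * loss ** alpha
                ev = [A * e for e in ev]
                ev[last_k - 1] += u
        if model == "ev":
            theta = (t / 10.0) ** c_ev
        elif model == "evpu":
            theta = (t / 10.0) ** c_p
        else:
            theta = 3.0 ** c_p - 1.0
        probs = softmax_brute(ev, theta)
        k = _choose(probs, TRACE_U_CHOICE[t - 1])
        out["expectancies"].append(list(ev))
        out["probs"].append(probs)
        out["chosen"].append(k)
        last_k = k
    return out
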