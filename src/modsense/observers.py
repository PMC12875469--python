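"""Simulated 3AFC listeners.

A listener is a psychometric function on an *easiness* axis (dB): for both
the temporal and the spectral task, a larger depth in dB means deeper
modulation and an easier trial, so easiness is simply the trial's depth in
dB.  The probability of a correct response is

    P(correct | e) = guess + (1 - guess - lapse) * F(slope * (e - midpoint))

with ``guess = 1/3`` for three alternatives, a lapse rate bounding ceiling
performance, and ``F`` either a logistic (default) or a Weibull-shaped
cumulative function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = ["ObserverParams", "psychometric_p", "observer_response", "psychometric_inverse"]


@dataclass(frozen=True)
class ObserverParams:
    """Psychometric-function parameters of one simulated listener.

    midpoint_dB : easiness at which performance is halfway between the
        guessing floor and the (1 - lapse) ceiling.
    slope : per-dB steepness (> 0) on the easiness axis.
    guess : chance level, 1/3 for 3AFC.
    lapse : stimulus-independent error rate in [0, 0.1].
    """

    midpoint_dB: float
    slope: float
    guess: float = 1.0 / 3.0
    lapse: float = 0.0
    form: Literal["logistic", "weibull"] = "logistic"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")
        if self.guess + self.lapse >= 1:
            raise ValueError("guess + lapse must be < 1")


def _core(params: ObserverParams, easiness_dB) -> np.ndarray:
    z = params.slope * (np.asarray(easiness_dB, dtype=float) - params.midpoint_dB)
    if params.form == "logistic":
        return expit(z)
    # Weibull on the easiness axis: 1 - exp(-exp(z)) (Gumbel/log-Weibull form)
    return 1.0 - np.exp(-np.exp(np.minimum(z, 50.0)))


def psychometric_p(params: ObserverParams, easiness_dB) -> np.ndarray | float:
    """P(correct) at the given easiness (dB); scalar in, scalar out."""
    p = params.guess + (1.0 - params.guess - params.lapse) * _core(params, easiness_dB)
    return float(p) if np.isscalar(easiness_dB) else p


def observer_response(
    params: ObserverParams, easiness_dB: float, rng: np.random.Generator
) -> bool:
    """One Bernoulli 3AFC response at the given easiness."""
    return bool(rng.random() < psychometric_p(params, easiness_dB))


def psychometric_inverse(params: ObserverParams, p_target: float) -> float:
    """Easiness (dB) at which P(correct) equals ``p_target``.

    Exists and is unique for ``guess < p_target < 1 - lapse`` because the
    psychometric function is strictly increasing.
    """
    if not params.guess < p_target < 1.0 - params.lapse:
        raise ValueError(
            f"p_target {p_target} outside achievable range "
            f"({params.guess}, {1.0 - params.lapse})"
        )
    core = (p_target - params.guess) / (1.0 - params.guess - params.lapse)
    if params.form == "logistic":
        z = np.log(core / (1.0 - core))
        return float(params.midpoint_dB + z / params.slope)
    # invert numerically for other forms
    lo, hi = params.midpoint_dB - 100 / params.slope, params.midpoint_dB + 100 / params.slope
    return float(brentq(lambda e: psychometric_p(params, e) - p_target, lo, hi))
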