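"""Temporal modulation transfer function (TMTF) summarization.

A TMTF is the modulation-detection threshold (dB, more negative = better)
as a function of amplitude-modulation rate.  It is summarized by two
numbers: the low-rate sensitivity plateau (intercept, dB) and the 3-dB-down
cutoff (Hz), the rate at which sensitivity has worsened by 3 dB relative to
the plateau.  The conventional parameter-light summary fitted here is a
first-order low-pass characteristic in dB,

    T(f) = S + 10 * log10(1 + (f / fc)^2),

whose value at ``f = fc`` is exactly ``S + 10*log10(2)`` ≈ S + 3.01 dB, so
``fc`` *is* the 3-dB point analytically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["TMTFData", "TMTFSummary", "fit_tmtf"]


@dataclass(frozen=True)
class TMTFData:
    """Thresholds (dB) at a set of strictly increasing modulation rates (Hz)."""

    rates_hz: tuple[float, ...]
    thresholds_dB: tuple[float, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.rates_hz, dtype=float)
        t = np.asarray(self.thresholds_dB, dtype=float)
        if len(r) != len(t):
            raise ValueError("rates and thresholds must have equal length")
        if np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("rates must be positive and strictly increasing")
        object.__setattr__(self, "rates_hz", tuple(float(x) for x in r))
        object.__setattr__(self, "thresholds_dB", tuple(float(x) for x in t))


@dataclass(frozen=True)
class TMTFSummary:
    intercept_dB: float
    cutoff_hz: float | None  # None when the data show no roll-off
    in_range: bool
    method: str  # "lowpass" or "interp"


def _lowpass(f: np.ndarray, S: float, log_fc: float) -> np.ndarray:
    fc = np.exp(log_fc)
    return S + 10.0 * np.log10(1.0 + (f / fc) ** 2)


def fit_tmtf(data: TMTFData) -> TMTFSummary:
    """Fit the first-order low-pass TMTF summary by least squares.

    The fit is performed over log-rate (``fc`` parameterized as its log so
    the optimizer works on an unconstrained scale).  If the parametric fit
    fails to converge the function falls back to monotone piecewise-linear
    interpolation in log-frequency: intercept = best (minimum) threshold,
    cutoff = the interpolated rate at intercept + 3 dB.

    Degenerate flat data return the common threshold as the intercept with
    the cutoff flagged undefined.
    """
    rates = np.asarray(data.rates_hz, dtype=float)
    thr = np.asarray(data.thresholds_dB, dtype=float)
    if len(rates) < 2:
        raise ValueError("need at least 2 rates")
    if np.ptp(thr) < 1e-9:
        return TMTFSummary(float(thr[0]), None, False, "flat")

    if len(rates) >= 3:
        try:
            p0 = (float(thr.min()), float(np.log(np.median(rates))))
            popt, _ = curve_fit(_lowpass, rates, thr, p0=p0, maxfev=20000)
            S, fc = float(popt[0]), float(np.exp(popt[1]))
            in_range = bool(rates[0] <= fc <= rates[-1])
            return TMTFSummary(S, fc, in_range, "lowpass")
        except RuntimeError:
            pass

    # two-point / fallback mode: monotone interpolation in log-frequency
    S = float(thr.min())
    target = S + 3.0
    logf = np.log(rates)
    cutoff = None
    for i in range(len(rates) - 1):
        lo, hi = thr[i], thr[i + 1]
        if (lo - target) * (hi - target) <= 0 and lo != hi:
            w = (target - lo) / (hi - lo)
            cutoff = float(np.exp(logf[i] + w * (logf[i + 1] - logf[i])))
            break
    return TMTFSummary(S, cutoff, cutoff is not None, "interp")
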