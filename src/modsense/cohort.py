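"""Latent-mediation synthetic cohort generator.

The generator stands in for an unpublished sample of 104 five- to
seven-year-olds.  Its causal skeleton encodes the hypothesis the analysis
stage is designed to probe: a latent *central auditory maturation* variable
``A`` mediates the effect of the demographic risk factors on language,

    A    = a1*zSES + a2*zGA + eps_A                (Var(A) = 1)
    thr_k = -(lambda)*A + sqrt(1-lambda^2)*eps_k   (lower threshold = better)
    y_j  = b1*A + b2*zSES + eps_j                  (z-scale, then affine map)

with *full* mediation of gestational age (no direct GA→language path) and
*partial* mediation of socioeconomic status (``b2 > 0`` is a direct path)
by default.  Demographic satellites (maternal education, birthweight, NICU
days) hang off SES/GA at their observed correlations.  All z-scored
variables are affinely mapped to configured means/SDs; bounded variables
(percent scores, gestational weeks, the SES index, thresholds) use a
moment-compensated clipped normal: the pre-clip parameters are solved so
the post-clip mean and SD hit the targets.

Default path coefficients were derived from the published correlation
pattern: cross-threshold r = lambda^2 (~0.72), r(SES, thr) = -lambda*a1,
r(GA, thr) = -lambda*a2, r(y, thr) = -lambda*(b1 + b2*a1),
r(y, SES) = b1*a1 + b2, r(y, GA) = b1*a2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import fsolve

from .inference import COHORT_COLUMNS, OUTCOME_VARS, THRESHOLD_VARS, validate_cohort
from .observers import ObserverParams
from .staircase import TrackConfig, measure_task

__all__ = [
    "CohortParams",
    "ObserverMapping",
    "generate_cohort",
    "observer_from_latent",
    "simulate_study",
    "read_cohort_csv",
    "write_cohort_csv",
    "DEFAULT_MOMENTS",
    "VARIABLE_BOUNDS",
]

#: Target (mean, SD) per observed variable.  Language scores use the
#: published standard-score moments as the working scale for the raw-score
#: columns (raw-score moments are not published).
DEFAULT_MOMENTS: dict[str, tuple[float, float]] = {
    "age_months": (71.4, 7.2),
    "ses_index": (25.8, 16.1),
    "maternal_ed_years": (13.0, 1.5),
    "gestational_age_weeks": (37.6, 3.5),
    "birthweight_g": (3054.0, 860.0),
    "nicu_days": (7.6, 24.8),
    "temporal8_dB": (-12.1, 6.2),
    "temporal64_dB": (-10.6, 5.9),
    "spectral_dB": (19.3, 8.3),
    "vocab_raw": (101.7, 14.1),
    "aud_comp_raw": (96.4, 13.8),
    "icc_pct": (44.0, 33.8),
    "rhyme_pct": (48.2, 31.0),
}

#: Hard bounds enforced by clipping (with moment compensation).
VARIABLE_BOUNDS: dict[str, tuple[float, float]] = {
    "ses_index": (1.0, 64.0),
    "gestational_age_weeks": (23.0, 42.0),
    "temporal8_dB": (-np.inf, 0.0),
    "temporal64_dB": (-np.inf, 0.0),
    "spectral_dB": (0.0, np.inf),
    "icc_pct": (0.0, 100.0),
    "rhyme_pct": (0.0, 100.0),
}


@dataclass(frozen=True)
class CohortParams:
    """Structural and calibration parameters of the synthetic cohort.

    a1, a2 : paths SES→A and GA→A (z scale).
    noise_A : SD of the latent disturbance; None standardizes Var(A)=1.
    threshold_loading : common loading of the three thresholds on A.
    threshold_noise : unique SD per threshold; None standardizes to unit
        variance.
    b1, b2 : per-outcome paths A→y and the *direct* SES→y path.  ``b2 > 0``
        makes SES partially mediated; the absence of any direct GA path makes
        gestational age fully mediated by construction.
    ga_direct : optional direct GA→y path (0 = full mediation).
    rho_ses_ga : correlation between the two risk factors.
    """

    n: int = 104
    a1: float = 0.30
    a2: float = 0.45
    rho_ses_ga: float = 0.0
    noise_A: float | None = None
    threshold_loading: float = float(np.sqrt(0.72))
    threshold_noise: float | None = None
    b1: float = 0.55
    b2: float = 0.25
    ga_direct: float = 0.0
    outcome_noise: float | None = None
    r_maternal_ed: float = 0.822
    r_birthweight: float = 0.823
    r_nicu: float = -0.779
    moments: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MOMENTS)
    )

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        lam = self.threshold_loading
        if not 0 <= lam <= 1:
            raise ValueError("threshold_loading must be in [0, 1]")
        var_A = self.a1**2 + self.a2**2 + 2 * self.a1 * self.a2 * self.rho_ses_ga
        if self.noise_A is None and var_A > 1:
            raise ValueError(
                "a1/a2/rho imply Var(A) > 1; the latent disturbance variance "
                f"would be negative (structural part = {var_A:.3f})"
            )

    @property
    def sd_A(self) -> float:
        if self.noise_A is not None:
            return self.noise_A
        return float(
            np.sqrt(1 - self.a1**2 - self.a2**2 - 2 * self.a1 * self.a2 * self.rho_ses_ga)
        )

    @property
    def sd_threshold(self) -> float:
        if self.threshold_noise is not None:
            return self.threshold_noise
        return float(np.sqrt(1 - self.threshold_loading**2))

    def sd_outcome(self) -> float:
        if self.outcome_noise is not None:
            return self.outcome_noise
        cov_A_ses = self.a1 + self.a2 * self.rho_ses_ga
        cov_A_ga = self.a2 + self.a1 * self.rho_ses_ga
        var = (
            self.b1**2
            + self.b2**2
            + self.ga_direct**2
            + 2 * self.b1 * self.b2 * cov_A_ses
            + 2 * self.b1 * self.ga_direct * cov_A_ga
            + 2 * self.b2 * self.ga_direct * self.rho_ses_ga
        )
        if var > 1:
            raise ValueError("outcome structural variance exceeds 1; reduce b1/b2")
        return float(np.sqrt(1 - var))


@lru_cache(maxsize=128)
def _clip_compensated(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Pre-clip (mu0, sigma0) such that clip(N(mu0, sigma0), lo, hi) has the
    target mean and SD.  Uses the analytic clipped-normal moments."""

    def clipped_moments(mu: float, sigma: float) -> tuple[float, float]:
        a = (lo - mu) / sigma if np.isfinite(lo) else -np.inf
        b = (hi - mu) / sigma if np.isfinite(hi) else np.inf
        Plo = stats.norm.cdf(a)
        Phib = stats.norm.cdf(b)
        M = Phib - Plo
        pa = stats.norm.pdf(a) if np.isfinite(a) else 0.0
        pb = stats.norm.pdf(b) if np.isfinite(b) else 0.0
        tn_mean = mu + sigma * (pa - pb) / M
        apa = a * pa if np.isfinite(a) else 0.0
        bpb = b * pb if np.isfinite(b) else 0.0
        tn_var = sigma**2 * (1 + (apa - bpb) / M - ((pa - pb) / M) ** 2)
        E = tn_mean * M
        E2 = (tn_var + tn_mean**2) * M
        if np.isfinite(lo):
            E += lo * Plo
            E2 += lo**2 * Plo
        if np.isfinite(hi):
            E += hi * (1 - Phib)
            E2 += hi**2 * (1 - Phib)
        return float(E), float(np.sqrt(max(E2 - E**2, 1e-12)))

    def residual(params):
        m, s = clipped_moments(params[0], abs(params[1]))
        return [m - mean, s - sd]

    sol = fsolve(residual, x0=[mean, sd], full_output=False, xtol=1e-10)
    mu0, sigma0 = float(sol[0]), float(abs(sol[1]))
    m, s = clipped_moments(mu0, sigma0)
    if abs(m - mean) > 0.01 * max(abs(mean), 1) or abs(s - sd) > 0.01 * sd:
        # solver failed (extreme targets); fall back to uncompensated
        return mean, sd
    return mu0, sigma0


def _to_scale(z: np.ndarray, var: str, moments: Mapping[str, tuple[float, float]]) -> np.ndarray:
    """Map a z-scored variable to its target moments, clipping at the
    variable's bounds with moment compensation."""
    mean, sd = moments[var]
    lo, hi = VARIABLE_BOUNDS.get(var, (-np.inf, np.inf))
    if np.isfinite(lo) or np.isfinite(hi):
        mu0, sigma0 = _clip_compensated(mean, sd, lo, hi)
        return np.clip(mu0 + sigma0 * z, lo, hi)
    return mean + sd * z


def _draw_latents(params: CohortParams, rng: np.random.Generator) -> dict[str, np.ndarray]:
    n = params.n
    z_ses = rng.standard_normal(n)
    z_ga = params.rho_ses_ga * z_ses + np.sqrt(
        1 - params.rho_ses_ga**2
    ) * rng.standard_normal(n)
    A = params.a1 * z_ses + params.a2 * z_ga + params.sd_A * rng.standard_normal(n)
    return {"z_ses": z_ses, "z_ga": z_ga, "A": A}


def generate_cohort(
    params: CohortParams, seed: int, return_latent: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Draw one synthetic cohort table.

    Deterministic for fixed ``(params, seed)``.  With ``return_latent`` the
    per-child latent draws (z-scored SES, GA, and the auditory latent ``A``)
    are returned alongside the table for end-to-end simulations.
    """
    rng = np.random.default_rng(seed)
    lat = _draw_latents(params, rng)
    z_ses, z_ga, A = lat["z_ses"], lat["z_ga"], lat["A"]
    n = params.n
    lam = params.threshold_loading
    sd_t = params.sd_threshold
    sd_y = params.sd_outcome()

    def satellite(base: np.ndarray, r: float) -> np.ndarray:
        return r * base + np.sqrt(1 - r**2) * rng.standard_normal(n)

    cols: dict[str, np.ndarray] = {}
    cols["age_months"] = _to_scale(rng.standard_normal(n), "age_months", params.moments)
    cols["ses_index"] = _to_scale(z_ses, "ses_index", params.moments)
    cols["maternal_ed_years"] = _to_scale(
        satellite(z_ses, params.r_maternal_ed), "maternal_ed_years", params.moments
    )
    cols["gestational_age_weeks"] = _to_scale(z_ga, "gestational_age_weeks", params.moments)
    cols["birthweight_g"] = _to_scale(
        satellite(z_ga, params.r_birthweight), "birthweight_g", params.moments
    )
    cols["nicu_days"] = _to_scale(satellite(z_ga, params.r_nicu), "nicu_days", params.moments)
    for t in THRESHOLD_VARS:
        z_t = -lam * A + sd_t * rng.standard_normal(n)
        cols[t] = _to_scale(z_t, t, params.moments)
    for y in OUTCOME_VARS:
        z_y = (
            params.b1 * A
            + params.b2 * z_ses
            + params.ga_direct * z_ga
            + sd_y * rng.standard_normal(n)
        )
        cols[y] = _to_scale(z_y, y, params.moments)

    df = pd.DataFrame(cols)[list(COHORT_COLUMNS)]
    validate_cohort(df)
    return (df, lat) if return_latent else df


# --------------------------------------------- observers from the latent


@dataclass(frozen=True)
class ObserverMapping:
    """Monotone map from the auditory latent to per-child staircase
    observers: a child one SD better on ``A`` has a psychometric midpoint
    ``gain_dB`` easier (more negative temporal depth / shallower ripple)."""

    pop_midpoint_dB: Mapping[str, float] = field(
        default_factory=lambda: {"temporal8": -16.0, "temporal64": -14.0, "spectral": 16.0}
    )
    gain_dB: Mapping[str, float] = field(
        default_factory=lambda: {"temporal8": 5.0, "temporal64": 5.0, "spectral": 7.0}
    )
    slope: float = 0.6
    lapse: float = 0.02


def observer_from_latent(
    A: float, task: str, mapping: ObserverMapping | None = None
) -> ObserverParams:
    """Deterministic observer for one child: midpoint decreases (gets
    easier) linearly in the latent ``A``."""
    mapping = mapping or ObserverMapping()
    if task not in mapping.pop_midpoint_dB:
        raise ValueError(f"unknown task {task!r}")
    midpoint = mapping.pop_midpoint_dB[task] - mapping.gain_dB[task] * A
    return ObserverParams(midpoint_dB=midpoint, slope=mapping.slope, lapse=mapping.lapse)


def simulate_study(
    n_children: int,
    seed: int,
    tasks: tuple[str, ...] = ("temporal8", "temporal64", "spectral"),
    mapping: ObserverMapping | None = None,
    cohort_params: CohortParams | None = None,
    run_practice_gate: bool = False,
) -> pd.DataFrame:
    """End-to-end pipeline: latent cohort → observers → two staircase runs
    per task → measured thresholds.

    Returns one row per child with the latent ``A``, and per task the
    measured (mean-of-two-runs) threshold and the observer's true
    70.71%-correct point.  The practice gate is off by default so every
    simulated child yields a measured threshold.
    """
    from .observers import psychometric_inverse

    params = replace(cohort_params or CohortParams(), n=n_children)
    rng = np.random.default_rng(seed)
    lat = _draw_latents(params, rng)
    mapping = mapping or ObserverMapping()
    rows = []
    for i in range(n_children):
        row: dict[str, float] = {"A": float(lat["A"][i])}
        for task in tasks:
            obs = observer_from_latent(lat["A"][i], task, mapping)
            cfg = TrackConfig.preset(task)
            st, _ = measure_task(obs, cfg, rng, run_practice_gate=run_practice_gate)
            row[f"{task}_measured_dB"] = st.mean_dB
            # the 2-down/1-up rule converges where P(correct) = sqrt(1/2)
            row[f"{task}_true_dB"] = psychometric_inverse(obs, 0.5**0.5)
        rows.append(row)
    return pd.DataFrame(rows)


def read_cohort_csv(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    validate_cohort(df).to_csv(path, index=False)
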