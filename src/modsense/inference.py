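"""Cohort-level statistical analysis.

This module carries the inference stage of the pipeline: Pearson
correlation tables between auditory thresholds and language outcomes,
forward stepwise regression to isolate the unique contribution of each
threshold, partial correlations used as a mediation-style probe (does a
demographic risk factor still explain language variance once auditory
function is controlled, and vice versa?), and a subject-resampling
bootstrap test for the difference between two dependent correlations
(the same auditory variable correlated with two different outcomes).

The unit of analysis is a cohort table: one row per child with
demographics (age, a two-factor socioeconomic index, maternal education,
gestational age, birthweight, NICU days), the three modulation-detection
thresholds, and four language scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COHORT_COLUMNS",
    "THRESHOLD_VARS",
    "OUTCOME_VARS",
    "ses_index",
    "validate_cohort",
    "pearson",
    "p_stars",
    "correlation_table",
    "StepwiseResult",
    "stepwise_forward",
    "PartialCorr",
    "partial_correlation",
    "partial_correlation_recursive",
    "CorrDiffTest",
    "corr_diff_boot",
    "StudyReport",
    "analyze_cohort",
]

#: Required columns of a cohort table, one row per child.
COHORT_COLUMNS = (
    "age_months",
    "ses_index",
    "maternal_ed_years",
    "gestational_age_weeks",
    "birthweight_g",
    "nicu_days",
    "temporal8_dB",
    "temporal64_dB",
    "spectral_dB",
    "vocab_raw",
    "aud_comp_raw",
    "icc_pct",
    "rhyme_pct",
)
THRESHOLD_VARS = ("temporal8_dB", "temporal64_dB", "spectral_dB")
OUTCOME_VARS = ("vocab_raw", "aud_comp_raw", "icc_pct", "rhyme_pct")
LEXICOSYNTACTIC = ("vocab_raw", "aud_comp_raw")
PHONOLOGICAL = ("icc_pct", "rhyme_pct")


def ses_index(education_scale: int, occupation_scale: int) -> int:
    """Two-factor socioeconomic index: education (1–8) × occupation (1–8).

    The product ranges 1–64, low to high, following the Hollingshead-style
    two-factor construction with an updated occupation list.
    """
    for name, v in (("education", education_scale), ("occupation", occupation_scale)):
        if not 1 <= v <= 8:
            raise ValueError(f"{name} scale must be in 1..8, got {v}")
    return int(education_scale) * int(occupation_scale)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort table against the schema; returns the frame."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"cohort table missing columns: {missing}")
    sub = df[list(COHORT_COLUMNS)]
    if sub.isna().any().any():
        raise ValueError("cohort analysis columns contain missing values")
    if ((df["ses_index"] < 1) | (df["ses_index"] > 64)).any():
        raise ValueError("ses_index out of [1, 64]")
    for c in ("icc_pct", "rhyme_pct"):
        if ((df[c] < 0) | (df[c] > 100)).any():
            raise ValueError(f"{c} out of [0, 100]")
    if (df["temporal8_dB"] > 0).any() or (df["temporal64_dB"] > 0).any():
        raise ValueError("temporal thresholds must be <= 0 dB")
    if (df["spectral_dB"] < 0).any():
        raise ValueError("spectral thresholds must be >= 0 dB")
    return df


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p (t reference)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def p_stars(p: float) -> str:
    """Significance stars at .05 / .01 / .001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_table(
    cohort: pd.DataFrame, rows: Sequence[str], cols: Sequence[str]
) -> pd.DataFrame:
    """Cell-wise Pearson table; each cell is a dict {r, p, stars}."""
    validate_names(cohort, list(rows) + list(cols))

    def cell(a: str, b: str) -> dict:
        if a == b:
            return {"r": 1.0, "p": 0.0, "stars": "***"}
        r, p = pearson(cohort[a].to_numpy(), cohort[b].to_numpy())
        return {"r": r, "p": p, "stars": p_stars(p)}

    data = [[cell(a, b) for b in cols] for a in rows]
    return pd.DataFrame(data, index=list(rows), columns=list(cols), dtype=object)


def validate_names(cohort: pd.DataFrame, names: Sequence[str]) -> None:
    unknown = [n for n in names if n not in cohort.columns]
    if unknown:
        raise KeyError(f"unknown cohort variables: {unknown}")


# ---------------------------------------------------------------- stepwise


@dataclass(frozen=True)
class StepwiseStep:
    entered: str
    betas: dict[str, float]  # standardized coefficients of retained predictors
    p_values: dict[str, float]
    r2: float


@dataclass(frozen=True)
class StepwiseResult:
    outcome: str
    steps: tuple[StepwiseStep, ...]

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(self.steps[-1].betas.keys()) if self.steps else ()

    @property
    def r2(self) -> float:
        return self.steps[-1].r2 if self.steps else 0.0


def _ols_zscored(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS on z-scored variables: returns (betas, p_values, R^2)."""
    import statsmodels.api as sm

    zy = (y - y.mean()) / y.std(ddof=1)
    zX = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    model = sm.OLS(zy, sm.add_constant(zX)).fit()
    return model.params[1:], model.pvalues[1:], float(model.rsquared)


def stepwise_forward(
    y: np.ndarray,
    X: Mapping[str, np.ndarray],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    outcome_name: str = "y",
) -> StepwiseResult:
    """Forward stepwise regression with backward re-checking.

    At each step the candidate with the smallest entry p below ``p_enter``
    joins the model (entry p from its t test in the model including the
    already-retained predictors); retained predictors whose p rises above
    ``p_remove`` are dropped.  Coefficients are standardized (computed on
    z-scored variables) and cumulative R² is reported per step.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.keys())
    mat = {k: np.asarray(v, dtype=float) for k, v in X.items()}
    n = len(y)
    if n <= len(names) + 2:
        raise ValueError("too few observations for stepwise selection")

    retained: list[str] = []
    steps: list[StepwiseStep] = []
    while True:
        candidates = [v for v in names if v not in retained]
        best_name, best_p = None, np.inf
        for cand in candidates:
            cols = retained + [cand]
            betas, ps, _ = _ols_zscored(y, np.column_stack([mat[c] for c in cols]))
            if ps[-1] < best_p:
                best_name, best_p = cand, float(ps[-1])
        if best_name is None or best_p >= p_enter:
            break
        retained.append(best_name)
        # backward removal pass
        while len(retained) > 1:
            betas, ps, _ = _ols_zscored(y, np.column_stack([mat[c] for c in retained]))
            worst = int(np.argmax(ps))
            if ps[worst] > p_remove and retained[worst] != best_name:
                retained.pop(worst)
            else:
                break
        betas, ps, r2 = _ols_zscored(y, np.column_stack([mat[c] for c in retained]))
        steps.append(
            StepwiseStep(
                entered=best_name,
                betas={c: float(b) for c, b in zip(retained, betas)},
                p_values={c: float(p) for c, p in zip(retained, ps)},
                r2=r2,
            )
        )
    return StepwiseResult(outcome=outcome_name, steps=tuple(steps))


# ---------------------------------------------------- partial correlation


@dataclass(frozen=True)
class PartialCorr:
    r_partial: float
    df: int
    p: float


def partial_correlation(
    y: np.ndarray, x: np.ndarray, controls: Mapping[str, np.ndarray] | np.ndarray
) -> PartialCorr:
    """Partial correlation of ``x`` and ``y`` given a set of controls.

    Computed as the correlation between the least-squares residuals of
    ``y`` and of ``x`` after regression on the controls (plus intercept).
    Degrees of freedom are ``n - 2 - k`` for ``k`` controls; the p-value
    uses the t reference ``t = r * sqrt(df / (1 - r^2))``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if isinstance(controls, Mapping):
        Z = (
            np.column_stack([np.asarray(v, float) for v in controls.values()])
            if controls
            else np.empty((len(y), 0))
        )
    else:
        Z = np.asarray(controls, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    n, k = len(y), Z.shape[1]
    if n <= 2 + k:
        raise ValueError("need n > 2 + number of controls")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient (collinear) controls")
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    ry = y - design @ coef_y
    rx = x - design @ coef_x
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    if abs(r) >= 1.0:
        return PartialCorr(r, df, 0.0)
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorr(r, df, p)


def partial_correlation_recursive(
    y: np.ndarray, x: np.ndarray, controls: Sequence[np.ndarray]
) -> float:
    """Closed-form recursive partial correlation (independent route).

    For one control z:  r_xy.z = (r_xy − r_xz·r_yz) / sqrt((1−r_xz²)(1−r_yz²));
    more controls peel off one at a time by recursion.  Used as the oracle
    against the residual-regression implementation.
    """
    controls = list(controls)
    if not controls:
        return float(stats.pearsonr(x, y)[0])
    z = controls[-1]
    rest = controls[:-1]
    r_xy = partial_correlation_recursive(y, x, rest)
    r_xz = partial_correlation_recursive(z, x, rest)
    r_yz = partial_correlation_recursive(z, y, rest)
    return float((r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2)))


# ------------------------------------------------------------- bootstrap


@dataclass(frozen=True)
class CorrDiffTest:
    """Bootstrap comparison of two dependent correlations r(x,y1) vs r(x,y2)."""

    r1: float
    r2: float
    statistic: float  # (r1 - r2) / se_boot on the original sample
    se_boot: float
    p: float  # one-sided bootstrap tail (replicate difference on the null side of 0)
    p_two_sided: float
    p_normal: float  # one-sided normal reference for the statistic
    n_boot: int
    n_discarded: int
    seed: int


def _rowwise_r(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r per row of two equally-shaped 2-D arrays."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def corr_diff_boot(
    cohort: pd.DataFrame,
    x: str,
    y1: str,
    y2: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> CorrDiffTest:
    """Test whether r(x, y1) differs from r(x, y2) on the same subjects.

    Whole subjects (rows) are resampled with replacement, preserving the
    dependence among the outcomes; ``se_boot`` is the SD over replicates of
    the correlation difference, and the statistic is the original-sample
    difference divided by that SE.  The primary p is the one-sided bootstrap
    tail probability that a replicate difference falls on the null side of
    zero; a two-sided version and the one-sided normal reference are also
    reported.  Degenerate (zero-variance) resamples are discarded; more
    than 5% discarded is an error.
    """
    if n_boot < 500:
        raise ValueError("n_boot must be >= 500")
    validate_names(cohort, [x, y1, y2])
    xv = cohort[x].to_numpy(dtype=float)
    y1v = cohort[y1].to_numpy(dtype=float)
    y2v = cohort[y2].to_numpy(dtype=float)
    n = len(xv)
    r1, _ = pearson(xv, y1v)
    r2, _ = pearson(xv, y2v)
    d_obs = r1 - r2

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    bx, b1, b2 = xv[idx], y1v[idx], y2v[idx]
    rr1 = _rowwise_r(bx, b1)
    rr2 = _rowwise_r(bx, b2)
    d = rr1 - rr2
    ok = np.isfinite(d)
    n_discarded = int(n_boot - ok.sum())
    if n_discarded > 0.05 * n_boot:
        raise ValueError(f"{n_discarded}/{n_boot} degenerate bootstrap resamples")
    d = d[ok]
    se = float(np.std(d, ddof=1))
    # the fully degenerate null (y1 == y2): every replicate difference is 0
    statistic = d_obs / se if se > 0 else 0.0
    if d_obs > 0:
        p_one = float(np.mean(d <= 0))
    elif d_obs < 0:
        p_one = float(np.mean(d >= 0))
    else:
        p_one = 0.5
    p_two = min(1.0, 2.0 * p_one)
    p_normal = float(stats.norm.sf(abs(statistic)))
    return CorrDiffTest(
        r1=r1,
        r2=r2,
        statistic=float(statistic),
        se_boot=se,
        p=p_one,
        p_two_sided=p_two,
        p_normal=p_normal,
        n_boot=n_boot,
        n_discarded=n_discarded,
        seed=seed,
    )


# ----------------------------------------------------------------- driver


@dataclass
class StudyReport:
    """The six table shapes of the analysis stage.

    * ``modulation_language_corr`` — thresholds × language outcomes (r/p/stars)
    * ``stepwise`` — per outcome, forward-stepwise selection among thresholds
    * ``corr_diffs`` — per threshold, bootstrap comparisons of its correlation
      with each lexicosyntactic vs each phonological outcome
    * ``risk_factor_corr`` — SES and gestational age × outcomes + thresholds
    * ``ses_partials`` / ``ga_partials`` — mediation-style partial
      correlations, controls chosen from the stepwise winners
    """

    modulation_language_corr: pd.DataFrame
    stepwise: dict[str, StepwiseResult]
    corr_diffs: dict[tuple[str, str, str], CorrDiffTest]
    risk_factor_corr: pd.DataFrame
    ses_partials: dict[str, dict[str, PartialCorr]]
    ga_partials: dict[str, dict[str, PartialCorr]]


def _risk_partials(
    cohort: pd.DataFrame, risk: str, stepwise: dict[str, StepwiseResult]
) -> dict[str, dict[str, PartialCorr]]:
    """Partials of a risk factor vs each outcome controlling the outcome's
    stepwise-selected thresholds, and of each selected threshold controlling
    the risk factor."""
    out: dict[str, dict[str, PartialCorr]] = {}
    for outcome in OUTCOME_VARS:
        selected = list(stepwise[outcome].selected) or list(THRESHOLD_VARS)
        cell: dict[str, PartialCorr] = {}
        cell[risk] = partial_correlation(
            cohort[outcome].to_numpy(),
            cohort[risk].to_numpy(),
            {t: cohort[t].to_numpy() for t in selected},
        )
        for t in selected:
            cell[t] = partial_correlation(
                cohort[outcome].to_numpy(),
                cohort[t].to_numpy(),
                {risk: cohort[risk].to_numpy()},
            )
        out[outcome] = cell
    return out


def analyze_cohort(cohort: pd.DataFrame, n_boot: int = 2000, seed: int = 0) -> StudyReport:
    """Run the full inference stage on a cohort table.

    The choice of which thresholds to control in the partial-correlation
    tables follows the stepwise winners for each outcome (falling back to
    all three thresholds if stepwise selects none).
    """
    validate_cohort(cohort)
    mod_lang = correlation_table(cohort, THRESHOLD_VARS, OUTCOME_VARS)

    stepwise = {
        outcome: stepwise_forward(
            cohort[outcome].to_numpy(),
            {t: cohort[t].to_numpy() for t in THRESHOLD_VARS},
            outcome_name=outcome,
        )
        for outcome in OUTCOME_VARS
    }

    corr_diffs: dict[tuple[str, str, str], CorrDiffTest] = {}
    for i, t in enumerate(THRESHOLD_VARS):
        for j, (lex, phon) in enumerate(
            (a, b) for a in LEXICOSYNTACTIC for b in PHONOLOGICAL
        ):
            corr_diffs[(t, lex, phon)] = corr_diff_boot(
                cohort, t, lex, phon, n_boot=n_boot, seed=seed + 1000 * i + j
            )

    risk = correlation_table(
        cohort, ("ses_index", "gestational_age_weeks"), OUTCOME_VARS + THRESHOLD_VARS
    )
    ses_partials = _risk_partials(cohort, "ses_index", stepwise)
    ga_partials = _risk_partials(cohort, "gestational_age_weeks", stepwise)
    return StudyReport(
        modulation_language_corr=mod_lang,
        stepwise=stepwise,
        corr_diffs=corr_diffs,
        risk_factor_corr=risk,
        ses_partials=ses_partials,
        ga_partials=ga_partials,
    )


def report_to_markdown(report: StudyReport) -> str:
    """Render a StudyReport as Markdown tables."""
    lines: list[str] = []

    def corr_md(title: str, tab: pd.DataFrame) -> None:
        lines.append(f"## {title}\n")
        lines.append("| | " + " | ".join(tab.columns) + " |")
        lines.append("|" + "---|" * (len(tab.columns) + 1))
        for r in tab.index:
            cells = [
                f"{tab.loc[r, c]['r']:+.3f}{tab.loc[r, c]['stars']}" for c in tab.columns
            ]
            lines.append(f"| {r} | " + " | ".join(cells) + " |")
        lines.append("")

    corr_md("Modulation detection vs language outcomes", report.modulation_language_corr)
    lines.append("## Stepwise regression (candidates: the three thresholds)\n")
    for outcome, res in report.stepwise.items():
        lines.append(f"**{outcome}**")
        for k, step in enumerate(res.steps, 1):
            betas = ", ".join(
                f"{v} β={b:+.3f} (p={res.steps[k-1].p_values[v]:.3g})"
                for v, b in step.betas.items()
            )
            lines.append(f"- step {k}: entered {step.entered}; {betas}; R²={step.r2:.3f}")
        if not res.steps:
            lines.append("- no predictor entered")
        lines.append("")
    lines.append("## Dependent-correlation comparisons (bootstrap)\n")
    lines.append("| threshold | lexicosyntactic | phonological | statistic | p (one-sided) |")
    lines.append("|---|---|---|---|---|")
    for (t, lex, phon), res in report.corr_diffs.items():
        lines.append(f"| {t} | {lex} | {phon} | {res.statistic:+.2f} | {res.p:.3f} |")
    lines.append("")
    corr_md("Risk factors vs outcomes and thresholds", report.risk_factor_corr)
    for title, partials in (
        ("SES partial correlations", report.ses_partials),
        ("Gestational-age partial correlations", report.ga_partials),
    ):
        lines.append(f"## {title}\n")
        for outcome, cell in partials.items():
            parts = ", ".join(
                f"{v}: r={pc.r_partial:+.3f}{p_stars(pc.p)} (df={pc.df})"
                for v, pc in cell.items()
            )
            lines.append(f"- {outcome}: {parts}")
        lines.append("")
    return "\n".join(lines)
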