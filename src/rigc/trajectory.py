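"""Developmental-trajectory fitting and modulating-factor models.

The lifespan trajectory of a score is summarized by a cubic smoothing
spline of the score on age at a fixed number of equivalent degrees of
freedom (default df = 7), with 95% confidence bands from a case-resampling
bootstrap and the peak age read off a 0.5-year grid.  Following the
classic smooth.spline convention, observations are collapsed to unique
ages (integer years) with counts as weights; the penalty is calibrated so
that the trace of the smoother matrix equals the requested df.

Modulating factors (sex, education, field of education, paranormal belief)
are assessed with general linear models that include centered age and
age-squared terms, reporting Type II sums of squares, p-values and partial
eta-squared (SS_term / (SS_term + SS_residual)) per term.  Internal
consistency across tasks uses Cronbach's alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import make_smoothing_spline

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TrajectoryFit",
    "GLMResult",
    "TermEffect",
    "ReliabilityResult",
    "fit_trajectory",
    "speed_accuracy_path",
    "fit_glm",
    "reliability_alpha",
    "age_window_correlation",
]

AGE_LO, AGE_HI, AGE_STEP = 4.0, 91.0, 0.5


@dataclass
class TrajectoryFit:
    variable: str
    spline_df: float
    lam: float
    age_grid: np.ndarray
    fitted: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    peak_age: float  # NaN when no unique peak exists
    no_unique_peak: bool
    bootstrap_reps: int
    seed: int | None

    def at(self, age: float) -> float:
        return float(np.interp(age, self.age_grid, self.fitted))


def _collapse(ages: np.ndarray, values: np.ndarray):
    """Unique sorted ages with per-age means and counts (spline weights)."""
    xs, inv = np.unique(ages, return_inverse=True)
    sums = np.bincount(inv, weights=values)
    counts = np.bincount(inv).astype(float)
    return xs.astype(float), sums / counts, counts


def _edf(xs: np.ndarray, ws: np.ndarray, lam: float) -> float:
    """Trace of the smoother matrix: fit each unit vector, read the diagonal."""
    tr = 0.0
    for j in range(len(xs)):
        e = np.zeros(len(xs))
        e[j] = 1.0
        tr += float(make_smoothing_spline(xs, e, w=ws, lam=lam)(xs[j]))
    return tr


def _lambda_for_df(xs: np.ndarray, ws: np.ndarray, df: float) -> float | None:
    """Penalty whose equivalent degrees of freedom match ``df`` (bisection).

    Returns ``None`` when the requested df is at the linear limit (edf -> 2
    as the penalty grows): the caller then uses the exact weighted
    least-squares line, which is what the spline converges to but free of
    the conditioning loss of an enormous penalty.
    """
    lo, hi = -10.0, 8.0  # log10 lambda bracket
    if _edf(xs, ws, 10.0**lo) < df:  # df above what the data support
        return 10.0**lo
    if _edf(xs, ws, 10.0**hi) > df:  # df at/below the linear limit of 2
        return None
    f = lambda log_lam: _edf(xs, ws, 10.0**log_lam) - df
    return 10.0 ** optimize.brentq(f, lo, hi, xtol=1e-4)


def _smoother(xs, ys, ws, lam):
    if lam is None:
        coef = np.polyfit(xs, ys, 1, w=np.sqrt(ws))
        return lambda grid: np.polyval(coef, grid)
    return make_smoothing_spline(xs, ys, w=ws, lam=lam)


def fit_trajectory(
    scores: pd.DataFrame,
    variable: str,
    spline_df: float = 7,
    bootstrap_reps: int = 500,
    seed: int | None = None,
    age_col: str = "age",
) -> TrajectoryFit:
    """Smoothing-spline trajectory of ``variable`` on age with 95% bands.

    Requires >= 30 complete cases spanning >= 20 distinct ages and
    ``spline_df >= 3`` (df = 2 is the linear limit and is honored too).
    Bands are percentile bootstrap over participants, refit at the penalty
    calibrated on the full data.  The peak age is the grid argmax; a flat
    fit yields ``peak_age = NaN`` and ``no_unique_peak = True``.
    """
    data = scores[[age_col, variable]].dropna()
    ages = data[age_col].to_numpy(dtype=float)
    vals = data[variable].to_numpy(dtype=float)
    if len(ages) < 30 or len(np.unique(ages)) < 20:
        raise ValueError(
            f"insufficient age spread: {len(ages)} cases over "
            f"{len(np.unique(ages))} distinct ages (need >=30 over >=20)"
        )
    xs, ys, ws = _collapse(ages, vals)
    lam = _lambda_for_df(xs, ws, spline_df)
    grid = np.arange(max(AGE_LO, xs[0]), min(AGE_HI, xs[-1]) + 1e-9, AGE_STEP)
    fitted = _smoother(xs, ys, ws, lam)(grid)

    rng = np.random.default_rng(seed)
    boot = np.empty((bootstrap_reps, len(grid)))
    n = len(ages)
    for b in range(bootstrap_reps):
        idx = rng.integers(0, n, size=n)
        bx, by, bw = _collapse(ages[idx], vals[idx])
        boot[b] = _smoother(bx, by, bw, lam)(grid)
    if bootstrap_reps > 0:
        lo_band = np.quantile(boot, 0.025, axis=0)
        hi_band = np.quantile(boot, 0.975, axis=0)
        lo_band, hi_band = np.minimum(lo_band, fitted), np.maximum(hi_band, fitted)
    else:
        lo_band = hi_band = fitted.copy()

    flat = np.ptp(fitted) < 1e-9
    return TrajectoryFit(
        variable=variable,
        spline_df=spline_df,
        lam=lam,
        age_grid=grid,
        fitted=fitted,
        ci_lower=lo_band,
        ci_upper=hi_band,
        peak_age=float("nan") if flat else float(grid[int(np.argmax(fitted))]),
        no_unique_peak=bool(flat),
        bootstrap_reps=bootstrap_reps,
        seed=seed,
    )


def speed_accuracy_path(ct_fit: TrajectoryFit, z_fit: TrajectoryFit) -> pd.DataFrame:
    """The developmental (CT, complexity) path, parametrized by age."""
    if len(ct_fit.age_grid) != len(z_fit.age_grid) or not np.allclose(
        ct_fit.age_grid, z_fit.age_grid
    ):
        raise ValueError("trajectory fits are on different age grids")
    return pd.DataFrame(
        {"age": ct_fit.age_grid, "ct": ct_fit.fitted, "z": z_fit.fitted}
    )


@dataclass(frozen=True)
class TermEffect:
    name: str
    coefficient: float  # NaN for multi-coefficient categorical terms
    p_value: float
    partial_eta_sq: float


@dataclass
class GLMResult:
    dv: str
    terms: list[TermEffect]
    n_used: int
    formula: str
    holm_adjusted: dict = field(default_factory=dict)

    def term(self, name: str) -> TermEffect:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


_IV_PATSY = {
    "age": "age_c + age_c2",
    "age_quadratic_only": "age_c2",
    "sex": "C(sex)",
    "education": "education",
    "field": "C(field)",
    "paranormal_belief": "paranormal_belief",
}


def fit_glm(
    scores: pd.DataFrame,
    dv: str,
    ivs: tuple[str, ...] = ("age", "sex", "education", "field", "paranormal_belief"),
    quadratic_age_only: bool = False,
) -> GLMResult:
    """General linear model of ``dv`` with Type II effect sizes per term.

    Age enters as centered linear + quadratic terms (or quadratic only with
    ``quadratic_age_only``).  When field or paranormal belief is among the
    IVs the analysis is restricted to participants above age 15 (younger
    participants have no differentiated education field or stable belief).
    """
    cols = [dv] + [c for c in ivs if c != "age"] + (["age"] if "age" in ivs else [])
    data = scores[list(dict.fromkeys(cols))].copy()
    if "field" in ivs or "paranormal_belief" in ivs:
        data = data[scores["age"] > 15]
    if "field" in data.columns:
        data = data[data["field"].astype(str) != ""]
    data = data.dropna()
    if "age" in ivs:
        age_c = data["age"] - data["age"].mean()
        data["age_c"] = age_c
        data["age_c2"] = age_c**2
    rhs_parts = []
    for iv in ivs:
        if iv == "age":
            rhs_parts.append(_IV_PATSY["age_quadratic_only" if quadratic_age_only else "age"])
        else:
            rhs_parts.append(_IV_PATSY.get(iv, iv))
    formula = f"{dv} ~ " + " + ".join(rhs_parts)

    n_terms = sum(p.count("+") + 1 for p in rhs_parts)
    if len(data) < 10 * (n_terms + 1):
        raise ValueError(
            f"only {len(data)} complete cases for {n_terms + 1} model terms "
            "(need >= 10 per term)"
        )
    model = smf.ols(formula, data=data)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, r = np.linalg.qr(exog)
        aliased = [
            model.exog_names[j]
            for j in range(exog.shape[1])
            if abs(r[j, j]) < 1e-8 * abs(r[0, 0])
        ]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    fit = model.fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    ss_resid = float(anova.loc["Residual", "sum_sq"])
    terms = []
    for name in anova.index:
        if name == "Residual":
            continue
        ss = float(anova.loc[name, "sum_sq"])
        coef = float(fit.params[name]) if name in fit.params.index else float("nan")
        terms.append(
            TermEffect(
                name=name,
                coefficient=coef,
                p_value=float(anova.loc[name, "PR(>F)"]),
                partial_eta_sq=ss / (ss + ss_resid),
            )
        )
    pvals = np.array([t.p_value for t in terms])
    order = np.argsort(pvals)
    holm = np.empty_like(pvals)
    running = 0.0
    for rank_i, j in enumerate(order):
        running = max(running, pvals[j] * (len(pvals) - rank_i))
        holm[j] = min(1.0, running)
    return GLMResult(
        dv=dv,
        terms=terms,
        n_used=len(data),
        formula=formula,
        holm_adjusted={t.name: float(h) for t, h in zip(terms, holm)},
    )


@dataclass(frozen=True)
class ReliabilityResult:
    variables: tuple[str, ...]
    alpha: float
    n_complete_cases: int


def reliability_alpha(scores: pd.DataFrame, variables) -> ReliabilityResult:
    """Cronbach's alpha over a set of columns (complete cases only).

    alpha = k/(k-1) * (1 - sum of item variances / variance of the sum).
    """
    variables = tuple(variables)
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    data = scores[list(variables)].dropna()
    if len(data) < 3:
        raise ValueError("need at least three complete cases")
    k = len(variables)
    item_var = data.var(axis=0, ddof=1)
    total_var = data.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total variance")
    alpha = k / (k - 1) * (1.0 - item_var.sum() / total_var)
    return ReliabilityResult(variables, float(alpha), len(data))


def age_window_correlation(
    scores: pd.DataFrame,
    variable_pair: tuple[str, str],
    age_range: tuple[float, float],
    age_col: str = "age",
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between two scores within an age window."""
    a, b = variable_pair
    lo, hi = age_range
    data = scores[(scores[age_col] >= lo) & (scores[age_col] <= hi)][[a, b]].dropna()
    if len(data) < 10:
        raise ValueError(f"only {len(data)} cases in age window [{lo}, {hi}] (need >= 10)")
    if data[a].std() == 0 or data[b].std() == 0:
        raise ValueError("degenerate variance in the age window")
    r, p = stats.pearsonr(data[a], data[b])
    return float(r), float(p)
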