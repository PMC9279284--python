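"""Regression models, group comparisons and auxiliary statistics.

Three regressions drive the analysis:

* a linear temperature model for burial in natural-biome lakes,
  ``burial = β₁·T + β₀`` (OLS);
* a second-order polynomial for forest OC accumulation vs temperature (OLS);
* an exponential forest-cover model for Amazon floodplain lakes,
  ``burial = a·exp(b·forest%)``, fitted by nonlinear least squares so the
  coefficient standard errors refer to the original scale; the log-linear
  OLS fit only supplies the starting values.

Group comparisons run one-way ANOVA with a Tukey HSD post-test on
natural-log burial rates, summarised as a compact letter display (groups
sharing a letter are not significantly different), alongside
Kruskal–Wallis, Kolmogorov–Smirnov normality and Bartlett
variance-homogeneity diagnostics.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "FitResult",
    "GroupComparison",
    "fit_linear",
    "fit_quadratic",
    "fit_temperature_models",
    "fit_forest_exponential",
    "group_comparison",
    "compact_letters",
    "select_buffer",
    "variance_curve",
]


@dataclass
class FitResult:
    """A fitted model with coefficient uncertainties.

    ``params``/``se`` are keyed by coefficient name; for the exponential
    model the keys are ``a`` and ``b`` of y = a·e^(b·x), for polynomials
    ``intercept``, ``x``, ``x2``.
    """

    model: str  # linear | quadratic | exponential
    params: dict[str, float]
    se: dict[str, float]
    r_squared: float
    p_value: float
    n: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.model == "linear":
            return p["intercept"] + p["x"] * x
        if self.model == "quadratic":
            return p["intercept"] + p["x"] * x + p["x2"] * x**2
        if self.model == "exponential":
            return p["a"] * np.exp(p["b"] * x)
        raise ValueError(f"unknown model {self.model!r}")

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """t-based (n − k df) two-sided confidence intervals per coefficient."""
        k = len(self.params)
        tcrit = sps.t.ppf(1 - alpha / 2, self.n - k)
        return {
            name: (v - tcrit * self.se[name], v + tcrit * self.se[name])
            for name, v in self.params.items()
        }


def _ols(x: np.ndarray, y: np.ndarray, degree: int) -> FitResult:
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must align")
    if x.size < degree + 2:
        raise ValueError(f"need >= {degree + 2} points for degree {degree}")
    cols = [np.ones_like(x)] + [x**d for d in range(1, degree + 1)]
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is collinear")
    res = sm.OLS(y, X).fit()
    names = ["intercept", "x", "x2"][: degree + 1]
    r2 = float(res.rsquared)
    return FitResult(
        model="linear" if degree == 1 else "quadratic",
        params=dict(zip(names, res.params)),
        se=dict(zip(names, res.bse)),
        r_squared=r2 if np.isfinite(r2) else 0.0,
        p_value=float(res.f_pvalue) if np.isfinite(res.f_pvalue) else float("nan"),
        n=int(x.size),
    )


def fit_linear(x, y) -> FitResult:
    """OLS line y = β₀ + β₁x."""
    return _ols(np.asarray(x), np.asarray(y), degree=1)


def fit_quadratic(x, y) -> FitResult:
    """OLS parabola y = β₀ + β₁x + β₂x²."""
    return _ols(np.asarray(x), np.asarray(y), degree=2)


def fit_temperature_models(
    natural_lakes: pd.DataFrame | None = None,
    forest_table: pd.DataFrame | None = None,
) -> tuple[FitResult | None, FitResult | None]:
    """Fit the two temperature responses on untransformed rates.

    ``natural_lakes``: (annual_temp, burial) per natural-biome lake → linear
    model.  ``forest_table``: (annual_temp, oc_accumulation) per forest
    region → quadratic model.  Either may be None.
    """
    lake_fit = forest_fit = None
    if natural_lakes is not None:
        lake_fit = fit_linear(
            natural_lakes["annual_temp"], natural_lakes["burial"]
        )
    if forest_table is not None:
        forest_fit = fit_quadratic(
            forest_table["annual_temp"], forest_table["oc_accumulation"]
        )
    return lake_fit, forest_fit


def fit_forest_exponential(forest_pct, burial) -> FitResult:
    """Fit burial = a·e^(b·forest%) by nonlinear least squares.

    Initialized from the log-linear OLS fit; standard errors come from the
    NLS covariance, so they refer to the original (not log) scale.
    """
    x = np.asarray(forest_pct, dtype=float)
    y = np.asarray(burial, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if np.any(y <= 0):
        raise ValueError("burial must be > 0 for the exponential model")
    b0, loga = np.polyfit(x, np.log(y), 1)
    p0 = (float(np.exp(loga)), float(b0))

    def f(x, a, b):
        return a * np.exp(b * x)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, pcov = optimize.curve_fit(f, x, y, p0=p0, maxfev=10000)
    resid = y - f(x, *popt)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    dof = x.size - 2
    if dof <= 0 or ss_res <= 1e-12 * max(ss_tot, float(y @ y)):
        se = np.zeros(2)  # interpolating fit: no residual scale
        p_value = 0.0
        r2 = 1.0
    else:
        se = np.sqrt(np.diag(pcov))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        fstat = (ss_tot - ss_res) / (ss_res / dof)
        p_value = float(sps.f.sf(fstat, 1, dof)) if ss_tot > 0 else float("nan")
    return FitResult(
        model="exponential",
        params={"a": float(popt[0]), "b": float(popt[1])},
        se={"a": float(se[0]), "b": float(se[1])},
        r_squared=float(r2),
        p_value=p_value,
        n=int(x.size),
    )


def compact_letters(groups, sig_pairs) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    ``sig_pairs`` lists the pairs declared significantly different; the
    result maps each group to a letter string such that two groups share a
    letter iff they were never declared different.
    """
    groups = list(groups)
    cols: list[set] = [set(groups)]
    for a, b in sig_pairs:
        for col in [c for c in cols if a in c and b in c]:
            cols.remove(col)
            for newcol in (col - {a}, col - {b}):
                if newcol and not any(newcol <= other for other in cols):
                    cols.append(newcol)
        # absorb columns that became subsets
        cols = [c for c in cols if not any(c < o for o in cols if o is not c)]
    alphabet = string.ascii_lowercase
    letters = {g: "" for g in groups}
    # stable letter order: by the first group of each column
    order = {g: i for i, g in enumerate(groups)}
    cols.sort(key=lambda c: min(order[g] for g in c))
    for i, col in enumerate(cols):
        ch = alphabet[i % 26] * (1 + i // 26)
        for g in col:
            letters[g] += ch
    return letters


@dataclass
class GroupComparison:
    """One-way comparison of burial rates across lake classes."""

    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # pairwise table on ln rates
    letters: dict[str, str]  # compact letter display
    kruskal_h: float
    kruskal_p: float
    ks_p: float  # normality of pooled ln-rate residuals
    bartlett_p: float  # variance homogeneity of ln rates
    excluded: tuple[str, ...] = ()


def group_comparison(
    classified_rates: dict[str, np.ndarray],
    alpha: float = 0.05,
    post_hoc: bool = True,
) -> GroupComparison:
    """ANOVA + Tukey on natural-log rates, with nonparametric diagnostics.

    Groups with fewer than 2 observations are excluded with a warning.
    The compact letter display assigns shared letters to groups that Tukey
    does not separate at family-wise ``alpha``.  ``post_hoc=False`` skips
    the Tukey test (its studentized-range quantile dominates the runtime),
    e.g. for simulation studies of the omnibus test alone.
    """
    kept: dict[str, np.ndarray] = {}
    excluded = []
    for label, rates in classified_rates.items():
        r = np.asarray(rates, dtype=float)
        if r.size < 2:
            excluded.append(label)
            continue
        if np.any(r <= 0):
            raise ValueError(f"group {label!r}: rates must be > 0 for log transform")
        kept[label] = np.log(r)
    if excluded:
        warnings.warn(f"groups excluded (n < 2): {excluded}", stacklevel=2)
    if len(kept) < 2:
        raise ValueError("need >= 2 groups with n >= 2")
    labels = list(kept)
    logs = [kept[g] for g in labels]
    f, p = sps.f_oneway(*logs)
    h, kp = sps.kruskal(*logs)
    _, bartlett_p = sps.bartlett(*logs)
    pooled = np.concatenate([v - v.mean() for v in logs])
    sd = pooled.std(ddof=len(labels))
    ks_p = (
        sps.kstest(pooled, sps.norm(loc=0.0, scale=sd).cdf)[1] if sd > 0 else 1.0
    )
    if post_hoc:
        values = np.concatenate(logs)
        group_idx = np.concatenate([[g] * len(kept[g]) for g in labels])
        tk = pairwise_tukeyhsd(values, group_idx, alpha=alpha)
        tukey_df = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
        sig_pairs = [
            (row["group1"], row["group2"])
            for _, row in tukey_df.iterrows()
            if bool(row["reject"])
        ]
        letters = compact_letters(labels, sig_pairs)
    else:
        tukey_df = pd.DataFrame()
        letters = {}
    return GroupComparison(
        anova_f=float(f),
        anova_p=float(p),
        tukey=tukey_df,
        letters=letters,
        kruskal_h=float(h),
        kruskal_p=float(kp),
        ks_p=float(ks_p),
        bartlett_p=float(bartlett_p),
        excluded=tuple(excluded),
    )


def select_buffer(per_buffer_fits: dict[float, FitResult]) -> float:
    """Buffer size whose regression explains the most variance.

    Returns the buffer (km²) with the highest r²; ties go to the smaller
    buffer (the more local covariate).
    """
    if not per_buffer_fits:
        raise ValueError("no buffer fits given")
    return min(
        per_buffer_fits,
        key=lambda b: (-per_buffer_fits[b].r_squared, b),
    )


def variance_curve(
    rates,
    n_grid,
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample variance vs number of measurements randomly subsampled.

    For each n in ``n_grid``, draws ``reps`` subsamples of size n without
    replacement and averages their (ddof=1) variances; used to check that
    the variance has stabilized at the achieved sample size.  Deterministic
    for a given seed.
    """
    rates = np.asarray(rates, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        n = int(n)
        if not 2 <= n <= rates.size:
            raise ValueError(f"subsample size {n} out of range [2, {rates.size}]")
        vs = [
            np.var(rng.choice(rates, size=n, replace=False), ddof=1)
            for _ in range(reps)
        ]
        rows.append({"n": n, "mean_variance": float(np.mean(vs))})
    return pd.DataFrame(rows)
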