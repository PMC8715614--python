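"""Overlapping-subgroup (sliding-window) reliability and slope analysis.

Respondents are binned into many overlapping windows of fixed width on the
standardized intelligence score.  Within each window we compute the mean
intelligence, coefficient omega of the composite's items (from a one-factor
fit on the within-window correlation matrix), and the OLS slope of each
outcome on the composite — with both variables kept on their full-sample
standardized scale, so slopes are comparable across windows.

Window-level meta-regressions then quantify how much of the apparent
"interaction" (the rise of the trait-outcome slope with mean intelligence) is
absorbed by the reliability gradient: the attenuation percent is
100*(1 - b_adjusted/b_unadjusted), where the adjusted model adds omega as a
covariate.  Classical OLS confidence intervals are the default even though
overlapping windows are dependent; a moving-block bootstrap alternative is
available via ``ci_method='bootstrap'`` and is labelled as such in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .psychometrics import SingleFactorModel, coefficient_omega

__all__ = [
    "WindowConfig",
    "make_windows",
    "window_statistics",
    "run_window_analysis",
    "meta_regression",
    "MetaComponent",
    "MetaFit",
    "summarize_meta",
    "attenuation_percent",
    "ci_overlap",
    "extreme_group_omega",
    "tidy_window_summary",
]


@dataclass
class WindowConfig:
    """Grid of overlapping windows on standardized intelligence."""

    width: float = 0.5
    n_windows: int = 901
    center_lo: float = -2.25
    center_hi: float = 2.25
    min_n: int = 50

    def validate(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.n_windows > 1 and self.center_hi <= self.center_lo:
            raise ValueError("center_hi must exceed center_lo")

    @property
    def centers(self) -> np.ndarray:
        if self.n_windows == 1:
            return np.array([(self.center_lo + self.center_hi) / 2.0])
        return np.linspace(self.center_lo, self.center_hi, self.n_windows)


def make_windows(config: WindowConfig) -> pd.DataFrame:
    """Window bounds [lo, hi) for every center of the grid."""
    config.validate()
    centers = config.centers
    half = config.width / 2.0
    return pd.DataFrame({"center": centers, "lo": centers - half, "hi": centers + half})


def _simple_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and SE of y on x (with intercept), complete cases."""
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3 or x[mask].std() == 0:
        return np.nan, np.nan
    res = stats.linregress(x[mask], y[mask])
    return float(res.slope), float(res.stderr)


def window_statistics(lo: float, hi: float, z: np.ndarray, items: np.ndarray,
                      composite: np.ndarray, outcomes: dict[str, np.ndarray],
                      min_n: int = 50) -> dict:
    """Statistics for one window [lo, hi) on standardized intelligence.

    ``items`` is the (already keyed and standardized) member-item matrix used
    for the omega fit; ``composite`` and every outcome stay on their
    full-sample scale (no within-window re-standardization).
    """
    in_win = (z >= lo) & (z < hi)
    n = int(np.count_nonzero(in_win))
    row = {"lo": lo, "hi": hi, "n": n, "mean_iq": np.nan, "omega": np.nan}
    for name in outcomes:
        row[f"slope_{name}"] = np.nan
        row[f"se_{name}"] = np.nan
    row["valid"] = False
    if n == 0:
        return row
    zw = z[in_win]
    row["mean_iq"] = float(zw.mean())
    if n < min_n:
        return row
    Xw = items[in_win]
    complete = np.isfinite(Xw).all(axis=1)
    omega_ok = False
    if complete.sum() >= min_n:
        Xc = Xw[complete]
        sds = Xc.std(axis=0, ddof=1)
        if np.all(sds > 0):
            R = np.corrcoef(Xc, rowvar=False)
            sol = SingleFactorModel.from_correlation(R, n_obs=int(complete.sum()))
            if sol.converged:
                row["omega"] = coefficient_omega(sol)
                omega_ok = True
    cw = composite[in_win]
    for name, y in outcomes.items():
        slope, se = _simple_slope(cw, y[in_win])
        row[f"slope_{name}"] = slope
        row[f"se_{name}"] = se
    row["valid"] = bool(omega_ok and all(np.isfinite(row[f"slope_{o}"]) for o in outcomes))
    return row


def run_window_analysis(z, items, composite, outcomes: dict,
                        config: WindowConfig | None = None) -> pd.DataFrame:
    """Per-window statistics over the whole grid; one row per window.

    Parameters
    ----------
    z : array
        Standardized intelligence scores.
    items : DataFrame or array
        Keyed, standardized member items of the composite (for omega).
    composite : array
        Composite scores on the full-sample scale.
    outcomes : dict name -> array
        Outcome vectors on their full-sample scale.
    """
    if config is None:
        config = WindowConfig()
    config.validate()
    z = np.asarray(z, dtype=float)
    items = np.asarray(items, dtype=float)
    composite = np.asarray(composite, dtype=float)
    outcomes = {k: np.asarray(v, dtype=float) for k, v in outcomes.items()}

    # windows are contiguous ranges after sorting by z, so sort once and slice
    finite = np.isfinite(z)
    order = np.argsort(z[finite], kind="stable")
    zs = z[finite][order]
    items_s = items[finite][order]
    comp_s = composite[finite][order]
    out_s = {k: v[finite][order] for k, v in outcomes.items()}

    bounds = make_windows(config)
    rows = []
    for center, lo, hi in bounds.itertuples(index=False):
        i0, i1 = np.searchsorted(zs, [lo, hi], side="left")
        sl = slice(i0, i1)
        row = window_statistics(
            lo, hi, zs[sl], items_s[sl], comp_s[sl],
            {k: v[sl] for k, v in out_s.items()}, min_n=config.min_n,
        )
        row["center"] = center
        rows.append(row)
    cols = ["center", "lo", "hi", "n", "mean_iq", "omega"]
    cols += [c for c in rows[0] if c.startswith(("slope_", "se_"))]
    cols += ["valid"]
    return pd.DataFrame(rows)[cols]


@dataclass
class MetaComponent:
    """One window-level meta-regression of slope on mean intelligence."""

    outcome: str
    adjusted: bool
    coef_mean_iq: float
    ci_mean_iq: tuple[float, float]
    coef_omega: float | None
    p_mean_iq: float
    n_windows: int
    ci_method: str = "ols"


def meta_regression(results: pd.DataFrame, outcome: str,
                    adjust_for_reliability: bool = False,
                    weights: str | None = "inverse_variance",
                    ci_method: str = "ols", n_boot: int = 2000,
                    block_len: int = 50, seed: int = 0) -> MetaComponent:
    """Window-level regression of slope on mean intelligence (optionally plus omega).

    By default each window is weighted by the inverse squared SE of its slope
    (the standard meta-analytic weighting), which keeps sparse tail windows
    from dominating the fit; ``weights=None`` gives the unweighted OLS
    variant.  ``ci_method='bootstrap'`` replaces the classical CI with a
    moving-block bootstrap over the (ordered, overlapping) windows, which
    respects their serial dependence.
    """
    valid = results[results["valid"]].reset_index(drop=True)
    if len(valid) < 3:
        raise ValueError("need >= 3 valid windows for meta-regression")
    y = valid[f"slope_{outcome}"].to_numpy()
    if weights == "inverse_variance":
        w = 1.0 / valid[f"se_{outcome}"].to_numpy() ** 2
    elif weights is None:
        w = np.ones(len(valid))
    else:
        raise ValueError("weights must be None or 'inverse_variance'")
    cols = [valid["mean_iq"].to_numpy()]
    if adjust_for_reliability:
        cols.append(valid["omega"].to_numpy())
    X = sm.add_constant(np.column_stack(cols))
    res = sm.WLS(y, X, weights=w).fit()
    ci = res.conf_int()
    coef_omega = float(res.params[2]) if adjust_for_reliability else None
    lo, hi = float(ci[1][0]), float(ci[1][1])
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        m = len(valid)
        n_blocks = int(np.ceil(m / block_len))
        coefs = np.empty(n_boot)
        for b in range(n_boot):
            starts = rng.integers(0, max(m - block_len, 1), size=n_blocks)
            idx = np.concatenate([np.arange(s, s + block_len) for s in starts])[:m]
            rb = sm.WLS(y[idx], X[idx], weights=w[idx]).fit()
            coefs[b] = rb.params[1]
        lo, hi = np.percentile(coefs, [2.5, 97.5])
    elif ci_method != "ols":
        raise ValueError("ci_method must be 'ols' or 'bootstrap'")
    return MetaComponent(
        outcome=outcome,
        adjusted=adjust_for_reliability,
        coef_mean_iq=float(res.params[1]),
        ci_mean_iq=(float(lo), float(hi)),
        coef_omega=coef_omega,
        p_mean_iq=float(res.pvalues[1]),
        n_windows=len(valid),
        ci_method=ci_method,
    )


def attenuation_percent(b_unadj: float, b_adj: float) -> float:
    """Share of the unadjusted meta-effect absorbed by the covariate.

    100*(1 - b_adj/b_unadj); may be negative (amplification) or exceed 100
    (sign flip).  Undefined for b_unadj = 0.
    """
    if b_unadj == 0:
        raise ValueError("attenuation undefined for b_unadj = 0")
    return 100.0 * (1.0 - b_adj / b_unadj)


def ci_overlap(ci_a: tuple[float, float], ci_b: tuple[float, float]) -> bool:
    """True iff two closed intervals intersect."""
    (a_lo, a_hi), (b_lo, b_hi) = ci_a, ci_b
    if a_lo > a_hi or b_lo > b_hi:
        raise ValueError("interval lower bound exceeds upper bound")
    return a_lo <= b_hi and b_lo <= a_hi


@dataclass
class MetaFit:
    """Meta-regression summary for one outcome: attenuation by reliability."""

    outcome: str
    unadjusted: MetaComponent
    adjusted: MetaComponent
    omega_on_iq: float          # slope of omega on mean intelligence
    p_omega_on_iq: float
    slope_on_omega: float       # simple regression of slope on omega
    p_slope_on_omega: float
    attenuation_pct: float
    cis_overlap: bool


def summarize_meta(results: pd.DataFrame, outcome: str,
                   weights: str | None = "inverse_variance",
                   ci_method: str = "ols", seed: int = 0) -> MetaFit:
    """Unadjusted and reliability-adjusted meta-regressions plus attenuation."""
    unadj = meta_regression(results, outcome, False, weights=weights,
                            ci_method=ci_method, seed=seed)
    adj = meta_regression(results, outcome, True, weights=weights,
                          ci_method=ci_method, seed=seed)
    valid = results[results["valid"]]
    om = sm.OLS(
        valid["omega"].to_numpy(), sm.add_constant(valid["mean_iq"].to_numpy())
    ).fit()
    so = sm.OLS(
        valid[f"slope_{outcome}"].to_numpy(),
        sm.add_constant(valid["omega"].to_numpy()),
    ).fit()
    return MetaFit(
        outcome=outcome,
        unadjusted=unadj,
        adjusted=adj,
        omega_on_iq=float(om.params[1]),
        p_omega_on_iq=float(om.pvalues[1]),
        slope_on_omega=float(so.params[1]),
        p_slope_on_omega=float(so.pvalues[1]),
        attenuation_pct=attenuation_percent(unadj.coef_mean_iq, adj.coef_mean_iq),
        cis_overlap=ci_overlap(unadj.ci_mean_iq, adj.ci_mean_iq),
    )


def extreme_group_omega(z, items, cut: float = 1.0, min_n: int = 50
                        ) -> tuple[float, float]:
    """Omega of the composite items in the low (z <= -cut) and high (z >= cut) groups."""
    z = np.asarray(z, dtype=float)
    items = np.asarray(items, dtype=float)
    omegas = []
    for mask in (z <= -cut, z >= cut):
        rows = items[mask & np.isfinite(z)]
        rows = rows[np.isfinite(rows).all(axis=1)]
        if len(rows) < min_n:
            raise ValueError("extreme group has fewer than min_n complete cases")
        R = np.corrcoef(rows, rowvar=False)
        sol = SingleFactorModel.from_correlation(R, n_obs=len(rows))
        if not sol.converged:
            raise RuntimeError("one-factor fit failed in extreme group")
        omegas.append(coefficient_omega(sol))
    return omegas[0], omegas[1]


def tidy_window_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Long-format window summary: omega and slopes vs. mean intelligence."""
    valid = results[results["valid"]]
    value_cols = ["omega"] + [c for c in valid.columns if c.startswith("slope_")]
    return valid.melt(
        id_vars=["center", "mean_iq", "n"],
        value_vars=value_cols,
        var_name="statistic",
        value_name="value",
    )
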