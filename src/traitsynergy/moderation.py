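"""Moderated regression of academic outcomes on intelligence and a trait.

The quadratic-adjusted moderation model is

    E[y] = b0 + b1*g + b2*g^2 + b3*t + b4*t^2 + b5*g*t

with all of y, g, t standardized before squares and products are formed (the
derived terms are *not* re-standardized, which keeps the coefficients on the
familiar standardized-beta scale).  The crude variant omits both quadratic
terms; comparing crude and adjusted b5 is what separates a genuine interaction
from quadratic confounding when g and t are correlated.

``build_results_table`` assembles the full results grid — 18 single items plus
3 composites, each against both outcomes — with per-cell p-values and
significance flags at the nominal and Bonferroni-corrected levels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .psychometrics import ItemSpec, COMPOSITES, score_composite, standardize

__all__ = [
    "ModerationFit",
    "ModeratedRegression",
    "fit_moderation",
    "intelligence_baseline",
    "bonferroni_threshold",
    "build_results_table",
    "DEFAULT_N_TESTS",
]

logger = logging.getLogger(__name__)

# Default multiplicity count for the full results grid.  The grid itself has
# 21 rows x 9 cells = 189 p-values; the default additionally counts the
# intelligence main/quadratic effects and the meta-regressions, and is
# configurable wherever it is used.
DEFAULT_N_TESTS = 195

TERMS_ADJUSTED = ["const", "intell", "intell2", "trait", "trait2", "intell_x_trait"]
TERMS_CRUDE = ["const", "intell", "trait", "intell_x_trait"]


@dataclass
class ModerationFit:
    """Standardized coefficients and inference for one moderation model."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    rsquared: float
    n_used: int
    adjusted: bool

    @property
    def b5(self) -> float:
        return float(self.params["intell_x_trait"])

    @property
    def p5(self) -> float:
        return float(self.pvalues["intell_x_trait"])


class ModeratedRegression:
    """Scikit-learn style estimator for the trait-by-intelligence model.

    ``fit(X, y)`` expects ``X`` with two columns (intelligence, trait); all
    variables are standardized internally, then OLS is run on
    ``y ~ g + t + g*t`` (``adjusted=False``) or
    ``y ~ g + g^2 + t + t^2 + g*t`` (``adjusted=True``).

    Attributes (after fit): ``coef_``, ``bse_``, ``pvalues_`` (pandas Series
    indexed by term name), ``rsquared_``, ``n_used_``.
    """

    def __init__(self, adjusted: bool = True, min_n: int = 10):
        self.adjusted = adjusted
        self.min_n = min_n

    def get_params(self, deep: bool = True) -> dict:
        return {"adjusted": self.adjusted, "min_n": self.min_n}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: (intelligence, trait)")
        g, t = X[:, 0], X[:, 1]
        mask = np.isfinite(g) & np.isfinite(t) & np.isfinite(y)
        n = int(mask.sum())
        if n < self.min_n:
            raise ValueError(f"need >= {self.min_n} complete cases, got {n}")
        gz = standardize(g[mask])
        tz = standardize(t[mask])
        yz = standardize(y[mask])
        if self.adjusted:
            design = np.column_stack([gz, gz**2, tz, tz**2, gz * tz])
            terms = TERMS_ADJUSTED
        else:
            design = np.column_stack([gz, tz, gz * tz])
            terms = TERMS_CRUDE
        design = sm.add_constant(design, has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("rank-deficient design (constant or collinear predictors)")
        res = sm.OLS(yz, design).fit()
        self.coef_ = pd.Series(res.params, index=terms)
        self.bse_ = pd.Series(res.bse, index=terms)
        self.pvalues_ = pd.Series(res.pvalues, index=terms)
        self.rsquared_ = float(res.rsquared)
        self.n_used_ = n
        return self

    def result_(self) -> ModerationFit:
        if not hasattr(self, "coef_"):
            raise ValueError("model is not fitted")
        return ModerationFit(
            self.coef_, self.bse_, self.pvalues_, self.rsquared_, self.n_used_,
            self.adjusted,
        )


def fit_moderation(y, g, t, adjusted: bool = True, min_n: int = 10) -> ModerationFit:
    """Fit the (crude or quadratic-adjusted) moderation model; see class docs."""
    model = ModeratedRegression(adjusted=adjusted, min_n=min_n)
    model.fit(np.column_stack([np.asarray(g, float), np.asarray(t, float)]), y)
    return model.result_()


@dataclass
class BaselineFit:
    beta_linear: float
    p_linear: float
    beta_quadratic: float
    p_quadratic: float
    r2_linear: float
    r2_quadratic: float
    n_used: int


def intelligence_baseline(y, g, min_n: int = 10) -> BaselineFit:
    """Standardized linear and quadratic regressions of an outcome on ability.

    Returns the linear beta and R^2 of ``y ~ g`` together with the quadratic
    term's beta and the R^2 of ``y ~ g + g^2``.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    mask = np.isfinite(g) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_n:
        raise ValueError(f"need >= {min_n} complete cases, got {n}")
    gz = standardize(g[mask])
    yz = standardize(y[mask])
    lin = sm.OLS(yz, sm.add_constant(gz)).fit()
    quad = sm.OLS(yz, sm.add_constant(np.column_stack([gz, gz**2]))).fit()
    return BaselineFit(
        beta_linear=float(lin.params[1]),
        p_linear=float(lin.pvalues[1]),
        beta_quadratic=float(quad.params[2]),
        p_quadratic=float(quad.pvalues[2]),
        r2_linear=float(lin.rsquared),
        r2_quadratic=float(quad.rsquared),
        n_used=n,
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test significance level, alpha / m."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 3:
        return np.nan, np.nan
    r, p = stats.pearsonr(a[mask], b[mask])
    return float(r), float(p)


def build_results_table(data: pd.DataFrame, specs: list[ItemSpec], iq_scores,
                        outcomes: tuple[str, ...] = ("gpa", "degree"),
                        alpha: float = 0.05,
                        n_tests: int = DEFAULT_N_TESTS) -> pd.DataFrame:
    """The full correlations-and-moderation results grid.

    One row per single item (18, on their raw keying) plus one per composite
    (3, reverse-keyed).  Per outcome the cells are: the trait-outcome
    correlation, the trait-squared coefficient from the adjusted model, and the
    crude and quadratic-adjusted interaction coefficients, each with p-values
    and significance flags at ``alpha`` and at ``alpha / n_tests``.
    Rows whose model cannot be fitted get missing cells and a logged warning.
    """
    iq = np.asarray(iq_scores, dtype=float)
    if len(iq) != len(data):
        raise ValueError("intelligence scores must align with data rows")
    bonf = bonferroni_threshold(alpha, n_tests)

    traits: list[tuple[str, np.ndarray]] = []
    for sp in specs:
        traits.append((sp.name, np.asarray(data[sp.column], dtype=float)))
    for comp in COMPOSITES:
        traits.append(
            (f"{comp}_composite", score_composite(data, specs, comp).to_numpy())
        )

    rows = []
    n_warned = 0
    for name, t in traits:
        row: dict = {"trait": name}
        row["r_iq"], row["p_r_iq"] = _pearson(t, iq)
        for out in outcomes:
            y = np.asarray(data[out], dtype=float)
            row[f"r_{out}"], row[f"p_r_{out}"] = _pearson(t, y)
            try:
                adj = fit_moderation(y, iq, t, adjusted=True)
                crude = fit_moderation(y, iq, t, adjusted=False)
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("row %s / outcome %s: %s", name, out, exc)
                n_warned += 1
                for cell in ("b_quad", "p_quad", "b_int_crude", "p_int_crude",
                             "b_int_adj", "p_int_adj", "n"):
                    row[f"{cell}_{out}"] = np.nan
                continue
            row[f"b_quad_{out}"] = float(adj.params["trait2"])
            row[f"p_quad_{out}"] = float(adj.pvalues["trait2"])
            row[f"b_int_crude_{out}"] = crude.b5
            row[f"p_int_crude_{out}"] = crude.p5
            row[f"b_int_adj_{out}"] = adj.b5
            row[f"p_int_adj_{out}"] = adj.p5
            row[f"n_{out}"] = adj.n_used
        rows.append(row)
    if n_warned:
        logger.warning("%d trait/outcome cells could not be fitted", n_warned)

    table = pd.DataFrame(rows)
    for col in table.columns:
        if col.startswith("p_"):
            stem = col[2:]
            table[f"sig_{stem}"] = table[col] < alpha
            table[f"bonf_{stem}"] = table[col] < bonf
    return table
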