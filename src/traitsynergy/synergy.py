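"""Cross-trait synergy meta-regression.

Across the 21 trait rows of the results grid, a synergistic pattern means the
trait-by-intelligence interaction coefficient tends to share the sign of the
trait-outcome correlation (an existing association, positive or negative,
strengthens with intelligence).  Regressing the (adjusted) interaction
coefficients on the trait-outcome correlations therefore classifies the
overall pattern: a significantly positive slope is synergistic, a
significantly negative one compensatory, otherwise indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["SynergyFit", "synergy_fit", "classify_interaction", "fig3_table"]


@dataclass
class SynergyFit:
    """Fit of interaction coefficient ~ trait-outcome correlation across traits."""

    outcome: str
    use_adjusted: bool
    slope: float
    intercept: float
    slope_se: float
    p_slope: float
    n_rows: int
    sigma: float        # residual SD (prediction-interval scale)
    x_mean: float       # prediction-interval parameters
    sxx: float
    label: str          # 'synergistic' | 'compensatory' | 'indeterminate'

    def prediction_interval(self, x0, level: float = 0.95):
        """Classical OLS prediction interval for a new trait at correlation x0."""
        x0 = np.asarray(x0, dtype=float)
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n_rows - 2)
        se_pred = self.sigma * np.sqrt(
            1.0 + 1.0 / self.n_rows + (x0 - self.x_mean) ** 2 / self.sxx
        )
        fit = self.intercept + self.slope * x0
        return fit - tcrit * se_pred, fit + tcrit * se_pred


def synergy_fit(table: pd.DataFrame, outcome: str = "gpa",
                use_adjusted: bool = True, label_alpha: float = 0.05,
                weights: str | None = None) -> SynergyFit:
    """Regress interaction coefficients on trait-outcome correlations.

    ``weights='inverse_variance'`` weights rows by 1/SE^2 of the interaction
    coefficient is not available from the grid (it stores p-values, not SEs),
    so inverse-variance weighting recovers the SE from the coefficient and its
    two-sided p-value; unweighted is the default.
    """
    icol = f"b_int_adj_{outcome}" if use_adjusted else f"b_int_crude_{outcome}"
    rcol = f"r_{outcome}"
    usable = table[[rcol, icol]].dropna()
    if len(usable) < 3:
        raise ValueError("need >= 3 rows with non-missing cells")
    x = usable[rcol].to_numpy()
    y = usable[icol].to_numpy()
    w = None
    if weights == "inverse_variance":
        pcol = f"p_int_adj_{outcome}" if use_adjusted else f"p_int_crude_{outcome}"
        p = table.loc[usable.index, pcol].to_numpy()
        n = table.loc[usable.index, f"n_{outcome}"].to_numpy()
        tstat = stats.t.ppf(1 - p / 2, np.maximum(n - 6, 1))
        se = np.where(tstat > 0, np.abs(y) / tstat, np.nan)
        w = 1.0 / se**2
        w = np.where(np.isfinite(w), w, np.nanmedian(w[np.isfinite(w)]))
    elif weights is not None:
        raise ValueError("weights must be None or 'inverse_variance'")
    X = sm.add_constant(x)
    res = (sm.WLS(y, X, weights=w) if w is not None else sm.OLS(y, X)).fit()
    slope = float(res.params[1])
    p_slope = float(res.pvalues[1])
    if p_slope < label_alpha and slope > 0:
        label = "synergistic"
    elif p_slope < label_alpha and slope < 0:
        label = "compensatory"
    else:
        label = "indeterminate"
    resid = y - res.predict(X)
    dof = max(len(x) - 2, 1)
    return SynergyFit(
        outcome=outcome,
        use_adjusted=use_adjusted,
        slope=slope,
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        p_slope=p_slope,
        n_rows=len(x),
        sigma=float(np.sqrt((resid**2).sum() / dof)),
        x_mean=float(x.mean()),
        sxx=float(((x - x.mean()) ** 2).sum()),
        label=label,
    )


def classify_interaction(b_interaction: float, r_trait_outcome: float) -> str:
    """Classify one interaction: same sign as the correlation = synergistic."""
    if b_interaction == 0 or r_trait_outcome == 0:
        return "null"
    if np.sign(b_interaction) == np.sign(r_trait_outcome):
        return "synergistic"
    return "compensatory"


def fig3_table(table: pd.DataFrame, fit: SynergyFit) -> pd.DataFrame:
    """Per-trait scatter table with fitted line and 95% prediction bounds."""
    icol = f"b_int_adj_{fit.outcome}" if fit.use_adjusted else f"b_int_crude_{fit.outcome}"
    rcol = f"r_{fit.outcome}"
    usable = table[["trait", rcol, icol]].dropna().reset_index(drop=True)
    x = usable[rcol].to_numpy()
    lo, hi = fit.prediction_interval(x)
    return pd.DataFrame(
        {
            "row": np.arange(1, len(usable) + 1),
            "trait": usable["trait"],
            "correlation": x,
            "interaction": usable[icol],
            "fitted": fit.intercept + fit.slope * x,
            "pred_lo": lo,
            "pred_hi": hi,
        }
    )
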