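"""One-factor measurement machinery.

Implements the measurement layer used throughout the pipeline: z-scoring,
single-factor extraction for the 12-test ability battery (maximum likelihood on
the correlation matrix, with a minimum-residual fallback), Thurstone regression
factor scores, coefficient omega, and standardized reverse-keyed composite
scores for the three personality composites (dependable, agreeable, open).

The final dependable composite is items {1R, 3R, 4, 11, 16R}; the conscientious
item (2) is excluded from it because of its very low loading, but the six-item
pre-removal variant is available via ``include_excluded=True`` for sensitivity
checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "ItemSpec",
    "load_item_specs",
    "standardize",
    "SingleFactorModel",
    "FactorSolution",
    "fit_single_factor",
    "factor_scores",
    "coefficient_omega",
    "score_composite",
    "keyed_item_matrix",
]

EPSILON_FLOOR = 0.005

COMPOSITES = ("dependable", "agreeable", "open")


@dataclass(frozen=True)
class ItemSpec:
    """One Likert item: scale range, keying direction, composite membership."""

    item: int
    name: str
    scale_min: int
    scale_max: int
    reverse: bool
    composite: str  # 'dependable' | 'agreeable' | 'open' | 'none'
    excluded: bool = False

    @property
    def column(self) -> str:
        return f"item_{self.item}"


def load_item_specs(include_excluded: bool = False) -> list[ItemSpec]:
    """Load the packaged 18-item specification table.

    Parameters
    ----------
    include_excluded
        If True, items flagged as excluded (the conscientious item dropped from
        the final dependable composite) keep their composite membership;
        otherwise their membership is set to ``'none'``.
    """
    with resources.files("traitsynergy.data").joinpath("item_specs.csv").open() as fh:
        table = pd.read_csv(fh)
    specs = []
    for row in table.itertuples(index=False):
        composite = row.composite
        if row.excluded and not include_excluded:
            composite = "none"
        specs.append(
            ItemSpec(
                item=int(row.item),
                name=str(row.name),
                scale_min=int(row.scale_min),
                scale_max=int(row.scale_max),
                reverse=bool(row.reverse),
                composite=composite,
                excluded=bool(row.excluded),
            )
        )
    return specs


def standardize(v) -> np.ndarray | pd.Series:
    """Z-score a vector over its non-missing entries (denominator n-1).

    Missing entries are preserved as missing.  Raises ``ValueError`` for
    vectors with fewer than two non-missing values or zero sample SD.
    """
    is_series = isinstance(v, pd.Series)
    x = np.asarray(v, dtype=float)
    mask = np.isfinite(x)
    if mask.sum() < 2:
        raise ValueError("standardize requires at least 2 non-missing values")
    m = x[mask].mean()
    s = x[mask].std(ddof=1)
    if s == 0:
        raise ValueError("standardize requires nonzero sample SD")
    out = np.full_like(x, np.nan)
    out[mask] = (x[mask] - m) / s
    if is_series:
        return pd.Series(out, index=v.index, name=v.name)
    return out


@dataclass
class FactorSolution:
    """A fitted one-factor model on standardized indicators."""

    loadings: np.ndarray
    uniquenesses: np.ndarray
    indicator_names: list[str]
    method: str  # 'ml' or 'minres'
    converged: bool
    n_obs: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "indicator": self.indicator_names,
                "loading": self.loadings,
                "uniqueness": self.uniquenesses,
            }
        )


def _ml_objective(params, R, p):
    lam = params[:p]
    psi = params[p:]
    sigma = np.outer(lam, lam)
    sigma[np.diag_indices(p)] += psi
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(2 * p)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    sigma_inv = np.linalg.inv(sigma)
    f = logdet + np.trace(sigma_inv @ R)
    # dF/dSigma = Sigma^-1 (Sigma - R) Sigma^-1
    grad_sigma = sigma_inv @ (sigma - R) @ sigma_inv
    grad_lam = 2.0 * grad_sigma @ lam
    grad_psi = np.diag(grad_sigma).copy()
    return f, np.concatenate([grad_lam, grad_psi])


def _minres_objective(lam, R):
    resid = R - np.outer(lam, lam)
    np.fill_diagonal(resid, 0.0)
    f = 0.5 * (resid**2).sum()
    grad = -2.0 * resid @ lam
    return f, grad


def _initial_loadings(R: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R)
    lam = vecs[:, -1] * np.sqrt(max(vals[-1], 1e-8))
    return np.clip(lam, -0.98, 0.98)


class SingleFactorModel:
    """Scikit-learn style one-factor model for a battery of indicators.

    ``fit`` extracts a single common factor from the indicator correlation
    matrix by maximum likelihood (minimum-residual fallback on
    non-convergence); ``transform`` returns Thurstone regression-method factor
    scores, re-standardized to mean 0 / SD 1 over the scored rows.

    Parameters
    ----------
    method : {'ml', 'minres'}
        Extraction objective. 'ml' falls back to 'minres' when the likelihood
        optimizer fails to converge.
    epsilon_floor : float
        Lower bound on uniquenesses (Heywood-case guard).
    min_present : int or None
        Minimum number of non-missing indicators a row needs to receive a
        score; ``None`` means ``ceil(2p/3)`` (8 of 12 for the ability battery).

    Attributes
    ----------
    loadings_ : ndarray of shape (p,)
        Standardized loadings, sign-aligned so their sum is positive.
    uniquenesses_ : ndarray of shape (p,)
        Unique variances, floored at ``epsilon_floor``.
    converged_ : bool
    method_used_ : str
    """

    def __init__(self, method: str = "ml", epsilon_floor: float = EPSILON_FLOOR,
                 min_present: int | None = None):
        self.method = method
        self.epsilon_floor = epsilon_floor
        self.min_present = min_present

    def get_params(self, deep: bool = True) -> dict:
        return {
            "method": self.method,
            "epsilon_floor": self.epsilon_floor,
            "min_present": self.min_present,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting ---------------------------------------------------------

    def _fit_corr(self, R: np.ndarray) -> tuple[np.ndarray, np.ndarray, str, bool]:
        p = R.shape[0]
        lam0 = _initial_loadings(R)
        psi0 = np.clip(1.0 - lam0**2, 0.05, 1.0)
        method_used = self.method
        converged = False
        lam = lam0
        psi = psi0
        if self.method == "ml":
            res = optimize.minimize(
                _ml_objective,
                np.concatenate([lam0, psi0]),
                args=(R, p),
                jac=True,
                method="L-BFGS-B",
                bounds=[(-1.5, 1.5)] * p + [(self.epsilon_floor, 4.0)] * p,
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
            )
            lam, psi = res.x[:p], res.x[p:]
            converged = bool(res.success)
            if not converged:
                method_used = "minres"
        if method_used == "minres":
            res = optimize.minimize(
                _minres_objective,
                lam0,
                args=(R,),
                jac=True,
                method="L-BFGS-B",
                bounds=[(-1.0, 1.0)] * p,
                options={"maxiter": 500, "ftol": 1e-14},
            )
            lam = res.x
            psi = np.clip(1.0 - lam**2, self.epsilon_floor, None)
            converged = bool(res.success)
        if lam.sum() < 0:
            lam = -lam
        psi = np.clip(psi, self.epsilon_floor, None)
        return lam, psi, method_used, converged

    def fit(self, X, y=None):
        X, names = _as_matrix(X)
        p = X.shape[1]
        if p < 3:
            raise ValueError("single-factor extraction needs >= 3 indicators")
        complete = np.isfinite(X).all(axis=1)
        if complete.sum() < p + 2:
            raise ValueError(
                f"need at least {p + 2} complete-case rows, got {int(complete.sum())}"
            )
        Xc = X[complete]
        self.means_ = Xc.mean(axis=0)
        self.sds_ = Xc.std(axis=0, ddof=1)
        if np.any(self.sds_ == 0):
            raise ValueError("constant indicator: correlation matrix undefined")
        R = np.corrcoef(Xc, rowvar=False)
        lam, psi, method_used, converged = self._fit_corr(R)
        if not converged:
            raise RuntimeError("one-factor extraction did not converge (ml and minres)")
        self.loadings_ = lam
        self.uniquenesses_ = psi
        self.indicator_names_ = names
        self.method_used_ = method_used
        self.converged_ = converged
        self.n_obs_ = int(complete.sum())
        return self

    @classmethod
    def from_correlation(cls, R: np.ndarray, names: list[str] | None = None,
                         n_obs: int = 0, **params) -> FactorSolution:
        """Fit directly on a correlation matrix (used by the window analysis)."""
        model = cls(**params)
        R = np.asarray(R, dtype=float)
        lam, psi, method_used, converged = model._fit_corr(R)
        if names is None:
            names = [f"x{i + 1}" for i in range(R.shape[0])]
        return FactorSolution(lam, psi, list(names), method_used, converged, n_obs)

    # -- scoring ---------------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Thurstone regression factor scores, re-standardized over scored rows.

        Rows with fewer than ``min_present`` non-missing indicators get NaN;
        partially observed rows are scored with the weight subvector implied by
        their available indicators.
        """
        _check_fitted(self)
        X, names = _as_matrix(X)
        if names != self.indicator_names_:
            if X.shape[1] != len(self.indicator_names_):
                raise ValueError("indicator columns do not match the fitted model")
        p = X.shape[1]
        min_present = self.min_present
        if min_present is None:
            min_present = int(np.ceil(2 * p / 3))
        Z = (X - self.means_) / self.sds_
        present = np.isfinite(Z)
        scores = np.full(X.shape[0], np.nan)
        sigma = np.outer(self.loadings_, self.loadings_)
        sigma[np.diag_indices(p)] += self.uniquenesses_
        # score rows grouped by missingness pattern so each weight subvector
        # is solved once
        pattern_codes = present @ (1 << np.arange(p, dtype=np.int64))
        for code in np.unique(pattern_codes):
            rows = pattern_codes == code
            avail = present[np.argmax(rows)]
            if avail.sum() < min_present:
                continue
            w = np.linalg.solve(sigma[np.ix_(avail, avail)], self.loadings_[avail])
            scores[rows] = Z[np.ix_(rows, avail)] @ w
        finite = np.isfinite(scores)
        if finite.sum() >= 2 and scores[finite].std(ddof=1) > 0:
            scores[finite] = (scores[finite] - scores[finite].mean()) / scores[
                finite
            ].std(ddof=1)
        return scores

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def solution_(self) -> FactorSolution:
        _check_fitted(self)
        return FactorSolution(
            self.loadings_,
            self.uniquenesses_,
            self.indicator_names_,
            self.method_used_,
            self.converged_,
            self.n_obs_,
        )


def _check_fitted(model: SingleFactorModel) -> None:
    if not hasattr(model, "loadings_"):
        raise ValueError("model is not fitted")


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D indicator matrix")
    return X, [f"x{i + 1}" for i in range(X.shape[1])]


def fit_single_factor(X, method: str = "ml",
                      epsilon_floor: float = EPSILON_FLOOR) -> FactorSolution:
    """Fit a one-factor model to an indicator matrix; see ``SingleFactorModel``."""
    model = SingleFactorModel(method=method, epsilon_floor=epsilon_floor).fit(X)
    return model.solution_()


def factor_scores(sol: FactorSolution, X, min_present: int | None = None) -> np.ndarray:
    """Regression-method factor scores for ``X`` under a fitted solution."""
    if not sol.converged:
        raise ValueError("factor solution did not converge")
    model = SingleFactorModel(min_present=min_present)
    Xm, names = _as_matrix(X)
    complete = np.isfinite(Xm).all(axis=1)
    model.loadings_ = sol.loadings
    model.uniquenesses_ = sol.uniquenesses
    model.indicator_names_ = sol.indicator_names
    model.method_used_ = sol.method
    model.converged_ = sol.converged
    model.n_obs_ = sol.n_obs
    model.means_ = Xm[complete].mean(axis=0)
    model.sds_ = Xm[complete].std(axis=0, ddof=1)
    return model.transform(X)


def coefficient_omega(sol: FactorSolution) -> float:
    """Coefficient omega: (sum lambda)^2 / ((sum lambda)^2 + sum theta)."""
    if not sol.converged:
        raise ValueError("factor solution did not converge")
    s = sol.loadings.sum()
    return float(s**2 / (s**2 + sol.uniquenesses.sum()))


def keyed_item_matrix(data: pd.DataFrame, specs: list[ItemSpec],
                      composite: str) -> pd.DataFrame:
    """Member items of a composite, standardized and reverse-keyed (negated).

    Items that cannot be standardized (constant or near-empty) are dropped
    with a warning so a single degenerate item does not void the composite.
    """
    members = [s for s in specs if s.composite == composite]
    if not members:
        raise ValueError(f"composite {composite!r} has no member items")
    cols = {}
    for s in members:
        try:
            z = standardize(data[s.column])
        except ValueError as exc:
            logger.warning("composite %s: dropping %s (%s)", composite, s.column, exc)
            continue
        cols[s.column] = -z if s.reverse else z
    if not cols:
        raise ValueError(f"composite {composite!r} has no usable member items")
    return pd.DataFrame(cols, index=data.index)


def score_composite(data: pd.DataFrame, specs: list[ItemSpec],
                    composite: str) -> pd.Series:
    """Standardized composite: mean of standardized, reverse-keyed member items.

    Rows with all member items missing get NaN; partially missing rows use the
    mean of their available items, and the result is re-standardized.
    """
    keyed = keyed_item_matrix(data, specs, composite)
    raw = keyed.mean(axis=1, skipna=True)
    out = pd.Series(np.nan, index=data.index, name=composite)
    mask = raw.notna()
    out[mask] = standardize(raw[mask].to_numpy())
    return out
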