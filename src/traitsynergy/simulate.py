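"""Synthetic respondent-table generator with known ground truth.

The generator emulates the study design downstream stages expect: a latent
general-ability factor ``g`` measured by 12 continuous indicators, a latent
personality trait ``T`` correlated with ``g``, 18 Likert items loading on
``T`` (reverse-keyed items load negatively), and two academic outcomes (a
continuous GPA and an ordinal 0-6 highest-degree code) generated from

    E[y] = b1*g + b2*g^2 + b3*T + b4*T^2 + b5*g*T

Two mechanisms that can masquerade as (or drive) trait-by-intelligence
interactions are built in and exposed as scenario presets:

* ``ganzach_synergistic`` / ``ganzach_compensatory`` — no true interaction
  (b5 = 0) but a convex / concave trait-outcome association (b4 != 0) combined
  with a positive trait-ability correlation, so the *crude* interaction model
  shows a spurious b5 of the corresponding sign.
* ``reliability_gradient`` — no true interaction or curvature, but the Likert
  item error SD falls with ability, s(g) = s0*exp(-k*g), so measured
  trait-outcome slopes strengthen with ability purely through reliability.

An optional logistic careless-responding mixture (probability
``expit(careless_intercept + careless_slope*g)``, responses uniform over the
scale) provides a second route to ability-dependent reliability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import norm

from .psychometrics import ItemSpec, load_item_specs

__all__ = [
    "SimConfig",
    "SCENARIOS",
    "make_config",
    "generate_population",
    "likert_discretize",
    "item_error_sd",
    "DEGREE_PROPORTIONS",
]

SCENARIOS = (
    "null",
    "ganzach_synergistic",
    "ganzach_compensatory",
    "reliability_gradient",
    "custom",
)

# Marginal distribution of the 0-6 highest-degree code (None, GED, high-school
# diploma, associate, bachelor, master, professional/PhD) used to discretize
# the latent degree propensity.
DEGREE_PROPORTIONS = np.array([515, 862, 2692, 598, 1352, 540, 149]) / 6708.0


@dataclass
class SimConfig:
    """Full parameterization of one simulated study."""

    n: int = 8984
    seed: int = 0
    rho_tg: float = 0.2
    ability_loadings: tuple = (0.7,) * 12
    item_loadings: tuple = (0.5,) * 18
    error_base_sd: float = 1.0
    error_gradient: float = 0.0
    careless_intercept: float = -30.0
    careless_slope: float = 0.0
    outcome_coefs: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)  # (b1, b2, b3, b4, b5)
    outcome_noise_sd: float = 1.0
    likert: bool = True
    likert_cutpoints: dict | None = None  # item index -> cutpoints; None = quantile default
    scenario: str = "custom"

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not -1.0 <= self.rho_tg <= 1.0:
            raise ValueError("rho_tg must be in [-1, 1]")
        if len(self.ability_loadings) != 12:
            raise ValueError("ability_loadings must have 12 entries")
        if any(not 0 < a <= 1 for a in self.ability_loadings):
            raise ValueError("ability loadings must lie in (0, 1]")
        if len(self.item_loadings) != 18:
            raise ValueError("item_loadings must have 18 entries")
        if any(lam <= 0 for lam in self.item_loadings):
            raise ValueError("item loadings must be positive")
        if self.error_base_sd < 0:
            raise ValueError("error_base_sd must be >= 0")
        if self.outcome_noise_sd < 0:
            raise ValueError("outcome_noise_sd must be >= 0")
        if len(self.outcome_coefs) != 5:
            raise ValueError("outcome_coefs must be (b1, b2, b3, b4, b5)")
        if self.likert_cutpoints is not None:
            for item, cuts in self.likert_cutpoints.items():
                cuts = np.asarray(cuts, dtype=float)
                if np.any(np.diff(cuts) <= 0):
                    raise ValueError(f"cutpoints for item {item} must be strictly increasing")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ability_loadings"] = list(self.ability_loadings)
        d["item_loadings"] = list(self.item_loadings)
        d["outcome_coefs"] = list(self.outcome_coefs)
        if self.likert_cutpoints is not None:
            d["likert_cutpoints"] = {
                int(k): [float(c) for c in v] for k, v in self.likert_cutpoints.items()
            }
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("ability_loadings", "item_loadings", "outcome_coefs"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_config(scenario: str = "custom", overrides: dict | None = None) -> SimConfig:
    """Build a fully populated ``SimConfig`` for a named scenario.

    Scenarios fix the mechanism-relevant parameters:

    * ``null`` — all outcome coefficients 0, homoscedastic items.
    * ``ganzach_synergistic`` — b4 = +0.15, b5 = 0, rho_tg = 0.3, k = 0.
    * ``ganzach_compensatory`` — b4 = -0.15, b5 = 0, rho_tg = 0.3, k = 0.
    * ``reliability_gradient`` — b4 = b5 = 0, b3 = 0.5, k = 0.15, plus a
      careless-responding mixture concentrated at low ability
      (intercept -2.0, slope -2.0), so measurement reliability rises with
      ability both smoothly and through the careless mechanism.
    * ``custom`` — neutral defaults, everything from ``overrides``.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    cfg = SimConfig(scenario=scenario)
    if scenario == "null":
        cfg.outcome_coefs = (0.0, 0.0, 0.0, 0.0, 0.0)
        cfg.error_gradient = 0.0
    elif scenario == "ganzach_synergistic":
        cfg.outcome_coefs = (0.46, 0.0, 0.2, 0.15, 0.0)
        cfg.rho_tg = 0.3
        cfg.error_gradient = 0.0
    elif scenario == "ganzach_compensatory":
        cfg.outcome_coefs = (0.46, 0.0, 0.2, -0.15, 0.0)
        cfg.rho_tg = 0.3
        cfg.error_gradient = 0.0
    elif scenario == "reliability_gradient":
        cfg.outcome_coefs = (0.46, 0.0, 0.5, 0.0, 0.0)
        cfg.error_gradient = 0.15
        cfg.careless_intercept = -2.0
        cfg.careless_slope = -2.0
    if overrides:
        valid = {f.name for f in dataclasses.fields(SimConfig)}
        for key, value in overrides.items():
            if key not in valid:
                raise ValueError(f"unknown SimConfig field {key!r}")
            if key in ("ability_loadings", "item_loadings", "outcome_coefs"):
                value = tuple(value)
            setattr(cfg, key, value)
    cfg.validate()
    return cfg


def item_error_sd(g, s0: float, k: float):
    """Item measurement-error SD as a function of ability: s0 * exp(-k*g).

    Strictly decreasing in ``g`` when ``k > 0``; requires ``s0 > 0``.
    """
    if s0 <= 0:
        raise ValueError("s0 must be > 0")
    return s0 * np.exp(-k * np.asarray(g, dtype=float))


def likert_discretize(x, cutpoints, scale_range=(1, 5)):
    """Map continuous responses to Likert categories via ordered thresholds.

    Values below the first cutpoint get the scale minimum; values at or above
    the last get the maximum.  Monotone nondecreasing in ``x``.
    """
    cutpoints = np.asarray(cutpoints, dtype=float)
    if cutpoints.ndim != 1 or cutpoints.size == 0:
        raise ValueError("cutpoints must be a non-empty 1-D sequence")
    if np.any(np.diff(cutpoints) <= 0):
        raise ValueError("cutpoints must be strictly increasing")
    lo, hi = int(scale_range[0]), int(scale_range[1])
    if cutpoints.size != hi - lo:
        raise ValueError("number of cutpoints must equal scale size - 1")
    return (np.searchsorted(cutpoints, np.asarray(x, dtype=float), side="right") + lo)


def default_cutpoints(spec: ItemSpec, lam: float, s0: float) -> np.ndarray:
    """Equal-probability normal-quantile cutpoints on the item's marginal scale.

    The continuous response has marginal SD sqrt(lam^2 + s0^2) at the center of
    the ability distribution; thresholds are standard-normal quantiles scaled
    by that SD.
    """
    n_cat = spec.scale_max - spec.scale_min + 1
    probs = np.arange(1, n_cat) / n_cat
    return norm.ppf(probs) * np.sqrt(lam**2 + s0**2)


def generate_population(config: SimConfig,
                        specs: list[ItemSpec] | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one respondent table plus its latent ground truth.

    Deterministic given ``config.seed``.  Returns ``(table, truth)`` where
    ``table`` has columns id, test_1..test_12, item_1..item_18, gpa, degree and
    ``truth`` has id, g, T and per-block careless flags (items 1-8 and 9-18
    form the two rating blocks).
    """
    config.validate()
    if specs is None:
        specs = load_item_specs()
    n = config.n
    rng = np.random.default_rng(config.seed)
    if n == 0:
        table = pd.DataFrame(
            columns=["id"] + [f"test_{j}" for j in range(1, 13)]
            + [f"item_{j}" for j in range(1, 19)] + ["gpa", "degree"]
        )
        truth = pd.DataFrame(columns=["id", "g", "T", "careless_block1", "careless_block2"])
        return table, truth

    # latent ability and trait, population correlation rho_tg
    z = rng.standard_normal((n, 2))
    g = z[:, 0]
    T = config.rho_tg * z[:, 0] + np.sqrt(1.0 - config.rho_tg**2) * z[:, 1]

    # ability battery: standardized-metric indicators a_j*g + sqrt(1-a_j^2)*e
    a = np.asarray(config.ability_loadings, dtype=float)
    tests = a * g[:, None] + np.sqrt(1.0 - a**2) * rng.standard_normal((n, 12))

    # heteroscedastic item noise and careless mixture
    if config.error_base_sd > 0:
        s = config.error_base_sd * np.exp(-config.error_gradient * g)
    else:
        s = np.zeros(n)
    p_careless = expit(config.careless_intercept + config.careless_slope * g)
    careless = rng.random((n, 2)) < p_careless[:, None]

    lam = np.asarray(config.item_loadings, dtype=float)
    signed_lam = np.where([sp.reverse for sp in specs], -lam, lam)
    items = np.empty((n, 18))
    for j, sp in enumerate(specs):
        x = signed_lam[j] * T + s * rng.standard_normal(n)
        block = 0 if sp.item <= 8 else 1
        flag = careless[:, block]
        if config.likert:
            if config.likert_cutpoints and sp.item in config.likert_cutpoints:
                cuts = np.asarray(config.likert_cutpoints[sp.item], dtype=float)
            else:
                cuts = default_cutpoints(sp, lam[j], config.error_base_sd)
            cat = likert_discretize(x, cuts, (sp.scale_min, sp.scale_max)).astype(float)
            if flag.any():
                cat[flag] = rng.integers(
                    sp.scale_min, sp.scale_max + 1, size=int(flag.sum())
                ).astype(float)
            items[:, j] = cat
        else:
            if flag.any():
                x = x.copy()
                x[flag] = rng.uniform(sp.scale_min, sp.scale_max, size=int(flag.sum()))
            items[:, j] = x

    # outcomes from the quadratic-plus-interaction surface
    b1, b2, b3, b4, b5 = config.outcome_coefs
    lp = b1 * g + b2 * g**2 + b3 * T + b4 * T**2 + b5 * g * T
    gpa = lp + config.outcome_noise_sd * rng.standard_normal(n)
    degree_latent = lp + config.outcome_noise_sd * rng.standard_normal(n)
    sd = degree_latent.std(ddof=1)
    if sd > 0:
        degree_z = (degree_latent - degree_latent.mean()) / sd
    else:
        degree_z = np.zeros(n)
    thresholds = norm.ppf(np.cumsum(DEGREE_PROPORTIONS)[:-1])
    degree = np.searchsorted(thresholds, degree_z, side="right")

    table = pd.DataFrame({"id": np.arange(n)})
    for j in range(12):
        table[f"test_{j + 1}"] = tests[:, j]
    for j in range(18):
        table[f"item_{j + 1}"] = items[:, j]
    table["gpa"] = gpa
    table["degree"] = degree
    truth = pd.DataFrame(
        {
            "id": np.arange(n),
            "g": g,
            "T": T,
            "careless_block1": careless[:, 0],
            "careless_block2": careless[:, 1],
        }
    )
    return table, truth
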