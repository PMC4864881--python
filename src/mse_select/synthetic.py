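"""Synthetic scenario generator for confounding / collinearity regimes.

Every engine in this package can be exercised without external data by
drawing subject-level records whose generative structure is known exactly:
covariates (binary or standard-normal, optionally intercorrelated), an
exposure linked to them either through a logistic model (binary exposure)
or through a joint-normal correlation (continuous exposure), and a binary
outcome from a logistic model with a rare baseline risk so that odds ratios
approximate risk ratios.

The named presets reproduce the four qualitative regimes a candidate
covariate can occupy — neither confounder nor collinear, pure confounder,
collinear non-confounder, collinear confounder — plus a continuous
correlated-pair regime (``sodium_potassium_like``) and a survey-like
scenario with one dominant confounder among several weak candidates
(``atopy_like``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

from .data_model import AnalysisSpec, Dataset
from .errors import ConfigurationError, GenerationError


@dataclass(frozen=True)
class ConfounderSpec:
    """One generated covariate and its two causal links.

    ``effect_on_outcome`` is the log odds ratio per unit in the outcome
    model.  ``association_with_exposure`` is a log odds ratio per unit in
    the exposure model when the exposure is binary, and a correlation when
    the exposure is continuous.  ``distribution`` is ``binary`` (Bernoulli,
    ``prevalence``) or ``normal`` (standard normal).  ``forced`` marks
    covariates that analyses always adjust for.
    """

    name: str
    effect_on_outcome: float = 0.0
    association_with_exposure: float = 0.0
    distribution: str = "binary"
    prevalence: float = 0.5
    forced: bool = False

    def __post_init__(self):
        if self.distribution not in ("binary", "normal"):
            raise ConfigurationError("distribution must be 'binary' or 'normal'")
        if self.distribution == "binary" and not 0.0 < self.prevalence < 1.0:
            raise GenerationError(
                f"confounder {self.name!r}: prevalence must be in (0,1)"
            )


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative parameters for one synthetic regime.

    ``exposure_prevalence`` may be ``None`` for a continuous (standard
    normal) exposure, in which case each normal confounder's
    ``association_with_exposure`` is read as a correlation.
    ``collinearity_r`` is the pairwise correlation among the normal
    covariates themselves.  ``baseline_risk`` is the outcome risk at
    exposure 0 and covariate reference values; the default 0.05 keeps the
    outcome rare.
    """

    n: int = 5000
    baseline_risk: float = 0.05
    exposure_prevalence: float | None = 0.5
    exposure_effect: float = 0.0
    confounders: tuple[ConfounderSpec, ...] = ()
    collinearity_r: float = 0.0
    seed: int = 0
    outcome_name: str = "y"
    exposure_name: str = "x"

    def __post_init__(self):
        object.__setattr__(self, "confounders", tuple(self.confounders))
        if self.n < 50:
            raise GenerationError("n must be at least 50")
        if not 0.0 < self.baseline_risk < 1.0:
            raise GenerationError("baseline_risk must be in (0,1)")
        if self.exposure_prevalence is not None and not 0.0 < self.exposure_prevalence < 1.0:
            raise GenerationError("exposure_prevalence must be in (0,1) or None")
        if not abs(self.collinearity_r) < 1.0:
            raise GenerationError("collinearity_r must satisfy |r| < 1")
        names = [c.name for c in self.confounders]
        if len(names) != len(set(names)):
            raise GenerationError("confounder names must be distinct")

    @property
    def truth(self) -> dict:
        """The generating coefficients, for parameter-recovery checks."""
        return {
            self.exposure_name: self.exposure_effect,
            **{c.name: c.effect_on_outcome for c in self.confounders},
        }


def analysis_spec(scenario: ScenarioSpec) -> AnalysisSpec:
    """The matching analysis declaration: forced covariates forced, the
    rest candidates."""
    return AnalysisSpec(
        outcome_name=scenario.outcome_name,
        exposure_name=scenario.exposure_name,
        forced=tuple(c.name for c in scenario.confounders if c.forced),
        candidates=tuple(c.name for c in scenario.confounders if not c.forced),
        family="logistic",
    )


def _normal_block(scenario: ScenarioSpec, rng) -> dict[str, np.ndarray]:
    """Draw the jointly normal covariates (and the exposure, if continuous)."""
    normals = [c for c in scenario.confounders if c.distribution == "normal"]
    labels = [c.name for c in normals]
    continuous_exposure = scenario.exposure_prevalence is None
    k = len(labels) + (1 if continuous_exposure else 0)
    if k == 0:
        return {}
    corr = np.full((k, k), scenario.collinearity_r, dtype=float)
    np.fill_diagonal(corr, 1.0)
    if continuous_exposure:
        # first coordinate is the exposure; its correlations come from the
        # confounders' association_with_exposure (read as correlations)
        corr = np.full((k, k), scenario.collinearity_r, dtype=float)
        np.fill_diagonal(corr, 1.0)
        for j, c in enumerate(normals, start=1):
            corr[0, j] = corr[j, 0] = c.association_with_exposure
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() <= 1e-10:
        raise GenerationError(
            "the requested correlation structure (collinearity_r and "
            "association_with_exposure) is not positive definite"
        )
    L = np.linalg.cholesky(corr)
    Z = rng.standard_normal((scenario.n, k)) @ L.T
    out = {}
    offset = 0
    if continuous_exposure:
        out[scenario.exposure_name] = Z[:, 0]
        offset = 1
    for j, name in enumerate(labels):
        out[name] = Z[:, j + offset]
    return out


def _calibrate_intercept(target: float, linear: np.ndarray) -> float:
    """Intercept making the mean logistic probability equal ``target``."""
    def gap(a):
        return float(np.mean(special.expit(a + linear)) - target)

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise GenerationError(
            "cannot reach the requested prevalence with the stated associations"
        )
    return float(optimize.brentq(gap, lo, hi, xtol=1e-12))


def generate(scenario: ScenarioSpec) -> Dataset:
    """Draw one dataset from ``scenario`` (deterministic given its seed)."""
    ss = np.random.SeedSequence(scenario.seed)
    rng_cov, rng_exp, rng_out = (np.random.default_rng(s) for s in ss.spawn(3))

    cols: dict[str, np.ndarray] = {}
    cols.update(_normal_block(scenario, rng_cov))
    for c in scenario.confounders:
        if c.distribution == "binary":
            cols[c.name] = rng_cov.binomial(1, c.prevalence, scenario.n).astype(float)

    if scenario.exposure_prevalence is not None:
        linear = np.zeros(scenario.n)
        for c in scenario.confounders:
            z = cols[c.name]
            centered = z - c.prevalence if c.distribution == "binary" else z
            linear = linear + c.association_with_exposure * centered
        a0 = _calibrate_intercept(scenario.exposure_prevalence, linear)
        x = rng_exp.binomial(1, special.expit(a0 + linear)).astype(float)
        cols[scenario.exposure_name] = x

    eta = special.logit(scenario.baseline_risk) + scenario.exposure_effect * cols[
        scenario.exposure_name
    ]
    for c in scenario.confounders:
        eta = eta + c.effect_on_outcome * cols[c.name]
    y = rng_out.binomial(1, special.expit(eta)).astype(int)

    frame = pd.DataFrame(
        {
            scenario.outcome_name: y,
            scenario.exposure_name: cols[scenario.exposure_name],
            **{c.name: cols[c.name] for c in scenario.confounders},
        }
    )
    return Dataset(frame=frame, weights=np.ones(scenario.n))


PRESETS = (
    "null",
    "confounder",
    "collinear_nonconfounder",
    "collinear_confounder",
    "sodium_potassium_like",
    "atopy_like",
)

_LN2 = math.log(2.0)
_LN3 = math.log(3.0)


def preset(name: str, n: int | None = None, seed: int = 0) -> ScenarioSpec:
    """A fully specified scenario for one of the canonical regimes.

    * ``null`` — exposure has no effect and the candidates are pure noise.
    * ``confounder`` — one binary covariate linked to both exposure and
      outcome: dropping it shifts the exposure coefficient (bias) without
      much change in its SE.
    * ``collinear_nonconfounder`` — a normal covariate strongly predictive
      of exposure but not of outcome: keeping it inflates the exposure SE
      for no bias benefit.
    * ``collinear_confounder`` — the same strong exposure link plus a real
      outcome effect: deletion trades bias against variance.
    * ``sodium_potassium_like`` — continuous exposure correlated 0.81 with
      a continuous candidate that also predicts the outcome.
    * ``atopy_like`` — survey-like: one dominant binary confounder among
      several weak/noise candidates, with a forced covariate.
    """
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available presets: {PRESETS}"
        )
    if name == "null":
        spec = ScenarioSpec(
            n=2000,
            exposure_effect=0.0,
            confounders=(
                ConfounderSpec("u1"),
                ConfounderSpec("u2", distribution="normal"),
            ),
            seed=seed,
        )
    elif name == "confounder":
        spec = ScenarioSpec(
            n=5000,
            exposure_effect=_LN2,
            confounders=(
                ConfounderSpec("u1", effect_on_outcome=_LN3,
                               association_with_exposure=_LN3),
            ),
            seed=seed,
        )
    elif name == "collinear_nonconfounder":
        spec = ScenarioSpec(
            n=5000,
            exposure_effect=_LN2,
            confounders=(
                ConfounderSpec("u1", effect_on_outcome=0.0,
                               association_with_exposure=2.0,
                               distribution="normal"),
            ),
            seed=seed,
        )
    elif name == "collinear_confounder":
        spec = ScenarioSpec(
            n=5000,
            exposure_effect=_LN2,
            confounders=(
                ConfounderSpec("u1", effect_on_outcome=0.7,
                               association_with_exposure=2.0,
                               distribution="normal"),
            ),
            seed=seed,
        )
    elif name == "sodium_potassium_like":
        spec = ScenarioSpec(
            n=5000,
            exposure_prevalence=None,
            exposure_effect=0.5,
            confounders=(
                ConfounderSpec("u1", effect_on_outcome=0.5,
                               association_with_exposure=0.81,
                               distribution="normal"),
            ),
            seed=seed,
        )
    else:  # atopy_like
        spec = ScenarioSpec(
            n=3000,
            baseline_risk=0.15,
            exposure_prevalence=0.4,
            exposure_effect=0.4,
            confounders=(
                ConfounderSpec("sex", effect_on_outcome=0.2, forced=True),
                ConfounderSpec("town", effect_on_outcome=_LN3,
                               association_with_exposure=1.5),
                ConfounderSpec("firstborn", effect_on_outcome=0.1),
                ConfounderSpec("smoker", effect_on_outcome=0.0,
                               association_with_exposure=0.2),
            ),
            seed=seed,
        )
    if n is not None:
        spec = replace(spec, n=n)
    return spec
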