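"""Selection-aware bootstrap for the exposure effect.

Model-based standard errors quoted after variable selection ignore the
selection step.  The bootstrap here resamples subject records with
replacement and reruns the *entire* procedure — selection included — on
every resample, so the spread of the resampled exposure coefficients
reflects both sampling and selection variability.  Intervals are percentile
or bias-corrected and accelerated (BCa); the BCa bias-correction constant
comes from the proportion of resample estimates below the point estimate
and the acceleration constant from jackknife influence values of the same
procedure.

A ``procedure`` is any callable mapping a :class:`~mse_select.data_model.ModelMatrix`
to the exposure log odds/rate-ratio estimate; :func:`fixed_roster_procedure`
and :func:`strategy_procedure` build the two common cases.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import AnalysisSpec, ModelMatrix, build_model_matrix
from .errors import ConfigurationError, ConvergenceAbort
from .fitting import fit_firth, fit_logF, fit_ml, PriorSpec
from .selection import run_strategy

logger = logging.getLogger(__name__)

DEFAULT_RESAMPLES = 4000  # matches the reporting convention this mirrors


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap summary for one procedure on one dataset.

    ``ci_lower``/``ci_upper`` are on the odds/rate-ratio scale for display;
    the log-scale limits are kept alongside.  ``n_failed`` counts resamples
    whose fit or selection failed; above 10% a warning is attached.
    """

    n_resamples: int
    seed: int
    point_estimate: float  # log scale
    coefficient_se: float
    ci_lower: float
    ci_upper: float
    ci_lower_log: float
    ci_upper_log: float
    method: str
    level: float
    n_failed: int
    warning: str | None = None


def fixed_roster_procedure(roster, method: str = "ml", prior: PriorSpec | None = None):
    """Procedure that always fits one fixed candidate roster."""
    roster = tuple(roster)

    def procedure(mm: ModelMatrix) -> float:
        design = mm.design(roster)
        if method == "firth":
            fit = fit_firth(design)
        elif method == "logF":
            fit = fit_logF(design, prior or PriorSpec())
        else:
            fit = fit_ml(design)
        if method == "ml" and not fit.converged:
            raise ConvergenceAbort("resample fit did not converge")
        return fit.coef(mm.spec.exposure_name)

    return procedure


def strategy_procedure(strategy: str, **options):
    """Procedure that reruns a full selection strategy and reports the
    exposure coefficient of the selected model."""

    def procedure(mm: ModelMatrix) -> float:
        trace = run_strategy(mm, strategy=strategy, **options)
        return trace.final_fit.coef(mm.spec.exposure_name)

    return procedure


def _resample_rng(seed: int, stream: int) -> np.random.Generator:
    # per-stream generators keyed by (seed, stream) so results do not depend
    # on execution order
    return np.random.default_rng([seed, stream])


def _bca_limits(thetas, theta_hat, jack, level):
    alpha = 1.0 - level
    B = len(thetas)
    prop = np.mean(thetas < theta_hat)
    prop = min(max(prop, 1.0 / (B + 1)), B / (B + 1.0))
    z0 = stats.norm.ppf(prop)
    jmean = jack.mean()
    d = jmean - jack
    denom = np.sum(d * d) ** 1.5
    a = 0.0 if denom == 0 else float(np.sum(d ** 3) / (6.0 * denom))
    out = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = stats.norm.ppf(q)
        adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
        out.append(float(np.quantile(thetas, stats.norm.cdf(adj), method="linear")))
    return out[0], out[1]


def bootstrap_procedure(
    dataset,
    spec: AnalysisSpec | None = None,
    procedure=None,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int = 0,
    method: str = "bca",
    level: float = 0.95,
) -> BootstrapResult:
    """Bootstrap SE and confidence limits for the exposure coefficient.

    Actual records are resampled with replacement (unstratified) and
    ``procedure`` is rerun on every resample.  Resamples where the selected
    roster differs from the original are kept as-is: that variability is the
    quantity being measured.
    """
    if n_resamples < 100:
        raise ConfigurationError("n_resamples must be at least 100")
    if method not in ("percentile", "bca"):
        raise ConfigurationError("method must be 'percentile' or 'bca'")
    if procedure is None:
        raise ConfigurationError("a procedure callable is required")
    mm = dataset if isinstance(dataset, ModelMatrix) else build_model_matrix(dataset, spec)
    actual_idx = np.flatnonzero(mm.is_actual)
    mm = mm.resample(actual_idx)
    n = mm.n

    theta_hat = procedure(mm)

    thetas = np.empty(n_resamples)
    n_failed = 0
    kept = 0
    for r in range(n_resamples):
        idx = _resample_rng(seed, r).integers(0, n, size=n)
        try:
            t = procedure(mm.resample(idx))
        except Exception:
            n_failed += 1
            continue
        if not math.isfinite(t):
            n_failed += 1
            continue
        thetas[kept] = t
        kept += 1
    if kept == 0:
        raise ConvergenceAbort("every bootstrap resample failed")
    thetas = thetas[:kept]

    warning = None
    if n_failed > n_resamples / 10:
        warning = (
            f"{n_failed}/{n_resamples} bootstrap resamples failed; "
            "interval may be unreliable"
        )
        warnings.warn(warning, stacklevel=2)

    se = float(np.std(thetas, ddof=1)) if kept > 1 else 0.0
    alpha = 1.0 - level
    if method == "percentile":
        lo = float(np.quantile(thetas, alpha / 2.0, method="linear"))
        hi = float(np.quantile(thetas, 1.0 - alpha / 2.0, method="linear"))
    else:
        jack = np.empty(n)
        all_rows = np.arange(n)
        ok = np.ones(n, dtype=bool)
        for i in range(n):
            rows = np.delete(all_rows, i)
            try:
                jack[i] = procedure(mm.resample(rows))
            except Exception:
                ok[i] = False
        jack = jack[ok]
        if len(jack) < 2:
            raise ConvergenceAbort("jackknife for the BCa acceleration failed")
        lo, hi = _bca_limits(thetas, theta_hat, jack, level)

    return BootstrapResult(
        n_resamples=n_resamples,
        seed=seed,
        point_estimate=float(theta_hat),
        coefficient_se=se,
        ci_lower=math.exp(lo),
        ci_upper=math.exp(hi),
        ci_lower_log=lo,
        ci_upper_log=hi,
        method=method,
        level=level,
        n_failed=n_failed,
        warning=warning,
    )
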