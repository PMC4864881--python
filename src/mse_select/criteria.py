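"""Bias, RMSE, ΔMSE and the collapsibility test for the exposure coefficient.

The accuracy currency throughout is the estimated mean squared error of the
exposure coefficient, MSE = B² + SE², where the bias B of a reduced model is
estimated against a referent (typically the full) model:

    ΔB      = β̂_reduced − β̂_referent
    Δ(SE²)  = SE_referent² − SE_reduced²
    ΔMSE    = (ΔB)² − Δ(SE²)
    RMSE    = sqrt((ΔB)² + SE_reduced²)

Deleting a covariate is harmless when ΔMSE < 0: the variance saved exceeds
the squared bias introduced.  When Δ(SE²) > 0 the same decision can be read
as a one-degree-of-freedom collapsibility test, χ²_c = (ΔB)²/Δ(SE²), since
ΔMSE > 0 ⇔ χ²_c > 1, i.e. retention corresponds to P < 0.32.  All
comparisons are on the log odds/rate-ratio scale; ratios are exponentiated
only for display.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import Dataset
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: |ΔB| > 10% of |β̂_referent| flags meaningful confounding (the classical
#: change-in-estimate convention); SE²_referent/SE²_reduced > 1.2 flags
#: strong collinearity.  Both are report annotations, not decision rules.
BIAS_FLAG_REL = 0.10
COLLINEAR_FLAG_RATIO = 1.2


@dataclass(frozen=True)
class ComparisonRecord:
    """ΔB / ΔMSE / collapsibility bundle for one reduced-vs-referent pair."""

    beta_reduced: float
    se_reduced: float
    beta_referent: float
    se_referent: float
    delta_b: float
    delta_se2: float
    delta_mse: float
    chi2: float | None
    p_value: float | None
    rmse_reduced: float
    indicates_bias: bool
    indicates_collinear: bool

    @property
    def drop_reduces_mse(self) -> bool:
        """True when the reduced model has the smaller estimated MSE."""
        return self.delta_mse < 0


def collapsibility_test(delta_b: float, delta_se2: float) -> tuple[float, float]:
    """One-df chi-squared test that covariate deletion leaves the exposure
    coefficient unchanged: χ² = (ΔB)²/Δ(SE²), upper-tail P on 1 df.

    Requires ``delta_se2 > 0`` (the deletion must reduce the variance for the
    statistic to be defined).
    """
    if delta_se2 <= 0:
        raise ConfigurationError(
            "collapsibility test requires a variance decrease (delta_se2 > 0)"
        )
    chi2 = delta_b * delta_b / delta_se2
    p_value = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p_value


def rmse(beta_hat: float, se: float, beta_referent: float) -> float:
    """Root of the estimated MSE of ``beta_hat`` against ``beta_referent``:
    sqrt((β̂ − β̂_ref)² + SE²)."""
    if se <= 0:
        raise ConfigurationError("se must be positive")
    bias = beta_hat - beta_referent
    return math.sqrt(bias * bias + se * se)


def compare_estimates(
    beta_reduced: float,
    se_reduced: float,
    beta_referent: float,
    se_referent: float,
) -> ComparisonRecord:
    """Assemble a :class:`ComparisonRecord` from raw coefficient summaries.

    When the deletion fails to shrink the SE (``Δ(SE²) ≤ 0``) the χ² and P
    are undefined and reported as ``None``; ΔMSE is then necessarily ≥ 0, so
    such a candidate is always retained.
    """
    delta_b = beta_reduced - beta_referent
    delta_se2 = se_referent * se_referent - se_reduced * se_reduced
    delta_mse = delta_b * delta_b - delta_se2
    if delta_se2 > 0:
        chi2, p_value = collapsibility_test(delta_b, delta_se2)
    elif delta_b == 0.0 and delta_se2 == 0.0:
        # nothing changed at all (e.g. a self-comparison): the no-change
        # hypothesis is trivially compatible
        chi2, p_value = 0.0, 1.0
    else:
        chi2, p_value = None, None
        logger.debug(
            "deletion did not reduce the exposure SE (delta_se2=%.3g); "
            "collapsibility test undefined, candidate retained",
            delta_se2,
        )
    indicates_bias = bool(
        abs(delta_b) > BIAS_FLAG_REL * abs(beta_referent)
        if beta_referent != 0
        else delta_b != 0
    )
    indicates_collinear = bool(
        se_referent * se_referent / (se_reduced * se_reduced) > COLLINEAR_FLAG_RATIO
    )
    return ComparisonRecord(
        beta_reduced=beta_reduced,
        se_reduced=se_reduced,
        beta_referent=beta_referent,
        se_referent=se_referent,
        delta_b=delta_b,
        delta_se2=delta_se2,
        delta_mse=delta_mse,
        chi2=chi2,
        p_value=p_value,
        rmse_reduced=rmse(beta_reduced, se_reduced, beta_referent),
        indicates_bias=indicates_bias,
        indicates_collinear=indicates_collinear,
    )


def compare(fit_reduced, fit_referent, exposure: str | None = None) -> ComparisonRecord:
    """Compare two fitted models on their exposure coefficient.

    ``fit_referent`` should be the designated standard (the full model, or
    the current larger model during selection).  Comparing a fit with itself
    yields ΔB = 0 and RMSE equal to its own SE.
    """
    exposure = exposure or fit_reduced.exposure
    if exposure is None:
        raise ConfigurationError("an exposure term label is required")
    for fit in (fit_reduced, fit_referent):
        if exposure not in fit.terms:
            raise ConfigurationError(
                f"exposure term {exposure!r} is absent from the fitted model"
            )
    return compare_estimates(
        beta_reduced=fit_reduced.coef(exposure),
        se_reduced=fit_reduced.se_of(exposure),
        beta_referent=fit_referent.coef(exposure),
        se_referent=fit_referent.se_of(exposure),
    )


@dataclass(frozen=True)
class SparseDataDiagnostic:
    """Subjects per exposure-outcome cell versus the 4-per-coefficient rule."""

    counts: dict  # (x, y) -> count
    threshold: float
    flagged: dict  # (x, y) -> bool
    skipped: bool = False
    note: str | None = None

    @property
    def any_flagged(self) -> bool:
        return any(self.flagged.values())


def sparse_data_check(
    dataset: Dataset, spec, n_confounder_terms: int
) -> SparseDataDiagnostic:
    """Check the rule of thumb that each cell of the 2×2 exposure-outcome
    table should hold at least about 4 subjects per confounder coefficient
    (e.g. 7 confounder terms → at least 28 subjects per cell) before the
    full-model ML estimate can be trusted to be free of sparse-data bias.

    Only defined for a binary exposure; otherwise the diagnostic is skipped
    with a note.
    """
    if n_confounder_terms < 0:
        raise ConfigurationError("n_confounder_terms must be non-negative")
    frame = dataset.frame.loc[dataset.is_actual]
    x = frame[spec.exposure_name].to_numpy()
    y = frame[spec.outcome_name].to_numpy()
    x_levels = np.unique(x)
    if len(x_levels) != 2 or not set(np.unique(x)) <= {0, 1}:
        return SparseDataDiagnostic(
            counts={},
            threshold=4.0 * n_confounder_terms,
            flagged={},
            skipped=True,
            note="sparse-data diagnostic requires a binary (0/1) exposure; skipped",
        )
    threshold = 4.0 * n_confounder_terms
    counts = {
        (xi, yi): int(np.sum((x == xi) & (y == yi)))
        for xi in (0, 1)
        for yi in (0, 1)
    }
    flagged = {
        cell: (n_confounder_terms > 0 and count < threshold)
        for cell, count in counts.items()
    }
    return SparseDataDiagnostic(counts=counts, threshold=threshold, flagged=flagged)
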