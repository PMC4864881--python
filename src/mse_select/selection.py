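"""Confounder-selection engines.

The headline strategy evaluates each candidate by the estimated change in
MSE of the exposure coefficient that its deletion (backward) or addition
(forward) would cause.  A single signed quantity drives both directions:

    D = (β̂_without − β̂_referent)² − (SE_referent² − SE_without²)

computed for the model *without* the candidate against a referent that
contains it.  Backward deletion drops the candidate with the most negative
D (deletion reduces MSE) and stops when every remaining D ≥ 0; forward
expansion adds the candidate with the largest positive D (its presence
reduces MSE) and stops when none remains positive.  The referent is either
the larger of the two models being compared (``larger_model``, the default)
or the initial full-model fit (``full_model``).

Comparator strategies from common practice are provided on the same
group-wise scaffolding: stepwise selection on joint Wald P-values, greedy
AIC/BIC search, and the relative change-in-estimate (CIE) rule.  Every
engine treats a categorical covariate's dummies as one atomic group, never
touches the exposure or forced terms, breaks ties by spec order, and logs
every evaluation in a :class:`SelectionTrace` so the selection path can be
audited and reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .criteria import ComparisonRecord, compare
from .data_model import AnalysisSpec, ModelMatrix, build_model_matrix
from .errors import ConfigurationError, ConvergenceAbort
from .fitting import FitResult, fit_firth, fit_ml

logger = logging.getLogger(__name__)

STRATEGIES = (
    "mse_backward",
    "mse_forward",
    "stepwise_p",
    "stepwise_aic",
    "stepwise_bic",
    "cie",
)
REFERENT_MODES = ("larger_model", "full_model")


@dataclass(frozen=True)
class SelectionStep:
    """One candidate evaluation or move inside a selection loop."""

    index: int
    candidate: str
    action: str  # dropped | added | kept | skipped
    comparison: ComparisonRecord | None = None
    statistic: float | None = None  # engine-specific: ΔMSE, P, ΔIC, rel. change
    detail: str | None = None


@dataclass
class SelectionTrace:
    """Ordered audit log of a selection run plus its outcome."""

    strategy: str
    referent_mode: str | None
    steps: list[SelectionStep] = field(default_factory=list)
    final_roster: tuple[str, ...] = ()
    final_fit: FitResult | None = None

    def record(self, **kwargs) -> None:
        self.steps.append(SelectionStep(index=len(self.steps), **kwargs))

    @property
    def n_evaluations(self) -> int:
        return len(self.steps)


class _FitCache:
    """Memoize ML fits per roster within one engine run."""

    def __init__(self, mm: ModelMatrix):
        self.mm = mm
        self._cache: dict[frozenset, FitResult] = {}

    def fit(self, roster) -> FitResult:
        key = frozenset(roster)
        hit = self._cache.get(key)
        if hit is None:
            hit = fit_ml(self.mm.design(key))
            self._cache[key] = hit
        return hit


def _as_matrix(dataset, spec) -> ModelMatrix:
    if isinstance(dataset, ModelMatrix):
        return dataset
    return build_model_matrix(dataset, spec)


def _check_full_model(fit: FitResult, message: str) -> None:
    if not fit.converged:
        raise ConvergenceAbort(message)


_FULL_ABORT_ADVICE = (
    "the full model did not converge; switch to a forward-selection "
    "strategy, or use penalized (Firth or log-F) fitting"
)


def _mse_of_deletion(cache, roster_without, referent_fit, exposure) -> ComparisonRecord:
    fit_without = cache.fit(roster_without)
    return compare(fit_without, referent_fit, exposure)


def select_backward_mse(
    dataset,
    spec: AnalysisSpec | None = None,
    referent_mode: str = "larger_model",
) -> SelectionTrace:
    """Backward deletion by estimated-MSE reduction.

    Starting from the full model, each remaining candidate is removed in
    turn; the candidate whose deletion lowers the estimated MSE of the
    exposure coefficient the most (most negative ΔMSE) is dropped, and the
    loop repeats until no deletion reduces the MSE.
    """
    if referent_mode not in REFERENT_MODES:
        raise ConfigurationError(f"referent_mode must be one of {REFERENT_MODES}")
    mm = _as_matrix(dataset, spec)
    spec = mm.spec
    exposure = spec.exposure_name
    cache = _FitCache(mm)
    trace = SelectionTrace(strategy="mse_backward", referent_mode=referent_mode)

    full_fit = cache.fit(spec.candidates)
    _check_full_model(full_fit, _FULL_ABORT_ADVICE)

    current = list(spec.candidates)
    while current:
        current_fit = cache.fit(current)
        referent_fit = current_fit if referent_mode == "larger_model" else full_fit
        evaluations: list[tuple[str, ComparisonRecord]] = []
        for name in current:
            reduced = [c for c in current if c != name]
            try:
                rec = _mse_of_deletion(cache, reduced, referent_fit, exposure)
            except Exception as exc:  # mid-loop refit failure: retain, log
                logger.warning("refit without %r failed (%s); candidate kept", name, exc)
                trace.record(candidate=name, action="skipped", detail=str(exc))
                continue
            fit_without = cache.fit(reduced)
            if not fit_without.converged:
                trace.record(
                    candidate=name, action="skipped",
                    detail="reduced model did not converge",
                )
                continue
            evaluations.append((name, rec))
        droppable = [(n, r) for n, r in evaluations if r.delta_mse < 0]
        if not droppable:
            for name, rec in evaluations:
                trace.record(
                    candidate=name, action="kept",
                    comparison=rec, statistic=rec.delta_mse,
                )
            break
        # most negative ΔMSE; ties go to the earliest candidate in spec order
        best = min(droppable, key=lambda t: (t[1].delta_mse, spec.candidates.index(t[0])))
        for name, rec in evaluations:
            action = "dropped" if name == best[0] else "kept"
            trace.record(
                candidate=name, action=action,
                comparison=rec, statistic=rec.delta_mse,
            )
        current.remove(best[0])

    trace.final_roster = tuple(current)
    trace.final_fit = cache.fit(current)
    return trace


def select_forward_mse(
    dataset,
    spec: AnalysisSpec | None = None,
    referent_mode: str = "larger_model",
) -> SelectionTrace:
    """Forward expansion by estimated-MSE reduction (mirror of backward).

    Starting from the minimal model (exposure + forced terms), the candidate
    whose *absence* costs the most estimated MSE — i.e. with the largest
    positive ΔMSE of the current model relative to the expanded referent —
    is added; the loop stops when no addition reduces the MSE.
    """
    if referent_mode not in REFERENT_MODES:
        raise ConfigurationError(f"referent_mode must be one of {REFERENT_MODES}")
    mm = _as_matrix(dataset, spec)
    spec = mm.spec
    exposure = spec.exposure_name
    cache = _FitCache(mm)
    trace = SelectionTrace(strategy="mse_forward", referent_mode=referent_mode)

    minimal_fit = cache.fit(())
    _check_full_model(
        minimal_fit, "the minimal model must converge for forward selection"
    )
    full_fit = None
    if referent_mode == "full_model":
        full_fit = cache.fit(spec.candidates)
        if not full_fit.converged:
            raise ConvergenceAbort(
                "full-model referent requested but the full model does not converge; "
                "use referent_mode='larger_model'"
            )

    current: list[str] = []
    remaining = list(spec.candidates)
    while remaining:
        current_fit = cache.fit(current)
        evaluations: list[tuple[str, ComparisonRecord]] = []
        for name in remaining:
            expanded = current + [name]
            try:
                expanded_fit = cache.fit(expanded)
            except Exception as exc:
                logger.warning("fit with %r failed (%s); candidate skipped", name, exc)
                trace.record(candidate=name, action="skipped", detail=str(exc))
                continue
            if not expanded_fit.converged:
                trace.record(
                    candidate=name, action="skipped",
                    detail="expanded model did not converge",
                )
                continue
            referent_fit = expanded_fit if referent_mode == "larger_model" else full_fit
            rec = compare(current_fit, referent_fit, exposure)
            evaluations.append((name, rec))
        addable = [(n, r) for n, r in evaluations if r.delta_mse > 0]
        if not addable:
            for name, rec in evaluations:
                trace.record(
                    candidate=name, action="kept",
                    comparison=rec, statistic=rec.delta_mse,
                )
            break
        best = max(addable, key=lambda t: (t[1].delta_mse, -spec.candidates.index(t[0])))
        for name, rec in evaluations:
            action = "added" if name == best[0] else "kept"
            trace.record(
                candidate=name, action=action,
                comparison=rec, statistic=rec.delta_mse,
            )
        current.append(best[0])
        remaining.remove(best[0])

    trace.final_roster = tuple(c for c in spec.candidates if c in current)
    trace.final_fit = cache.fit(current)
    return trace


def _group_wald_p(fit: FitResult, mm: ModelMatrix, name: str) -> float:
    """Joint Wald test of all terms of candidate group ``name`` in ``fit``."""
    term_labels = [mm.columns[i] for i in mm.groups[name]]
    idx = [fit.terms.index(t) for t in term_labels]
    beta = fit.params[idx]
    cov = fit.cov_of(idx)
    try:
        stat = float(beta @ np.linalg.solve(cov, beta))
    except np.linalg.LinAlgError:
        stat = float(beta @ np.linalg.pinv(cov) @ beta)
    return float(stats.chi2.sf(stat, df=len(idx)))


def select_stepwise_p(
    dataset,
    spec: AnalysisSpec | None = None,
    direction: str = "forward",
    alpha: float = 0.20,
) -> SelectionTrace:
    """Classical stepwise selection on group Wald P-values.

    Forward: add the candidate with the smallest joint-Wald P below
    ``alpha``.  Backward: drop the candidate with the largest P at or above
    ``alpha``.  The exposure and forced terms are never tested.
    """
    if not 0.0 < alpha <= 1.0:
        raise ConfigurationError("alpha must be in (0, 1]")
    if direction not in ("forward", "backward"):
        raise ConfigurationError("direction must be 'forward' or 'backward'")
    mm = _as_matrix(dataset, spec)
    spec = mm.spec
    cache = _FitCache(mm)
    trace = SelectionTrace(strategy="stepwise_p", referent_mode=None)

    if direction == "backward":
        current = list(spec.candidates)
        _check_full_model(cache.fit(current), _FULL_ABORT_ADVICE)
        while current:
            fit = cache.fit(current)
            pvals = [(name, _group_wald_p(fit, mm, name)) for name in current]
            removable = [(n, p) for n, p in pvals if p >= alpha]
            if not removable:
                for name, p in pvals:
                    trace.record(candidate=name, action="kept", statistic=p)
                break
            worst = max(removable, key=lambda t: (t[1], -spec.candidates.index(t[0])))
            for name, p in pvals:
                action = "dropped" if name == worst[0] else "kept"
                trace.record(candidate=name, action=action, statistic=p)
            current.remove(worst[0])
    else:
        current = []
        remaining = list(spec.candidates)
        while remaining:
            pvals = []
            for name in remaining:
                fit = cache.fit(current + [name])
                if not fit.converged:
                    trace.record(candidate=name, action="skipped",
                                 detail="model did not converge")
                    continue
                pvals.append((name, _group_wald_p(fit, mm, name)))
            addable = [(n, p) for n, p in pvals if p < alpha]
            if not addable:
                for name, p in pvals:
                    trace.record(candidate=name, action="kept", statistic=p)
                break
            best = min(addable, key=lambda t: (t[1], spec.candidates.index(t[0])))
            for name, p in pvals:
                action = "added" if name == best[0] else "kept"
                trace.record(candidate=name, action=action, statistic=p)
            current.append(best[0])
            remaining.remove(best[0])

    trace.final_roster = tuple(c for c in spec.candidates if c in current)
    trace.final_fit = cache.fit(current)
    return trace


def select_stepwise_ic(
    dataset,
    spec: AnalysisSpec | None = None,
    direction: str = "forward",
    criterion: str = "aic",
) -> SelectionTrace:
    """Greedy stepwise search minimizing AIC or BIC.

    At each step the single add (forward) or drop (backward) giving the
    largest criterion improvement is taken; the loop stops when no move
    improves the criterion.
    """
    if criterion not in ("aic", "bic"):
        raise ConfigurationError("criterion must be 'aic' or 'bic'")
    if direction not in ("forward", "backward"):
        raise ConfigurationError("direction must be 'forward' or 'backward'")
    mm = _as_matrix(dataset, spec)
    spec = mm.spec
    cache = _FitCache(mm)
    trace = SelectionTrace(strategy=f"stepwise_{criterion}", referent_mode=None)
    ic = lambda fit: getattr(fit, criterion)

    if direction == "backward":
        current = list(spec.candidates)
        _check_full_model(cache.fit(current), _FULL_ABORT_ADVICE)
        moves = lambda cur: [([c for c in cur if c != n], n) for n in cur]
    else:
        current = []
        moves = lambda cur: [
            (cur + [n], n) for n in spec.candidates if n not in cur
        ]

    while True:
        candidates_now = moves(current)
        if not candidates_now:
            break
        base_ic = ic(cache.fit(current))
        deltas = []
        for roster, name in candidates_now:
            fit = cache.fit(roster)
            if not fit.converged:
                trace.record(candidate=name, action="skipped",
                             detail="model did not converge")
                continue
            deltas.append((name, roster, ic(fit) - base_ic))
        improving = [(n, r, d) for n, r, d in deltas if d < 0]
        if not improving:
            for name, _, d in deltas:
                trace.record(candidate=name, action="kept", statistic=d)
            break
        best = min(improving, key=lambda t: (t[2], spec.candidates.index(t[0])))
        for name, _, d in deltas:
            action = (
                ("dropped" if direction == "backward" else "added")
                if name == best[0] else "kept"
            )
            trace.record(candidate=name, action=action, statistic=d)
        current = best[1]

    trace.final_roster = tuple(c for c in spec.candidates if c in current)
    trace.final_fit = cache.fit(current)
    return trace


def _rel_change(beta_new: float, beta_old: float) -> float:
    """Relative change of the exposure odds/rate ratio: |exp(Δβ) − 1|."""
    return abs(math.exp(beta_new - beta_old) - 1.0)


def select_cie(
    dataset,
    spec: AnalysisSpec | None = None,
    direction: str = "forward",
    rel_threshold: float = 0.10,
) -> SelectionTrace:
    """Change-in-estimate selection on the exposure ratio scale.

    Forward: repeatedly add the candidate whose inclusion changes the
    exposure odds/rate ratio the most, as long as that change exceeds
    ``rel_threshold``.  Backward: repeatedly drop the candidate whose
    removal changes it least, as long as that change stays within the
    threshold.
    """
    if rel_threshold <= 0:
        raise ConfigurationError("rel_threshold must be positive")
    if direction not in ("forward", "backward"):
        raise ConfigurationError("direction must be 'forward' or 'backward'")
    mm = _as_matrix(dataset, spec)
    spec = mm.spec
    exposure = spec.exposure_name
    cache = _FitCache(mm)
    trace = SelectionTrace(strategy="cie", referent_mode=None)

    if direction == "backward":
        current = list(spec.candidates)
        _check_full_model(cache.fit(current), _FULL_ABORT_ADVICE)
        while current:
            base = cache.fit(current).coef(exposure)
            changes = []
            for name in current:
                fit = cache.fit([c for c in current if c != name])
                changes.append((name, _rel_change(fit.coef(exposure), base)))
            removable = [(n, c) for n, c in changes if c <= rel_threshold]
            if not removable:
                for name, c in changes:
                    trace.record(candidate=name, action="kept", statistic=c)
                break
            least = min(removable, key=lambda t: (t[1], spec.candidates.index(t[0])))
            for name, c in changes:
                action = "dropped" if name == least[0] else "kept"
                trace.record(candidate=name, action=action, statistic=c)
            current.remove(least[0])
    else:
        current = []
        remaining = list(spec.candidates)
        while remaining:
            base = cache.fit(current).coef(exposure)
            changes = []
            for name in remaining:
                fit = cache.fit(current + [name])
                if not fit.converged:
                    trace.record(candidate=name, action="skipped",
                                 detail="model did not converge")
                    continue
                changes.append((name, _rel_change(fit.coef(exposure), base)))
            addable = [(n, c) for n, c in changes if c > rel_threshold]
            if not addable:
                for name, c in changes:
                    trace.record(candidate=name, action="kept", statistic=c)
                break
            best = max(addable, key=lambda t: (t[1], -spec.candidates.index(t[0])))
            for name, c in changes:
                action = "added" if name == best[0] else "kept"
                trace.record(candidate=name, action=action, statistic=c)
            current.append(best[0])
            remaining.remove(best[0])

    trace.final_roster = tuple(c for c in spec.candidates if c in current)
    trace.final_fit = cache.fit(current)
    return trace


def exhaustive_best_roster(
    dataset,
    spec: AnalysisSpec | None = None,
    bias_referent: str = "ml_full",
) -> tuple[tuple[str, ...], float]:
    """Exhaustive search over all candidate subsets minimizing the estimated
    RMSE of the exposure coefficient against the full-model referent.

    Intended as a small-H oracle for validating the greedy engines (cost is
    2^H fits), not as a production strategy.
    """
    mm = _as_matrix(dataset, spec)
    spec = mm.spec
    H = len(spec.candidates)
    if H > 12:
        raise ConfigurationError("exhaustive search is limited to H <= 12 candidates")
    cache = _FitCache(mm)
    if bias_referent == "firth_full":
        referent_fit = fit_firth(mm.design(spec.candidates))
    else:
        referent_fit = cache.fit(spec.candidates)
    best_roster, best_rmse = None, math.inf
    for mask in range(2 ** H):
        roster = tuple(
            c for i, c in enumerate(spec.candidates) if mask >> i & 1
        )
        fit = cache.fit(roster)
        if not fit.converged:
            continue
        rec = compare(fit, referent_fit, spec.exposure_name)
        if rec.rmse_reduced < best_rmse:
            best_roster, best_rmse = roster, rec.rmse_reduced
    return best_roster, best_rmse


def heterogeneity_report(dataset, spec: AnalysisSpec, covariates, roster=None):
    """Post-hoc assessment of effect-measure modification.

    For each named covariate, refit the selected model with
    exposure-by-covariate product terms added and report the joint Wald test
    of the products.  This is reporting only — heterogeneity is never a
    selection criterion.
    """
    mm = _as_matrix(dataset, spec)
    roster = tuple(roster if roster is not None else spec.candidates)
    base = mm.design(roster)
    out = {}
    exposure_col = list(base.columns).index(spec.exposure_name)
    for name in covariates:
        if name not in mm.groups:
            raise ConfigurationError(f"unknown covariate {name!r}")
        term_labels = [mm.columns[i] for i in mm.groups[name]]
        missing = [t for t in term_labels if t not in base.columns]
        if missing:
            raise ConfigurationError(
                f"covariate {name!r} is not in the fitted model; add it to the roster"
            )
        prod_cols, prod_labels = [], []
        for t in term_labels:
            j = list(base.columns).index(t)
            prod_cols.append(base.X[:, exposure_col] * base.X[:, j])
            prod_labels.append(f"{spec.exposure_name}:{t}")
        from .data_model import Design

        design = Design(
            X=np.column_stack([base.X, *[c[:, None] for c in prod_cols]]),
            columns=tuple([*base.columns, *prod_labels]),
            y=base.y,
            weights=base.weights,
            is_actual=base.is_actual,
            family=base.family,
            exposure=base.exposure,
            roster=base.roster,
        )
        fit = fit_ml(design)
        idx = [fit.terms.index(t) for t in prod_labels]
        beta = fit.params[idx]
        cov = fit.cov_of(idx)
        try:
            stat = float(beta @ np.linalg.solve(cov, beta))
        except np.linalg.LinAlgError:
            stat = float(beta @ np.linalg.pinv(cov) @ beta)
        out[name] = {
            "chi2": stat,
            "df": len(idx),
            "p_value": float(stats.chi2.sf(stat, df=len(idx))),
            "product_terms": {t: fit.coef(t) for t in prod_labels},
        }
    return out


def run_strategy(
    dataset,
    spec: AnalysisSpec | None = None,
    strategy: str = "mse_backward",
    **options,
) -> SelectionTrace:
    """Dispatch one selection run by strategy name (CLI names accepted)."""
    name = strategy.replace("-", "_")
    mm = _as_matrix(dataset, spec)
    if name == "mse_backward":
        return select_backward_mse(mm, referent_mode=options.get("referent_mode", "larger_model"))
    if name == "mse_forward":
        return select_forward_mse(mm, referent_mode=options.get("referent_mode", "larger_model"))
    if name == "stepwise_p":
        return select_stepwise_p(
            mm,
            direction=options.get("direction", "forward"),
            alpha=options.get("alpha", 0.20),
        )
    if name in ("stepwise_aic", "stepwise_bic"):
        return select_stepwise_ic(
            mm,
            direction=options.get("direction", "forward"),
            criterion=name.removeprefix("stepwise_"),
        )
    if name == "cie":
        return select_cie(
            mm,
            direction=options.get("direction", "forward"),
            rel_threshold=options.get("rel_threshold", 0.10),
        )
    raise ConfigurationError(
        f"unknown strategy {strategy!r}; expected one of {STRATEGIES}"
    )
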