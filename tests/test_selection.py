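import math

import numpy as np
import pytest

from mse_select import (
    AnalysisSpec,
    ConfigurationError,
    ConfounderSpec,
    ConvergenceAbort,
    ScenarioSpec,
    analysis_spec,
    build_model_matrix,
    compare,
    dataset_from_frame,
    exhaustive_best_roster,
    fit_ml,
    generate,
    run_strategy,
    select_backward_mse,
    select_cie,
    select_forward_mse,
    select_stepwise_ic,
    select_stepwise_p,
)
from mse_select.selection import _group_wald_p

LN2, LN3 = math.log(2), math.log(3)


def _matrix(toy_frame, toy_spec):
    return build_model_matrix(dataset_from_frame(toy_frame, toy_spec), toy_spec)


def _confounder_matrix(seed, n=3000):
    sc = ScenarioSpec(
        n=n, exposure_effect=LN2, seed=seed,
        confounders=(ConfounderSpec("u1", effect_on_outcome=LN3,
                                    association_with_exposure=LN3),),
    )
    ds = generate(sc)
    return build_model_matrix(ds, analysis_spec(sc))


ALL_ENGINES = [
    ("mse_backward", {}),
    ("mse_forward", {}),
    ("stepwise_p", {}),
    ("stepwise_aic", {}),
    ("stepwise_bic", {}),
    ("cie", {}),
]


class TestStructuralProperties:
    def test_empty_candidate_list_returns_minimal_model(self, toy_frame):
        spec = AnalysisSpec(outcome_name="y", exposure_name="x", forced=("w1",))
        mm = build_model_matrix(
            dataset_from_frame(toy_frame[["y", "x", "w1"]], spec), spec
        )
        for strategy, opts in ALL_ENGINES:
            trace = run_strategy(mm, strategy=strategy, **opts)
            assert trace.final_roster == ()
            assert trace.steps == []

    @pytest.mark.parametrize("strategy,opts", ALL_ENGINES)
    def test_forced_and_exposure_never_in_trace(self, toy_frame, toy_spec,
                                                strategy, opts):
        mm = _matrix(toy_frame, toy_spec)
        trace = run_strategy(mm, strategy=strategy, **opts)
        touched = {s.candidate for s in trace.steps}
        assert "w1" not in touched and "x" not in touched
        assert set(trace.final_roster) <= set(toy_spec.candidates)
        assert {"x", "w1"} <= {t.split("=")[0] for t in trace.final_fit.terms}

    @pytest.mark.parametrize("strategy,opts", ALL_ENGINES)
    def test_deterministic_reruns(self, toy_frame, toy_spec, strategy, opts):
        mm = _matrix(toy_frame, toy_spec)
        t1 = run_strategy(mm, strategy=strategy, **opts)
        t2 = run_strategy(mm, strategy=strategy, **opts)
        assert t1.final_roster == t2.final_roster
        assert [(s.candidate, s.action, s.statistic) for s in t1.steps] == [
            (s.candidate, s.action, s.statistic) for s in t2.steps
        ]
        np.testing.assert_array_equal(t1.final_fit.params, t2.final_fit.params)

    def test_backward_drop_decision_matches_collapsibility_threshold(
        self, toy_frame, toy_spec
    ):
        """A candidate is droppable (ΔMSE < 0) iff its collapsibility χ² < 1
        whenever the deletion reduced the exposure variance."""
        mm = _matrix(toy_frame, toy_spec)
        trace = select_backward_mse(mm)
        checked = 0
        for step in trace.steps:
            rec = step.comparison
            if rec is None or rec.chi2 is None:
                continue
            assert (rec.delta_mse < 0) == (rec.chi2 < 1)
            checked += 1
        assert checked > 0

    def test_abort_when_full_model_is_separated(self):
        import pandas as pd

        n = 40
        rng = np.random.default_rng(8)
        x = rng.binomial(1, 0.5, n)
        u = np.arange(n) % 2
        y = u.copy()  # u separates y perfectly
        frame = pd.DataFrame({"y": y, "x": x, "u1": u, "u2": rng.standard_normal(n)})
        spec = AnalysisSpec(outcome_name="y", exposure_name="x",
                            candidates=("u1", "u2"))
        mm = build_model_matrix(dataset_from_frame(frame, spec), spec)
        with pytest.warns(Warning):
            with pytest.raises(ConvergenceAbort, match="forward|penalized"):
                select_backward_mse(mm)


class TestMseEngines:
    def test_referent_mode_validation(self, toy_frame, toy_spec):
        mm = _matrix(toy_frame, toy_spec)
        with pytest.raises(ConfigurationError):
            select_backward_mse(mm, referent_mode="other")

    def test_strong_confounder_is_kept_backward(self):
        mm = _confounder_matrix(seed=0, n=5000)
        trace = select_backward_mse(mm)
        assert "u1" in trace.final_roster

    def test_strong_confounder_enters_first_forward(self):
        entered_first = 0
        for r in range(20):
            mm = _confounder_matrix(seed=300 + r, n=3000)
            trace = select_forward_mse(mm)
            added = [s.candidate for s in trace.steps if s.action == "added"]
            if added and added[0] == "u1":
                entered_first += 1
        assert entered_first >= 19

    def test_null_candidates_nothing_added_forward(self):
        # no candidate shifts the coefficient or reduces its SE materially
        sc = ScenarioSpec(
            n=4000, exposure_effect=LN2, seed=5,
            confounders=(ConfounderSpec("u1"), ConfounderSpec("u2")),
        )
        mm = build_model_matrix(generate(sc), analysis_spec(sc))
        trace = select_forward_mse(mm)
        # pure-noise additions rarely help; at this seed none does
        assert trace.final_roster == ()

    def test_collinear_nonconfounder_dropped_at_theoretical_rate(self):
        """Dropping happens when the collapsibility χ² < 1; under the null of
        no confounding that event has probability P(χ²₁ < 1) ≈ 0.68, so the
        drop rate over replicates should sit near 0.68 — while a strong true
        confounder in the same model is essentially always retained."""
        drop_u = keep_z = 0
        R = 60
        for r in range(R):
            sc = ScenarioSpec(
                n=3000, exposure_effect=LN2, seed=1000 + r,
                confounders=(
                    ConfounderSpec("z", effect_on_outcome=LN3,
                                   association_with_exposure=LN3),
                    ConfounderSpec("u", association_with_exposure=2.0,
                                   distribution="normal"),
                ),
            )
            mm = build_model_matrix(generate(sc), analysis_spec(sc))
            trace = select_backward_mse(mm)
            drop_u += "u" not in trace.final_roster
            keep_z += "z" in trace.final_roster
        assert keep_z / R >= 0.95
        assert 0.50 <= drop_u / R <= 0.85

    def test_forward_backward_agree_single_candidate(self):
        for seed in range(5):
            mm = _confounder_matrix(seed=seed, n=1500)
            fwd = select_forward_mse(mm)
            bwd = select_backward_mse(mm)
            # with one candidate both directions evaluate the same two models
            d_fwd = fwd.steps[0].comparison.delta_mse
            d_bwd = bwd.steps[0].comparison.delta_mse
            assert d_fwd == pytest.approx(d_bwd)
            assert fwd.final_roster == bwd.final_roster


class TestComparatorEngines:
    def test_backward_alpha_one_drops_nothing(self, toy_frame, toy_spec):
        mm = _matrix(toy_frame, toy_spec)
        trace = select_stepwise_p(mm, direction="backward", alpha=1.0)
        assert set(trace.final_roster) == set(toy_spec.candidates)

    def test_forward_tiny_alpha_adds_nothing(self, toy_frame, toy_spec):
        mm = _matrix(toy_frame, toy_spec)
        trace = select_stepwise_p(mm, direction="forward", alpha=1e-12)
        assert trace.final_roster == ()

    def test_single_candidate_retention_equals_wald_decision(self):
        for seed, alpha in [(0, 0.05), (1, 0.20), (2, 0.50)]:
            mm = _confounder_matrix(seed=seed, n=800)
            fit = fit_ml(mm.design(("u1",)))
            p = _group_wald_p(fit, mm, "u1")
            trace = select_stepwise_p(mm, direction="forward", alpha=alpha)
            assert (("u1",) == trace.final_roster) == (p < alpha)

    def test_bic_roster_nested_in_aic_roster_forward(self):
        # equal-df candidates: both criteria rank moves identically and the
        # ln(n) > 2 penalty makes BIC stop no later than AIC
        for seed in range(6):
            sc = ScenarioSpec(
                n=1200, exposure_effect=LN2, seed=700 + seed,
                confounders=(
                    ConfounderSpec("u1", effect_on_outcome=0.6,
                                   association_with_exposure=0.6),
                    ConfounderSpec("u2", effect_on_outcome=0.3),
                    ConfounderSpec("u3"),
                ),
            )
            mm = build_model_matrix(generate(sc), analysis_spec(sc))
            aic = select_stepwise_ic(mm, direction="forward", criterion="aic")
            bic = select_stepwise_ic(mm, direction="forward", criterion="bic")
            assert set(bic.final_roster) <= set(aic.final_roster)

    def test_noise_candidate_dropped_by_both_criteria(self):
        sc = ScenarioSpec(
            n=4000, exposure_effect=LN2, seed=17,
            confounders=(ConfounderSpec("u1"),),
        )
        mm = build_model_matrix(generate(sc), analysis_spec(sc))
        for criterion in ("aic", "bic"):
            trace = select_stepwise_ic(mm, direction="backward", criterion=criterion)
            assert trace.final_roster == ()

    def test_cie_huge_threshold_adds_nothing(self, toy_frame, toy_spec):
        mm = _matrix(toy_frame, toy_spec)
        trace = select_cie(mm, direction="forward", rel_threshold=1e9)
        assert trace.final_roster == ()

    def test_cie_retains_confounder_changing_ratio_20_percent(self):
        mm = _confounder_matrix(seed=3, n=5000)
        base = fit_ml(mm.design(())).coef("x")
        adj = fit_ml(mm.design(("u1",))).coef("x")
        assert abs(math.exp(base - adj) - 1) > 0.20  # scenario premise
        for direction in ("forward", "backward"):
            trace = select_cie(mm, direction=direction, rel_threshold=0.10)
            assert trace.final_roster == ("u1",)


class TestExhaustiveOracle:
    @staticmethod
    def _h3_matrix(seed, n=150):
        sc = ScenarioSpec(
            n=n, baseline_risk=0.2, exposure_effect=0.5, collinearity_r=0.5,
            seed=seed,
            confounders=(
                ConfounderSpec("u1", effect_on_outcome=0.8,
                               association_with_exposure=0.8),
                ConfounderSpec("u2", effect_on_outcome=0.5,
                               association_with_exposure=1.0,
                               distribution="normal"),
                ConfounderSpec("u3", association_with_exposure=1.2,
                               distribution="normal"),
            ),
        )
        return build_model_matrix(generate(sc), analysis_spec(sc))

    def test_greedy_never_beats_exhaustive_search(self):
        for seed in range(8):
            mm = self._h3_matrix(seed)
            _, best = exhaustive_best_roster(mm)
            full = fit_ml(mm.design(mm.spec.candidates))
            for strategy in ("mse_backward", "mse_forward"):
                for mode in ("larger_model", "full_model"):
                    trace = run_strategy(mm, strategy=strategy, referent_mode=mode)
                    rec = compare(trace.final_fit, full, "x")
                    assert rec.rmse_reduced >= best - 1e-9

    def test_greedy_can_be_strictly_suboptimal(self):
        """One-at-a-time selection need not find the subset with the overall
        smallest estimated MSE; this fixture exhibits a strict gap."""
        mm = self._h3_matrix(seed=1)
        best_roster, best = exhaustive_best_roster(mm)
        full = fit_ml(mm.design(mm.spec.candidates))
        trace = run_strategy(mm, strategy="mse_backward", referent_mode="full_model")
        rec = compare(trace.final_fit, full, "x")
        assert rec.rmse_reduced > best + 1e-3
        assert tuple(trace.final_roster) != tuple(best_roster)
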