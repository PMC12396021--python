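"""Tests of the in-silico experiments: paired scenario ensembles,
stratified summaries, viability windows, perturbation populations,
sensitivity, and the golden-hour analysis."""

import math

import numpy as np
import pandas as pd
import pytest

from beclin_duality import (ParameterSet, duration_threshold,
                            intervention_panel, local_sensitivity,
                            perturbation_experiment, stratified_apoptosis,
                            viability_window)
from beclin_duality import experiments
from beclin_duality.experiments import NonContiguousSurvivalError


class TestScenarioRun:
    def test_wild_type_fraction_in_expected_range(self, eight_scenario_run):
        """~89% of stressed wild-type variants are apoptotic; at n ~ 500
        the binomial 3-sigma band is about +/- 4 points."""
        wt = eight_scenario_run.result("wild-type")
        assert 0.84 < wt.fraction < 0.94
        lo, hi = wt.ci
        assert lo < wt.fraction < hi

    def test_every_protection_reduces_apoptosis(self, eight_scenario_run):
        """Each mechanism knockout and the saturation relief lowers the
        apoptotic fraction relative to wild type."""
        f = eight_scenario_run.fractions()
        for name, frac in f.items():
            if name != "wild-type":
                assert frac < f["wild-type"], name

    def test_paired_knockouts_rarely_sensitize(self, eight_scenario_run):
        """On the same variants, a knockout's apoptotic set is almost a
        subset of the wild-type one (< 1% of variants flip towards
        death)."""
        att = eight_scenario_run.attribution("wild-type")
        n = len(eight_scenario_run.outcomes)
        for name, row in att.iterrows():
            if name == "wild-type":
                continue
            assert row["sensitized"] / n < 0.01, name

    def test_attribution_is_exact_bookkeeping(self, eight_scenario_run):
        att = eight_scenario_run.attribution("wild-type")
        n = len(eight_scenario_run.outcomes)
        f = eight_scenario_run.fractions()
        for name, row in att.iterrows():
            net = (row["sensitized"] - row["rescued"]) / n
            assert net == pytest.approx(f[name] - f["wild-type"],
                                        abs=1e-12)

    def test_exclusions_are_shared_across_scenarios(self,
                                                    eight_scenario_run):
        run = eight_scenario_run
        assert run.n_total == len(run.outcomes) + len(run.excluded)
        assert all(r.n == len(run.outcomes) for r in run.results)
        # saturation-relieved scenarios have no flux-saturated variants
        assert run.degenerate_counts["no-saturation"] == 0

    def test_unstressed_ensemble_mostly_survives(self, small_ensemble):
        """Forcing S = 0 keeps every non-degenerate variant that rests
        on the survival branch alive."""
        ens = small_ensemble
        df = ens.variants.copy()
        df["S"] = 0.0
        from beclin_duality.ensemble import VariantEnsemble
        run = experiments.scenario_fractions(
            VariantEnsemble(variants=df, seed=ens.seed),
            scenarios=experiments.CANONICAL_SCENARIOS[:1])
        resting_high = [
            i for i in range(ens.n)
            if i not in run.excluded and _rests_apoptotic(ens, i)]
        wt = run.result("wild-type")
        assert wt.n_apoptotic == len(resting_high)


def _rests_apoptotic(ens, i):
    from beclin_duality import unstressed_steady_state, \
        DegenerateVariantError
    try:
        y = unstressed_steady_state(ens.parameter_set(i))
    except DegenerateVariantError:
        return False
    return y[4] > 0.5


class TestStratified:
    def test_table_shape_and_missing_cells(self, eight_scenario_run):
        run = eight_scenario_run
        tab = stratified_apoptosis(run.variants,
                                   run.outcomes["wild-type"], bins=6)
        assert tab.index.name == "stress_band"
        assert set(tab.index) <= {"mild", "moderate", "severe", "extreme"}
        assert ((tab.fillna(0) >= 0) & (tab.fillna(0) <= 1)).all().all()

    def test_single_variant_gives_degenerate_fractions(self):
        variants = pd.DataFrame({"S": [0.7], "alpha_B": [1.0]})
        tab = stratified_apoptosis(variants, [True], bins=3)
        vals = tab.loc["mild"].dropna()
        assert set(vals) == {1.0}


class TestViabilityWindow:
    def test_stress_narrows_the_window_from_above(self, r_params):
        """theta_H falls as stress rises; the low threshold moves much
        less (the upper, pro-apoptotic threshold is the sensitive one)."""
        w_mild = viability_window(r_params, 0.5)
        w_mod = viability_window(r_params, 2.0)
        assert not w_mild.empty and not w_mod.empty
        assert w_mod.theta_H < w_mild.theta_H
        assert w_mild.theta_L < w_mild.theta_H

    def test_severe_stress_empties_the_window(self, r_params):
        w = viability_window(r_params, 8.0)
        assert w.empty
        assert w.theta_L is None and w.theta_H is None

    def test_inefficient_autophagosome_formation_kills_all(self, r_params):
        """Halving alpha_A makes even moderate stress uniformly lethal
        across the expression scan."""
        w = viability_window(r_params.replace(alpha_A=0.5), 2.0,
                             grid=np.geomspace(0.1, 10, 40))
        assert w.empty

    def test_window_edges_bracket_outcomes(self, r_params):
        """Just inside the refined thresholds the cell survives; just
        outside it dies."""
        w = viability_window(r_params, 2.0)
        from beclin_duality.experiments import _survives
        from beclin_duality.model_core import StressProtocol
        proto = StressProtocol.standard(2.0)
        eps = 5e-3
        assert _survives(r_params, w.theta_L + eps, 2.0, proto, 1e-6, 1e-9)
        assert not _survives(r_params, w.theta_L - eps, 2.0, proto,
                             1e-6, 1e-9)
        assert _survives(r_params, w.theta_H - eps, 2.0, proto, 1e-6, 1e-9)
        assert not _survives(r_params, w.theta_H + eps, 2.0, proto,
                             1e-6, 1e-9)

    def test_non_contiguous_survival_raises(self, r_params, monkeypatch):
        calls = iter([False, True, False, True, False])
        monkeypatch.setattr(experiments, "_survives",
                            lambda *a, **k: next(calls))
        with pytest.raises(NonContiguousSurvivalError):
            viability_window(r_params, 1.0, grid=np.linspace(0.5, 2.5, 5))


class TestPerturbation:
    def test_fold_ordering_flips_with_stress(self, r_params):
        """Under mild stress overexpression protects and knockdown
        harms; under severe stress the ordering reverses."""
        mild = perturbation_experiment(r_params, 0.5, n=400, seed=7)
        severe = perturbation_experiment(r_params, 4.0, n=400, seed=7)
        f_m, f_s = mild["fraction"], severe["fraction"]
        assert f_m[2.0] <= f_m[1.0] <= f_m[0.5]
        assert f_s[0.5] <= f_s[1.0] <= f_s[2.0]
        assert f_m[0.5] - f_m[2.0] > 0.1
        assert f_s[2.0] - f_s[0.5] > 0.1

    def test_zero_noise_single_cell_is_deterministic(self, r_params):
        res = perturbation_experiment(r_params, 0.5, folds=(1.0,), n=1,
                                      noise_sd=0.0, seed=0)
        assert res["fraction"].iloc[0] in (0.0, 1.0)

    def test_zero_expression_cells_are_counted_apoptotic(self, r_params):
        res = perturbation_experiment(r_params, 0.5, folds=(0.5,), n=2000,
                                      seed=11)
        row = res.loc[0.5]
        assert row["n_zero_expression"] > 0
        assert row["n_apoptotic"] >= row["n_zero_expression"]


class TestSensitivity:
    GRID = np.geomspace(0.1, 10, 30)

    def test_unit_fold_is_identity(self, r_params):
        df = local_sensitivity(r_params, 2.0, fold=1.0,
                               parameters=["beta_B", "alpha_A"],
                               grid=self.GRID)
        assert (df["theta_L_shift"].abs() < 1e-12).all()
        assert (df["theta_H_shift"].abs() < 1e-12).all()

    def test_cleavage_and_formation_rates_dominate(self, r_params):
        """beta_B and alpha_A perturbations hit both thresholds hardest:
        one direction of each destroys the window outright at moderate
        stress."""
        df = local_sensitivity(
            r_params, 2.0, fold=2.0, grid=self.GRID,
            parameters=["beta_B", "alpha_A", "sigma_C", "sigma_J",
                        "beta_A"])
        by = df.set_index(["parameter", "direction"])
        assert by.loc[("beta_B", "up"), "empty"]
        assert by.loc[("alpha_A", "down"), "empty"]
        # the gentler axes keep a window in both directions
        for p in ("sigma_C", "sigma_J", "beta_A"):
            assert not by.loc[(p, "up"), "empty"]
            assert not by.loc[(p, "down"), "empty"]


class TestGoldenHour:
    def test_representative_threshold_near_printed_value(self, r_params):
        """S = 8 commits the representative cell after ~4.8 h of
        stress."""
        res = duration_threshold(r_params, S=8.0)
        assert res.t_star == pytest.approx(4.8, abs=0.2)

    def test_unstressed_cell_never_commits(self, r_params):
        res = duration_threshold(r_params, S=0.0)
        assert res.unbounded
        assert res.t_star_censored == res.horizon

    def test_outcome_is_single_switch_in_duration(self, r_params):
        """Sweeping durations at 0.1 h resolution shows one survival ->
        apoptosis transition (bistable commitment)."""
        from beclin_duality import _kernels, unstressed_steady_state
        y0 = unstressed_steady_state(r_params)
        p = r_params.to_array()
        outcomes = []
        for d in np.arange(0.0, 10.01, 0.1):
            y, st = _kernels.protocol_final(y0.copy(), 8.0, 0.0, d, 48.0,
                                            p, 1e-8, 1e-10)
            assert st == 0
            outcomes.append(y[4] > 0.5)
        flips = np.flatnonzero(np.diff(np.asarray(outcomes)))
        assert len(flips) == 1

    def test_resolution_self_consistency(self, r_params):
        a = duration_threshold(r_params, S=8.0, resolution=0.05)
        b = duration_threshold(r_params, S=8.0, resolution=0.025)
        assert abs(a.t_star - b.t_star) < 0.05

    def test_panel_structure_and_baseline_fold(self, r_params):
        panel = intervention_panel(r_params, S=8.0, resolution=0.1)
        names = [r.name for r in panel]
        assert names[0] == "baseline"
        assert panel[0].fold == 1.0
        # every intervention appears with and without saturation relief
        plain = {n for n in names[1:] if not n.endswith("+phiA-x10")}
        relieved = {n[:-len("+phiA-x10")] for n in names[1:]
                    if n.endswith("+phiA-x10")}
        assert plain == relieved
        for r in panel[1:]:
            assert r.fold > 1.0  # all interventions extend the window

    def test_interventions_are_acute(self, r_params):
        """Overrides apply to the dynamics but the cell starts from its
        pre-treatment resting state: an expression knockdown given at
        stress onset must beat a chronically adapted knockdown cell at
        S = 8 (the chronic cell rests with more damaged mitochondria)."""
        acute = duration_threshold(r_params, S=8.0,
                                   overrides={"alpha_B": 0.5})
        chronic = duration_threshold(r_params.replace(alpha_B=0.5), S=8.0)
        assert acute.t_star > chronic.t_star
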