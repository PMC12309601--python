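import dataclasses

import numpy as np
import pytest

from cuproflux.dynamics import (
    anneal,
    assemble_derivatives,
    homeostatic_slope,
    integrate,
    jacobian,
    knockout,
    perturb_component,
    recovery_time,
    step_nutrient,
    sweep_nutrient,
)
from cuproflux.network import ALPHA_CELL, cu_weight_vector


class TestDerivatives:
    def test_amac_derivative_matches_reaction_sum(self, calibration, baseline14):
        system = calibration.system(14.0)
        f = assemble_derivatives(system)
        y = np.array([baseline14[n] for n in system.network.component_names])
        dy = f(0.0, y)
        R = system.rates(baseline14)
        expected = R["BAMAC"] - R["MMACF"] + R["MMACR"] - R["DAMAC"]
        i = system.network.component_names.index("aMAC")
        assert dy[i] == pytest.approx(expected, rel=1e-12)

    def test_cu_weighted_derivative_is_net_import(self, calibration):
        # algebraic identity of S: w·dC/dt = CUIN1 + CUIN2 − α·(w·C)
        system = calibration.system(30.0)
        state = {n: 0.7 * c for n, c in
                 calibration.profile("M50").concentrations.items()}
        w = cu_weight_vector(calibration.network)
        f = assemble_derivatives(system)
        y = np.array([state[n] for n in system.network.component_names])
        dy = f(0.0, y)
        R = system.rates(state)
        total_cu = sum(w[n] * c for n, c in state.items())
        expected = R["CUIN1"] + R["CUIN2"] - ALPHA_CELL * total_cu
        assert w.to_numpy() @ dy == pytest.approx(expected, rel=1e-9)

    def test_derivative_near_zero_at_annealed_state(self, calibration, baseline14):
        f = assemble_derivatives(calibration.system(14.0))
        y = np.array([baseline14[n] for n in calibration.network.component_names])
        assert np.abs(f(0.0, y)).max() < 1e-9


class TestAnnealing:
    def test_all_conditions_converge(self, annealed_states):
        for label, res in annealed_states.items():
            assert res.converged, label
            assert res.residual < 1e-9

    def test_annealed_states_stay_near_estimates(self, calibration, annealed_states):
        for p in calibration.profiles:
            res = annealed_states[p.label]
            for name, c0 in p.concentrations.items():
                ratio = res.concentrations[name] / c0
                assert 0.5 <= ratio <= 2.0, (p.label, name, ratio)

    def test_annealing_shifts_the_state(self, calibration, annealed_states):
        # the attractor differs from the estimate (self-correction), but
        # not by much
        shifts = []
        for p in calibration.profiles:
            res = annealed_states[p.label]
            shifts.append(max(
                abs(res.concentrations[n] / p.concentrations[n] - 1)
                for n in p.concentrations
            ))
        assert max(shifts) > 1e-4

    def test_local_stability_of_all_attractors(self, calibration, annealed_states):
        for p in calibration.profiles:
            J = jacobian(calibration.system(p.copper),
                         annealed_states[p.label].concentrations)
            eigs = np.linalg.eigvals(J)
            assert eigs.real.max() < 0, p.label

    def test_fixed_point_trajectory_is_flat(self, calibration, baseline14):
        traj = integrate(calibration.system(14.0), baseline14, (0.0, 2000.0))
        for name in traj.states.columns:
            dev = np.abs(traj.states[name] / baseline14[name] - 1).max()
            assert dev < 1e-3, name

    def test_fixed_point_insensitive_to_demetallation_speed(self, calibration):
        # recalibrating with demetallation 200x (instead of 100x) dilution
        # stiffens the metallation pairs but barely moves the attractor
        from cuproflux.pipeline import run_calibration
        from cuproflux.templates import default_template

        tpl = dataclasses.replace(default_template(), demetallation_multiplier=200.0)
        fast_cal = run_calibration(template=tpl)
        slow_ss = anneal(calibration.system(14.0),
                         calibration.profile("M10").concentrations)
        fast_ss = anneal(fast_cal.system(14.0),
                         fast_cal.profile("M10").concentrations)
        for name in ("aMAC", "MAC", "aACE", "ACE", "CU"):
            assert fast_ss.concentrations[name] == pytest.approx(
                slow_ss.concentrations[name], rel=0.02
            )


class TestPerturbation:
    def test_doubling_labile_pool_recovers(self, calibration, baseline14):
        traj, metrics = perturb_component(
            calibration.system(14.0), baseline14, "CU", 2.0, t_end=2000.0
        )
        assert 300.0 <= metrics["recovery_time"] <= 900.0
        # CU itself relaxes far faster than the protein components
        hl = metrics["half_lives"]
        assert hl["CU"] < 10.0
        others = [v for k, v in hl.items() if k != "CU" and v > 0]
        assert np.median(others) > 10 * hl["CU"]

    def test_identity_perturbation_is_a_no_op(self, calibration, baseline14):
        traj, metrics = perturb_component(
            calibration.system(14.0), baseline14, "CU", 1.0,
            t_event=50.0, t_end=500.0, n_points=500,
        )
        assert metrics["recovery_time"] == pytest.approx(0.0, abs=1.0)
        for name in traj.states.columns:
            assert np.abs(traj.states[name] / baseline14[name] - 1).max() < 1e-3

    def test_extreme_perturbation_returns_to_same_attractor(
        self, calibration, baseline14
    ):
        traj, _ = perturb_component(
            calibration.system(14.0), baseline14, "CU", 200.0, t_end=8000.0
        )
        final = traj.final_state
        for name, c in baseline14.items():
            assert final[name] == pytest.approx(c, rel=0.01), name

    def test_halving_or_doubling_any_component_recovers(
        self, calibration, baseline14
    ):
        system = calibration.system(14.0)
        for component, factor in [("CUP", 0.5), ("aMAC", 2.0), ("CTR", 0.5)]:
            traj, _ = perturb_component(
                system, baseline14, component, factor, t_end=4000.0, n_points=800
            )
            final = traj.final_state
            for name, c in baseline14.items():
                assert final[name] == pytest.approx(c, rel=0.01), (component, name)


class TestNutrientStep:
    def test_step_reaches_the_target_attractor(self, calibration, annealed_states):
        base10 = anneal(
            calibration.system(10.0), calibration.profile("M10").concentrations
        ).concentrations
        traj = step_nutrient(
            calibration.system(10.0), base10, 10.0, 250.0, t_end=12_000.0
        )
        direct = anneal(
            calibration.system(250.0), calibration.profile("M250").concentrations
        ).concentrations
        for name, c in direct.items():
            assert traj.final_state[name] == pytest.approx(c, rel=0.005), name

    def test_metallothionein_is_slowest_to_adjust(self, calibration):
        base10 = anneal(
            calibration.system(10.0), calibration.profile("M10").concentrations
        ).concentrations
        traj = step_nutrient(
            calibration.system(10.0), base10, 10.0, 250.0, t_end=12_000.0,
            n_points=6000,
        )
        target = traj.final_state
        settle = {}
        for name in traj.states.columns:
            dev = np.abs(traj.states[name] - target[name]) / max(target[name], 1e-12)
            late = np.flatnonzero((dev.to_numpy() > 0.01) & (traj.times >= 100.0))
            settle[name] = traj.times[late[-1]] - 100.0 if len(late) else 0.0
        assert max(settle, key=settle.get) in ("CUP", "aCUP")
        assert settle["CUP"] > 700.0

    def test_step_to_same_value_changes_nothing(self, calibration, baseline14):
        traj = step_nutrient(
            calibration.system(14.0), baseline14, 14.0, 14.0,
            t_end=500.0, n_points=300,
        )
        for name in traj.states.columns:
            assert np.abs(traj.states[name] / baseline14[name] - 1).max() < 1e-3


@pytest.fixture(scope="module")
def sweep_tables(calibration, baseline14):
    grid = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 250.0])
    wt = sweep_nutrient(calibration.system(14.0), grid, baseline14)
    mut = sweep_nutrient(
        knockout(calibration.system(14.0), "CUIN2"), grid, baseline14
    )
    return wt, mut


class TestKnockoutAndSweep:
    def test_unknown_reaction_rejected(self, calibration):
        with pytest.raises(KeyError):
            knockout(calibration.system(14.0), "NOPE")

    def test_no_knockout_is_identity(self, calibration, baseline14):
        system = calibration.system(14.0)
        assert system.rates(baseline14).equals(
            dataclasses.replace(system, knockout_multipliers={}).rates(baseline14)
        )

    def test_deleting_low_affinity_importer_starves_the_cell(self, calibration):
        base10 = anneal(
            calibration.system(10.0), calibration.profile("M10").concentrations
        ).concentrations
        mutant = anneal(
            knockout(calibration.system(10.0), "CUIN2"), base10
        ).concentrations
        for name in ("CU", "OTH", "CUP", "ACE", "MAC"):
            assert mutant[name] < base10[name], name
        for name in ("aMAC", "aACE", "aOTH", "CTR"):
            assert mutant[name] > base10[name], name

    def test_wild_type_labile_pool_rises_monotonically(self, sweep_tables):
        wt, _ = sweep_tables
        assert wt["converged"].all()
        cu = wt["CU"].to_numpy()
        assert (np.diff(cu) > 0).all()

    def test_mutant_copper_uptake_saturates(self, calibration, sweep_tables):
        wt, mut = sweep_tables
        w = cu_weight_vector(calibration.network)
        mut_total = (mut[list(w.index)] * w).sum(axis=1)
        wt_total = (wt[list(w.index)] * w).sum(axis=1)
        assert mut_total.loc[250.0] < wt_total.loc[250.0]
        assert 5.0 < mut_total.loc[250.0] < 15.0  # plateau near ~10 μM
        # nearly flat at high copper
        assert mut_total.loc[250.0] / mut_total.loc[50.0] < 1.1

    def test_mutant_regulates_tighter_than_wild_type(self, sweep_tables):
        wt, mut = sweep_tables
        assert homeostatic_slope(mut) < homeostatic_slope(wt)

    def test_frozen_regulation_responds_more_steeply(self, calibration, baseline14):
        # replace each logistic switch by its plateau constant: the
        # labile pool then rises faster with nutrient copper
        frozen = dataclasses.replace(
            calibration.system(14.0), params=calibration.params.frozen()
        )
        grid = np.array([10.0, 30.0, 50.0])
        wt = sweep_nutrient(calibration.system(14.0), grid, baseline14)
        ab = sweep_nutrient(frozen, grid, baseline14)
        rise_wt = wt["CU"].iloc[-1] / wt["CU"].iloc[0]
        rise_ab = ab["CU"].iloc[-1] / ab["CU"].iloc[0]
        assert rise_ab > rise_wt

    def test_flat_curve_has_zero_slope(self):
        import pandas as pd

        table = pd.DataFrame({"CU": [0.5, 0.5, 0.5, 0.5]},
                             index=[10.0, 20.0, 30.0, 50.0])
        table.index.name = "COPPER"
        assert homeostatic_slope(table) == pytest.approx(0.0, abs=1e-12)


def test_recovery_time_detects_sustained_return(calibration, baseline14):
    traj, _ = perturb_component(
        calibration.system(14.0), baseline14, "CU", 2.0, t_end=2000.0
    )
    t = recovery_time(traj, baseline14, t_event=100.0)
    assert np.isfinite(t) and t > 100.0
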