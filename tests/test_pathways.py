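import numpy as np
import pandas as pd
import pytest

from cuproflux.network import ALPHA_CELL
from cuproflux.pathways import (
    INDEPENDENT_REACTIONS,
    calibrate_cuin1,
    nonnegative_pathway_basis,
    null_basis,
    verify_flow_balance,
)

from dd_oracle import extreme_rays, in_cone


def toy_matrix(entries, reactions, species=None):
    species = species or [f"s{i}" for i in range(len(entries))]
    return pd.DataFrame(entries, index=species, columns=reactions)


class TestNullBasis:
    def test_canonical_dimension(self, S):
        G = null_basis(S)
        assert G.dimension == 15
        resid = np.abs(S.to_numpy() @ G.matrix.to_numpy()).max()
        assert resid < 1e-10

    def test_toy_single_flow(self):
        S = toy_matrix([[1, -1]], ["in", "out"])
        G = null_basis(S)
        assert G.dimension == 1
        v = G.matrix.to_numpy().ravel()
        assert v[0] == pytest.approx(v[1])


class TestPathwayBasis:
    def test_canonical_nonnegative_and_spanning(self, S, pathway_basis):
        W = pathway_basis.matrix.to_numpy()
        assert W.shape == (25, 15)
        assert W.min() >= 0.0
        assert np.abs(S.to_numpy() @ W).max() < 1e-8
        assert np.linalg.matrix_rank(W, tol=1e-9) == 15
        # normalization: largest entry of each pathway is 1
        assert np.allclose(W.max(axis=0), 1.0)

    def test_canonical_columns_are_cone_members_by_dd_oracle(self, S, pathway_basis):
        rays = extreme_rays(S.to_numpy())
        assert len(rays) >= 15
        assert np.linalg.matrix_rank(np.array(rays, float)) == 15
        for col in pathway_basis.matrix.columns:
            assert in_cone(pathway_basis.matrix[col].to_numpy(), rays)

    def test_toy_single_pathway(self):
        S = toy_matrix([[1, -1]], ["in", "out"])
        W = nonnegative_pathway_basis(null_basis(S))
        np.testing.assert_allclose(W.matrix.to_numpy().ravel(), [1.0, 1.0])

    def test_reaction_relabeling_permutes_rows(self, S):
        rng = np.random.default_rng(0)
        perm = rng.permutation(S.shape[1])
        S_perm = S.iloc[:, perm]
        W_perm = nonnegative_pathway_basis(null_basis(S_perm))
        # same flux cone: permuted-basis columns, mapped back to the
        # original reaction order, are flows of the original cone
        rays = extreme_rays(S.to_numpy())
        back = W_perm.matrix.reindex(S.columns)
        assert np.abs(S.to_numpy() @ back.to_numpy()).max() < 1e-8
        for col in back.columns:
            assert in_cone(back[col].to_numpy(), rays)

    def test_random_small_networks_match_dd_oracle(self, rng):
        checked = 0
        attempts = 0
        while checked < 20 and attempts < 400:
            attempts += 1
            m = int(rng.integers(2, 7))
            n = int(rng.integers(m + 1, 13))
            S = np.zeros((m, n), dtype=int)
            for j in range(n):
                kind = rng.integers(0, 3)
                if kind == 0:  # input
                    S[rng.integers(0, m), j] += rng.integers(1, 3)
                elif kind == 1:  # output
                    S[rng.integers(0, m), j] -= rng.integers(1, 3)
                else:  # conversion
                    a, b = rng.integers(0, m, size=2)
                    S[a, j] -= rng.integers(1, 3)
                    S[b, j] += rng.integers(1, 3)
            Sf = pd.DataFrame(S, columns=[f"r{j}" for j in range(n)])
            G = null_basis(Sf)
            if G.dimension == 0:
                continue
            rays = extreme_rays(S)
            # only networks where every reaction can carry flux admit a
            # nonnegative basis
            support = np.array(rays, float).sum(axis=0) if rays else np.zeros(n)
            if len(rays) < G.dimension or (support <= 0).any():
                continue
            W = nonnegative_pathway_basis(G)
            Wm = W.matrix.to_numpy()
            assert Wm.min() >= 0
            assert np.linalg.matrix_rank(Wm, tol=1e-9) == G.dimension
            assert np.abs(S @ Wm).max() < 1e-8
            for col in W.matrix.columns:
                assert in_cone(W.matrix[col].to_numpy(), rays)
            checked += 1
        assert checked == 20


class TestRateAssignment:
    def test_mbcs_influx_anchor(self, calibration):
        mbcs = calibration.profile("MBCS")
        k1, rates = calibrate_cuin1(mbcs, calibration.ref, calibration.network)
        assert rates["MBCS"] == pytest.approx(0.018, abs=0.0005)
        assert rates["MBCS"] == pytest.approx(
            ALPHA_CELL * mbcs.total_cell_cu, rel=1e-12
        )

    def test_mbcs_all_import_through_ctr(self, calibration):
        mbcs_assignment = calibration.assignments[0]
        assert mbcs_assignment.condition == "MBCS"
        assert mbcs_assignment.rates["CUIN2"] == 0.0

    def test_cuin1_increases_with_copper_toward_saturation(self, calibration):
        k1 = calibration.k_cuin1
        km = calibration.network.reaction("CUIN1").parameters["km"]
        saturations = [c / (km + c) for c in (0.5, 2.0, 20.0, 200.0)]
        assert saturations == sorted(saturations)
        assert k1 > 0

    def test_calibration_round_trip_recovers_k(self, calibration):
        # rebuild CUIN1 rates from the calibrated k and invert again
        mbcs = calibration.profile("MBCS")
        k1, _ = calibrate_cuin1(mbcs, calibration.ref, calibration.network)
        assert k1 == pytest.approx(calibration.k_cuin1, rel=1e-9)

    def test_dilution_rates_scale_with_concentration(self, calibration):
        for a, p in zip(calibration.assignments, calibration.profiles):
            for name in ("DAMAC", "DCU", "DCTR"):
                species = next(iter(calibration.network.reaction(name).substrates))
                assert a.rates[name] == pytest.approx(
                    ALPHA_CELL * p.concentrations[species], rel=1e-12
                )

    def test_demetallation_hundredfold_rule(self, calibration):
        for a in calibration.assignments:
            assert a.rates["MMACR"] == pytest.approx(100 * a.rates["DMAC"], rel=1e-12)
            assert a.rates["MOTHR"] == pytest.approx(100 * a.rates["DOTH"], rel=1e-12)


class TestSolveSteadyState:
    def test_closed_form_biosynthesis(self, calibration):
        # hand elimination of the apo+holo balances: BAMAC = α([aMAC]+[MAC])
        for a, p in zip(calibration.assignments, calibration.profiles):
            expected = ALPHA_CELL * (
                p.concentrations["aMAC"] + p.concentrations["MAC"]
            )
            assert a.rates["BAMAC"] == pytest.approx(expected, rel=1e-9)

    def test_closed_form_metallation(self, calibration):
        # MAC balance with the 100x rule: MMACF = 101 α [MAC]
        for a, p in zip(calibration.assignments, calibration.profiles):
            assert a.rates["MMACF"] == pytest.approx(
                101 * ALPHA_CELL * p.concentrations["MAC"], rel=1e-9
            )

    def test_steady_state_for_all_conditions(self, calibration):
        S = calibration.S.to_numpy()
        for a in calibration.assignments:
            R = a.rates.to_numpy()
            assert (R >= 0).all()
            assert np.abs(S @ R).max() < 1e-8 * max(R.max(), 1e-12)

    def test_direct_linear_solve_agrees(self, calibration):
        # independent cross-check without the pathway basis: fix the 15
        # independents and solve the 10 remaining from S R = 0
        S = calibration.S
        dep = [r for r in S.columns if r not in INDEPENDENT_REACTIONS]
        ind = list(INDEPENDENT_REACTIONS)
        for a in calibration.assignments:
            A = S[dep].to_numpy(dtype=float)
            b = -S[ind].to_numpy(dtype=float) @ a.rates[ind].to_numpy()
            x = np.linalg.solve(A, b)
            np.testing.assert_allclose(x, a.rates[dep].to_numpy(), atol=1e-10)

    def test_pathway_coefficients_reproduce_rates(self, calibration):
        W = calibration.W.matrix.to_numpy()
        for a in calibration.assignments:
            np.testing.assert_allclose(
                W @ a.c_bp, a.rates.to_numpy(), atol=1e-8 * a.rates.max()
            )


class TestFlowBalance:
    def test_all_conditions_balanced(self, calibration):
        assert all(r["balanced"] for r in calibration.balance_report)

    def test_constructed_violation_is_reported(self, calibration):
        a = calibration.assignments[-1]  # M250, nonzero CUIN2
        broken = a.rates.copy()
        broken["CUIN2"] = 0.0
        from cuproflux.pathways import RateAssignment

        bad = RateAssignment(a.condition, broken, a.independent)
        report = verify_flow_balance(
            bad, calibration.profile(a.condition), ALPHA_CELL
        )
        assert not report["balanced"]
        assert report["residual"] < 0  # import deficit

    def test_mbcs_balance_value(self, calibration):
        report = next(r for r in calibration.balance_report if r["condition"] == "MBCS")
        assert report["influx"] == pytest.approx(0.018, abs=0.0005)
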