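"""Rate laws, steady states and parameter handling of the two models."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as floats_st

from quenchsim import model_core as mc


class TestHillResponse:
    @pytest.mark.parametrize("x,K,h,l,mode,expected", [
        (0.0, 3.0, 2.0, 0.0, "repression", 1.0),
        (1e9, 1.0, 2.0, 0.01, "repression", 0.01),
        (1.0, 1.0, 1.0, 0.0, "repression", 0.5),
        (0.0, 5.0, 2.0, 0.02, "activation", 0.02),
        (1e9, 5.0, 2.0, 0.02, "activation", 1.0),
    ])
    def test_limits_and_half_occupancy(self, x, K, h, l, mode, expected):
        assert mc.hill_response(x, K, h, l, mode) == pytest.approx(
            expected, abs=1e-6)

    @settings(max_examples=50, derandomize=True)
    @given(floats_st.floats(1e-6, 1e3), floats_st.floats(1e-6, 1e3))
    def test_repression_strictly_decreasing(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert (mc.hill_response(lo, 10.0, 2.0, 0.1) >
                mc.hill_response(hi, 10.0, 2.0, 0.1))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mc.hill_response(-1.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            mc.hill_response(1.0, 0.0, 2.0)
        with pytest.raises(ValueError):
            mc.hill_response(1.0, 1.0, 2.0, l=1.0)

    def test_derivative_matches_finite_difference(self):
        for mode in ("repression", "activation"):
            for x in (0.0, 0.5, 2.0, 40.0):
                d = mc._hill_derivative(x, 7.0, 2.0, 0.05, mode)
                eps = 1e-6 * max(x, 1.0)
                fd = (mc.hill_response(x + eps, 7.0, 2.0, 0.05, mode)
                      - mc.hill_response(max(x - eps, 0.0), 7.0, 2.0,
                                         0.05, mode)) / (
                    (x + eps) - max(x - eps, 0.0))
                assert d == pytest.approx(fd, abs=1e-5)


class TestLuxComplex:
    def test_no_ligand_or_receptor(self):
        assert mc.lux_qssa_complex(0.0, 20.0, 100.0) == 0.0
        assert mc.lux_qssa_complex(15.0, 0.0, 100.0) == 0.0

    def test_equilibrium_root_vs_bruteforce(self, rng):
        for _ in range(50):
            A, RT, K = rng.uniform(0.01, 200, 3)
            RA = mc.lux_qssa_complex(A, RT, K)
            # conservation-equation residual at the returned root
            resid = (RT - RA) * (A - RA) - K * RA
            assert abs(resid) < 1e-10 * max(A * RT, 1.0)
            assert 0.0 <= RA <= min(A, RT) + 1e-12
            # brute-force scan: no admissible root closer to equilibrium
            grid = np.linspace(0.0, min(A, RT), 20001)
            res_grid = (RT - grid) * (A - grid) - K * grid
            best = grid[np.argmin(np.abs(res_grid))]
            assert abs(best - RA) < 2 * (grid[1] - grid[0])

    def test_derivative(self, rng):
        for _ in range(20):
            A, RT, K = rng.uniform(0.1, 100, 3)
            eps = 1e-6 * A
            fd = (mc.lux_qssa_complex(A + eps, RT, K)
                  - mc.lux_qssa_complex(A - eps, RT, K)) / (2 * eps)
            assert mc.lux_qssa_dRA_dA(A, RT, K) == pytest.approx(fd,
                                                                 rel=1e-5)


class TestToyModel:
    def test_steady_state_is_root(self, toy_params, toy_ss):
        r = mc.toy_rates(toy_ss, toy_params)
        assert np.max(np.abs(r)) < 1e-10

    def test_pure_degradation(self):
        p = mc.ToyParams(p1=1e-12, p2=1e-12, p3=1e-12, p4=1e-12, p5=1e-12)
        r = mc.toy_rates(np.ones(4), p)
        assert np.allclose(r, -1.0, atol=1e-11)

    def test_jacobian_structure(self, toy_params, toy_ss):
        """Ring repression chain plus the two quench couplings."""
        J = mc.toy_jacobian(toy_ss, toy_params)
        assert np.allclose(np.diag(J), -1.0)
        assert J[0, 2] < 0 and J[1, 0] < 0 and J[2, 1] < 0  # ring
        assert J[3, 0] < 0 and J[0, 3] > 0                  # quench loop
        zero = [(0, 1), (1, 2), (1, 3), (2, 0), (2, 3), (3, 1), (3, 2)]
        for i, j in zero:
            assert J[i, j] == 0.0

    def test_wrong_species_count(self, toy_params):
        with pytest.raises(ValueError):
            mc.toy_rates(np.ones(5), toy_params)


class TestFullModel:
    def test_steady_state_is_root(self, set1_params, set1_ss):
        r = mc.full_rates(set1_ss, set1_params)
        scale = np.maximum(set1_ss.values, 1.0)
        assert np.max(np.abs(r) / scale) < 1e-9

    def test_relaxation_confirms_steady_state(self, set2_params, set2_ss):
        from scipy.integrate import solve_ivp
        f = lambda t, y: mc.full_rates(y, set2_params)
        sol = solve_ivp(f, (0, 100), set2_ss.values, method="BDF",
                        rtol=1e-9, atol=1e-12)
        assert np.max(np.abs(sol.y[:, -1] - set2_ss.values)
                      / np.maximum(set2_ss.values, 1.0)) < 1e-6

    def test_copy_number_velocity_invariance(self, set1_params, set1_ss):
        """(n, k) -> (alpha*n, k/alpha) leaves the rate vector unchanged."""
        alpha = 3.7
        p2 = dataclasses.replace(
            set1_params, n_C=set1_params.n_C * alpha,
            k_C=set1_params.k_C / alpha)
        r1 = mc.full_rates(set1_ss, set1_params)
        r2 = mc.full_rates(set1_ss, p2)
        assert np.allclose(r1, r2, rtol=0, atol=1e-12)

    def test_tetR_split_symmetry(self, set1_params, set1_ss):
        """Moving delta from the oscillator-derived tetR mRNA pool to the
        quench-derived pool leaves TetR protein dynamics unchanged."""
        x = set1_ss.values.copy()
        delta = 0.3
        x2 = x.copy()
        x2[1] += delta
        x2[2] -= delta
        i_pT = mc.FULL_SPECIES.index("TetR")
        r1 = mc.full_rates(x, set1_params)
        r2 = mc.full_rates(x2, set1_params)
        assert r1[i_pT] == pytest.approx(r2[i_pT], abs=1e-12)

    def test_birth_death_balance_per_component(self, set2_params, set2_ss):
        """Each component at steady state sits at its own
        production/degradation balance (the linear birth-death law)."""
        p, s = set2_params, set2_ss
        assert s["cI"] == pytest.approx(p.a_C * s["m_cI"] / p.g_pC, rel=1e-9)
        assert s["AHL"] == pytest.approx(p.k_A * s["LuxI"] / p.g_A, rel=1e-9)

    def test_set2_molecule_floor(self, set2_params, set2_ss):
        assert np.min(set2_ss.values) / set2_params.C >= 4.0

    def test_missing_parameter_is_named(self):
        with pytest.raises(mc.ConfigurationError, match="k_C"):
            mc.GeneCircuitParams(
                n_C=4, k_C=None, l_C=0.002, n_TO=4, k_TO=20, l_TO=0.002,
                n_TQ=4, k_TQ=20, l_TQ=0.002, n_L=4, k_L=20, l_L=0.002,
                n_I=4, k_I=20, l_I=0.002,
                K_C=20, K_T=20, K_L=20, K_RA=1.0, K_R=100.0)


class TestJacobians:
    @pytest.mark.parametrize("model,fixture", [("toy", "toy_fig2"),
                                               ("full", "set2")])
    def test_against_central_differences(self, model, fixture, rng):
        _m, p = mc.load_params(fixture)
        n = len(mc.species_names(model))
        for _ in range(5):
            x = rng.uniform(0.5, 50.0, n)
            J = mc.reaction_jacobian(model, x, p)
            for j in range(n):
                eps = 1e-6 * max(x[j], 1.0)
                xp, xm = x.copy(), x.copy()
                xp[j] += eps
                xm[j] -= eps
                col = (mc.rates(model, xp, p) - mc.rates(model, xm, p)) / (
                    2 * eps)
                scale = np.maximum(np.abs(col), 1e-3)
                assert np.max(np.abs(J[:, j] - col) / scale) < 1e-5


class TestSteadyStateSolver:
    def test_nonnegative_and_reproducible(self, set1_params):
        s1 = mc.find_steady_state("full", set1_params)
        s2 = mc.find_steady_state("full", set1_params)
        assert np.all(s1.values >= 0)
        assert np.allclose(s1.values, s2.values, rtol=0, atol=1e-12)

    def test_explicit_failure_not_nan(self):
        # an absurd parameterization that cannot balance within the cap
        p = mc.ToyParams(p1=1e30, p2=1e30, p3=1e-30, p4=1e30, p5=1e-30)
        try:
            s = mc.find_steady_state("toy", p, max_restarts=1)
        except mc.ConvergenceError:
            return
        assert np.all(np.isfinite(s.values))


class TestUnitsAndFixtures:
    def test_single_molecule_concentration(self):
        assert mc.single_molecule_concentration(1e-15) == pytest.approx(
            1.66054, rel=1e-4)

    def test_fixture_C_consistent_with_cell_volume(self, set2_params):
        assert set2_params.molecule_concentration() == pytest.approx(
            set2_params.C, rel=1e-4)

    def test_unknown_key_rejected(self, tmp_path):
        f = tmp_path / "bad.yaml"
        f.write_text("model: toy\np1: 1\np2: 1\np3: 1\np4: 1\np5: 1\n"
                     "bogus_rate: 3\n")
        with pytest.raises(mc.ConfigurationError, match="bogus_rate"):
            mc.load_params(str(f))

    def test_luxr_pool_is_twelve_molecules(self, set2_params):
        assert round(set2_params.R_T / set2_params.C) == 12
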