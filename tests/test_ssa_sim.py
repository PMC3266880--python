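"""Exact stochastic kernel: conversions, exactness laws, conservation,
diffusion discretization and aggregation conventions."""

import numpy as np
import pytest
from scipy import stats

from quenchsim import model_core as mc, ssa_sim as ss


class TestConversions:
    def test_zero(self):
        assert ss.molecules_from_concentration(0.0, 1e-15) == 0

    def test_single_molecule_femtolitre(self):
        conc = ss.concentration_from_molecules(1, 1e-15)
        assert conc == pytest.approx(1.66054, rel=1e-4)
        assert ss.molecules_from_concentration(conc, 1e-15) == 1

    def test_round_trip_exact_on_integers(self):
        v = 8e-16
        for n in (0, 1, 7, 123, 10 ** 6):
            assert ss.molecules_from_concentration(
                ss.concentration_from_molecules(n, v), v) == n

    def test_set2_luxr_pool(self, set2_params):
        n = ss.molecules_from_concentration(
            set2_params.R_T, set2_params.cell_volume_litres())
        assert n == 12

    def test_max_bindable_promoters(self, set2_params):
        """12 LuxR monomers form at most 6 promoter-binding homodimers."""
        n = ss.molecules_from_concentration(
            set2_params.R_T, set2_params.cell_volume_litres())
        assert n // 2 == 6


class TestDiffusionJumpRate:
    def test_unit(self):
        assert ss.diffusion_jump_rate(1.0, 1.0) == 1.0

    def test_halving_h_quadruples(self):
        assert ss.diffusion_jump_rate(3.0, 0.5) == pytest.approx(
            4 * ss.diffusion_jump_rate(3.0, 1.0))

    def test_variance_grows_as_2Dt(self):
        """Count-weighted positional variance of a pure-diffusion SSA
        matches the diffusion kernel within 5%."""
        # horizon short enough that the reflecting walls (at +/-80) see
        # negligible mass: sd(8 hr) = 25 compartments
        D, h, n0 = 40.0, 1.0, 10_000
        m = ss.build_pure_diffusion(161, D, h, n0)
        t_end = 8.0
        traj = ss.simulate_ssa(m, t_end, seed=7, record_dt=1.0)
        x = (np.arange(m.n_compartments) - m.n_compartments // 2) * h
        for i, t in enumerate(traj.times[1:], start=1):
            counts = traj.counts[i, :, ss._I["AHL"]]
            var = np.sum(counts * x ** 2) / np.sum(counts)
            assert var == pytest.approx(2 * D * t, rel=0.05)


class TestExactness:
    def test_birth_death_poisson_moments(self):
        """Stationary distribution of a birth-death channel pair is
        Poisson(c/g): mean within 3 SE, variance/mean within 5%."""
        c, g = 50.0, 2.0
        m = ss.build_birth_death(c, g, x0=25)
        traj = ss.simulate_ssa(m, 1100.0, seed=2, record_dt=0.05)
        x = traj.counts[traj.times > 100.0, 0, 0]
        assert traj.metadata["n_events"] > 10 ** 5
        # effective sample size: decorrelation time 1/g
        n_eff = (traj.times[-1] - 100.0) * g
        se = np.sqrt(c / g / n_eff)
        assert abs(x.mean() - c / g) < 3 * se
        assert x.var() / x.mean() == pytest.approx(1.0, abs=0.05)

    def test_waiting_times_exponential(self):
        """Inter-event times of a single-channel model follow the
        exponential law (KS p > 0.01) across seeds."""
        c = 7.0
        m = ss.build_birth_death(c, 0.0, x0=0)
        for seed in (1, 2, 3):
            traj = ss.simulate_ssa(m, 1600.0, seed=seed, record_dt=100.0,
                                   log_events=10_000)
            ev = traj.metadata["event_times"]
            assert len(ev) == 10_000
            gaps = np.diff(np.concatenate([[0.0], ev]))
            p = stats.kstest(gaps, "expon", args=(0, 1.0 / c)).pvalue
            assert p > 0.01

    def test_same_seed_bit_identical(self, set2_params):
        m = ss.build_reaction_set(set2_params, 1, geometry="single_cell",
                                  n_empty_side=10)
        t1 = ss.simulate_ssa(m, 3.0, seed=42, record_dt=0.05)
        t2 = ss.simulate_ssa(m, 3.0, seed=42, record_dt=0.05)
        assert np.array_equal(t1.counts, t2.counts)
        t3 = ss.simulate_ssa(m, 3.0, seed=43, record_dt=0.05)
        assert not np.array_equal(t1.counts, t3.counts)


class TestReactionSet:
    def test_channel_count_and_digest_stability(self, set2_params):
        m1 = ss.build_reaction_set(set2_params, 3, geometry="line")
        m2 = ss.build_reaction_set(set2_params, 3, geometry="line")
        assert m1.digest() == m2.digest()
        m3 = ss.build_reaction_set(set2_params, 3, geometry="line",
                                   diffusion_on=False)
        assert m1.digest() != m3.digest()

    def test_observable_totals_static_under_binding(self, set2_params):
        """Binding/unbinding/dimerization channels leave every observable
        total unchanged (stoichiometric identity)."""
        m = ss.build_reaction_set(set2_params, 1, geometry="line")
        weights = {}
        for name, parts in ss._TOTALS.items():
            w = np.zeros(ss.N_SP)
            for sp, wt in parts.items():
                w[ss._I[sp]] = wt
            weights[name] = w
        for i, cname in enumerate(m.channel_names):
            if not cname.startswith(("bind_", "unbind_", "dim_", "undim_")):
                continue
            delta = np.zeros(ss.N_SP)
            for k in range(m.stoich_ptr[i], m.stoich_ptr[i + 1]):
                delta[m.stoich_sp[k] % ss.N_SP] += m.stoich_delta[k]
            for name, w in weights.items():
                assert w @ delta == 0, (cname, name)

    def test_conservation_in_simulation(self, set2_params):
        m = ss.build_reaction_set(set2_params, 4, geometry="line")
        traj = ss.simulate_ssa(m, 5.0, seed=9, record_dt=0.05)
        obs = ss.aggregate_protein_totals(traj, reacting=m.reacting)
        luxr = obs.species("LuxR")
        assert np.all(luxr == 12)
        # promoter-site conservation, every operator pair, every cell
        for op, n in (("OcI", 4), ("OtetO", 4), ("Olux", 4),
                      ("OlacI", 4), ("OluxI", 4)):
            tot = (traj.raw_species(op + "_free")
                   + traj.raw_species(op + "_bound"))
            assert np.all(tot == n)

    def test_initial_condition_rounds_steady_state(self, set2_params,
                                                   set2_ss):
        m = ss.build_reaction_set(set2_params, 2, geometry="line")
        obs = ss.aggregate_protein_totals(
            ss.StochasticTrajectory(
                times=np.array([0.0]),
                counts=m.initial.reshape(1, 2, ss.N_SP),
                seed=0, model_digest=""), reacting=m.reacting)
        for name in mc.FULL_SPECIES:
            expected = round(set2_ss[name] / set2_params.C)
            assert abs(obs.species(name)[0, 0] - expected) <= 1

    def test_hill_exponent_other_than_two_rejected(self, set2_params):
        import dataclasses
        bad = dataclasses.replace(set2_params, h_C=3.0)
        with pytest.raises(mc.ConfigurationError):
            ss.build_reaction_set(bad, 1)

    def test_mean_field_matches_deterministic_model(self, set2_params,
                                                    set2_ss):
        """With binding taken to the fast-equilibrium limit and inflated
        volume, the mean-field ODE of the reaction set reproduces the
        deterministic steady state to < 1% per observable species."""
        from scipy.integrate import solve_ivp
        cfg = ss.SSAConfig(kr_dim=2e4, kon_op=2e4, kon_RA=2e3)
        m = ss.build_reaction_set(set2_params, 1, geometry="line",
                                  config=cfg, volume_scale=100.0,
                                  diffusion_on=False)
        sol = solve_ivp(lambda t, x: ss.mean_field_rates(m, x), (0, 30),
                        m.initial.astype(float), method="BDF",
                        rtol=1e-8, atol=1e-8)
        xf = sol.y[:, -1]
        C = set2_params.C / 100.0
        for name in mc.FULL_SPECIES:
            tot = sum(w * xf[ss._I[sp]]
                      for sp, w in ss._TOTALS[name].items())
            assert tot * C == pytest.approx(set2_ss[name], rel=0.01), name


class TestNoDiffusionIndependence:
    def test_cells_uncorrelated(self, set2_params):
        m = ss.build_reaction_set(set2_params, 10, geometry="line",
                                  diffusion_on=False)
        traj = ss.simulate_ssa(m, 30.0, seed=4, record_dt=0.1)
        obs = ss.aggregate_protein_totals(traj, reacting=m.reacting)
        ci = obs.species("cI").astype(float)
        sel = traj.times > 5.0
        rs = []
        for a in range(0, 9):
            r = np.corrcoef(ci[sel, a], ci[sel, a + 1])[0, 1]
            rs.append(r)
        # individual correlations are noisy; their mean must vanish
        assert abs(np.mean(rs)) < 0.15


class TestAggregation:
    def test_monomer_equivalent_arithmetic(self):
        counts = np.zeros((1, 1, ss.N_SP), dtype=np.int64)
        counts[0, 0, ss._I["cI"]] = 3
        counts[0, 0, ss._I["cI_2"]] = 2
        counts[0, 0, ss._I["OlacI_bound"]] = 1
        traj = ss.StochasticTrajectory(times=np.array([0.0]), counts=counts,
                                       seed=0, model_digest="")
        obs = ss.aggregate_protein_totals(traj)
        assert obs.species("cI")[0, 0] == 9

    def test_ahl_total_includes_bound_ligand(self):
        counts = np.zeros((1, 1, ss.N_SP), dtype=np.int64)
        counts[0, 0, ss._I["AHL"]] = 5
        counts[0, 0, ss._I["LuxR_AHL"]] = 2
        counts[0, 0, ss._I["LuxR_AHL_2"]] = 1
        counts[0, 0, ss._I["Olux_bound"]] = 1
        traj = ss.StochasticTrajectory(times=np.array([0.0]), counts=counts,
                                       seed=0, model_digest="")
        obs = ss.aggregate_protein_totals(traj)
        assert obs.species("AHL")[0, 0] == 5 + 2 + 2 + 2


class TestMeanFieldConvergence:
    def test_inflated_volume_tracks_deterministic(self, set2_params,
                                                  set2_ss):
        """At 30x volume the SSA stays within a few percent of the
        deterministic steady state (law of large numbers)."""
        m = ss.build_reaction_set(set2_params, 1, geometry="line",
                                  volume_scale=30.0, diffusion_on=False)
        traj = ss.simulate_ssa(m, 10.0, seed=6, record_dt=0.05)
        obs = ss.aggregate_protein_totals(traj, reacting=m.reacting)
        C = set2_params.C / 30.0
        for name in ("cI", "TetR", "LacI"):
            x = obs.species(name)[traj.times > 2.0, 0].astype(float)
            assert x.mean() * C == pytest.approx(set2_ss[name], rel=0.1)
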