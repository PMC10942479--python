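"""Variational characterization of equilibria and KKT verification."""
import numpy as np
import pytest

from ecocavity.dynamics import IntegrationOptions, integrate_to_steady_state
from ecocavity.equilibrium_opt import (em_essential, kkt_residuals,
                                       objective_value, solve_equilibrium)
from ecocavity.glv_reduction import effective_glv
from ecocavity.systems import CRMSystem


class TestObjectives:
    def test_dissimilarities_vanish_at_supply_point(self, macarthur_pair):
        K = macarthur_pair.K
        assert objective_value("d_euclidean", macarthur_pair, K) == 0.0
        syse = CRMSystem(c=[[0.1, 0.1]], m=[1.0], kind="external",
                         kappa=[2.0, 3.0], omega=[1.0, 1.0])
        assert objective_value("d_KL", syse, syse.supply_point) == pytest.approx(0.0)

    def test_quadratic_objective_at_empty_community(self, macarthur_pair):
        # Q(0) = (K1 + K2)/2 for unit rates, values and zero populations
        assert objective_value("Q_population", macarthur_pair,
                               np.zeros(2)) == pytest.approx(3.825)

    def test_kl_diverges_at_depleted_resource(self):
        syse = CRMSystem(c=[[0.1, 0.1]], m=[1.0], kind="external",
                         kappa=[2.0, 3.0], omega=[1.0, 1.0])
        # logarithmic divergence as R_1 -> 0+
        vals = [objective_value("d_KL", syse, np.array([eps, 3.0]))
                for eps in (1e-3, 1e-6, 1e-9, 1e-12)]
        assert np.all(np.diff(vals) > 1.0)
        with pytest.raises(ValueError):
            objective_value("d_KL", syse, np.array([0.0, 3.0]))

    def test_quadratic_objective_is_convex(self, macarthur_pair):
        # Hessian of Q is sum_a (w K / r) c_a c_a' -- check PSD numerically
        c, w, K, r = (macarthur_pair.c, macarthur_pair.w, macarthur_pair.K,
                      macarthur_pair.r_res)
        H = (c * (w * K / r)[None, :]) @ c.T
        assert np.linalg.eigvalsh(H).min() > -1e-10

    def test_Q_descends_along_reduced_dynamics(self, macarthur_pair):
        # after resources equilibrate, the flow is a rescaled gradient
        # descent of Q: its value never increases along the trajectory
        from scipy.integrate import solve_ivp
        eff = effective_glv(macarthur_pair)

        def rhs(t, N):
            Np = np.maximum(N, 0.0)
            return Np * (eff.r_eff - eff.alpha @ Np)

        sol = solve_ivp(rhs, (0, 40.0), np.array([0.05, 2.5]),
                        t_eval=np.linspace(0, 40, 300), rtol=1e-10, atol=1e-12)
        Q = [objective_value("Q_population", macarthur_pair, np.maximum(N, 0.0))
             for N in sol.y.T]
        assert np.all(np.diff(Q) <= 1e-9)


class TestSolveEquilibrium:
    def test_prohibitive_costs_leave_environment_at_supply(self):
        sysm = CRMSystem(c=[[0.2, 0.2], [0.3, 0.1]], m=[50.0, 60.0],
                         kind="self_renewing", K=[1.0, 1.0], r_res=[1.0, 1.0])
        res = solve_equilibrium(sysm)
        assert np.all(res.N_opt == 0)
        assert np.allclose(res.R_opt, [1.0, 1.0])
        syse = CRMSystem(c=[[0.2, 0.2]], m=[50.0], kind="external",
                         kappa=[1.0, 1.0], omega=[1.0, 1.0])
        res = solve_equilibrium(syse)
        assert np.all(res.N_opt == 0)
        assert np.allclose(res.R_opt, [1.0, 1.0], atol=1e-8)

    def test_minimizer_equals_dynamics_on_worked_example(self, macarthur_pair, macarthur_pair_oracle):
        N_star, R_star = macarthur_pair_oracle
        res = solve_equilibrium(macarthur_pair)
        assert res.converged and res.kkt_ok
        assert np.allclose(res.N_opt, N_star, atol=1e-8)
        assert np.allclose(res.R_opt, R_star, atol=1e-8)
        state = integrate_to_steady_state(
            macarthur_pair, options=IntegrationOptions(method="ode"))
        assert np.allclose(res.N_opt, state.N, atol=1e-6)

    def test_random_external_instances_match_dynamics(self):
        from ecocavity.experiments import optimization_vs_dynamics
        rows = optimization_vs_dynamics(n_instances=20, S=12, M=12, seed=0,
                                        kinds=("external",))
        for row in rows:
            assert row["kkt_max"] < 1e-6
            assert row["rel_dev_N"] < 1e-4 and row["rel_dev_R"] < 1e-4

    def test_multiplier_abundance_duality(self):
        # each surviving species' KKT multiplier times e_i is its abundance;
        # extinct species have zero multiplier and strictly negative growth
        rng = np.random.default_rng(8)
        syse = CRMSystem(c=rng.uniform(0, 0.2, (10, 10)),
                         m=rng.uniform(0.05, 0.15, 10), kind="external",
                         kappa=rng.uniform(0.5, 1.5, 10), omega=np.ones(10),
                         e=rng.uniform(0.5, 2.0, 10))
        res = solve_equilibrium(syse)
        state = integrate_to_steady_state(
            syse, options=IntegrationOptions(method="ode"))
        assert np.allclose(res.N_opt, state.N, atol=1e-6)
        g = syse.growth_rates(res.R_opt)
        assert np.all(g[res.N_opt == 0] < 0)


class TestKKTResiduals:
    def test_optimizer_output_satisfies_all_conditions(self, macarthur_pair):
        res = solve_equilibrium(macarthur_pair)
        assert all(v < 1e-6 for v in res.kkt.values())

    def test_perturbation_breaks_stationarity(self, macarthur_pair):
        res = solve_equilibrium(macarthur_pair)
        N = res.N_opt * 1.01
        kkt = kkt_residuals(macarthur_pair, (N, res.R_opt))
        assert kkt["steady_populations"] > 1e-4 or kkt["stationarity"] > 1e-4

    def test_dynamics_and_optimizer_residuals_same_order(self, macarthur_pair):
        state = integrate_to_steady_state(
            macarthur_pair, options=IntegrationOptions(method="ode"))
        kkt_dyn = kkt_residuals(macarthur_pair, state)
        res = solve_equilibrium(macarthur_pair)
        assert max(kkt_dyn.values()) < 1e-6
        assert max(res.kkt.values()) < 1e-6


class TestEssentialEM:
    def _single(self):
        return CRMSystem(c=[[1.0, 2.0]], m=[1.0], kind="essential",
                         kappa=[2.0, 2.0], omega=[1.0, 1.0], v=[[1.0, 1.0]],
                         liebig=True)

    def test_infeasible_species_leave_supply_untouched(self):
        sysm = CRMSystem(c=[[1.0, 2.0]], m=[50.0], kind="essential",
                         kappa=[2.0, 2.0], omega=[1.0, 1.0], v=[[1.0, 1.0]],
                         liebig=True)
        res = em_essential(sysm)
        assert np.all(res.N_opt == 0)
        assert np.allclose(res.R_opt, [2.0, 2.0])
        assert np.allclose(res.supply_point, [2.0, 2.0])

    def test_effective_supply_self_consistent(self):
        sysm = self._single()
        res = em_essential(sysm)
        assert res.converged
        # recompute the effective supply at the returned state
        beta = sysm.limiting_resource(res.R_opt)
        uptake = np.min(sysm.c * res.R_opt[None, :], axis=1)
        R0 = sysm.supply_point.copy()
        for a in range(2):
            drain = sum(res.N_opt[i] * sysm.v[i, a] * uptake[i]
                        for i in range(1) if beta[i] != a)
            R0[a] -= drain / sysm.omega[a]
        assert np.allclose(R0, res.supply_point, atol=1e-8)

    def test_em_matches_ode_oracle(self):
        sysm = self._single()
        res = em_essential(sysm)
        state = integrate_to_steady_state(
            sysm, options=IntegrationOptions(method="ode"))
        assert state.converged
        assert np.allclose(res.N_opt, state.N, atol=1e-4)
        assert np.allclose(res.R_opt, state.R, atol=1e-4)
        # closed-form oracle: N = 1, R = (1, 1)
        assert np.allclose(res.N_opt, [1.0], atol=1e-8)
        assert np.allclose(res.R_opt, [1.0, 1.0], atol=1e-8)

    def test_two_species_em_vs_ode(self):
        sysm = CRMSystem(c=[[1.0, 2.0], [2.0, 1.0]], m=[1.0, 1.0],
                         kind="essential", kappa=[3.0, 3.0], omega=[1.0, 1.0],
                         v=[[1.0, 0.2], [0.2, 1.0]], liebig=True)
        res = em_essential(sysm)
        state = integrate_to_steady_state(
            sysm, options=IntegrationOptions(method="ode"))
        assert res.converged and state.converged
        assert np.allclose(res.N_opt, state.N, atol=1e-4)
        assert np.allclose(res.R_opt, state.R, atol=1e-4)
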