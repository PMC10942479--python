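"""Effective-GLV reductions and two-species coexistence analysis."""
import numpy as np
import pytest

from ecocavity._solvers import glv_support_iteration
from ecocavity.glv_reduction import (effective_glv, invasion_analysis,
                                     niche_overlap, resource_equilibrium)
from ecocavity.dynamics import IntegrationOptions, integrate_to_steady_state
from ecocavity.systems import CRMSystem, GLVSystem


def _mcrm(c, m, K, r=None, d=None):
    K = np.asarray(K, float)
    return CRMSystem(c=c, m=m, kind="self_renewing", K=K,
                     r_res=K if r is None else r, d=d)


class TestResourceEquilibrium:
    def test_empty_community_returns_supply_point(self):
        sysm = _mcrm([[0.5, 0.3]], [1.0], [2.0, 3.0])
        assert np.allclose(resource_equilibrium(sysm, np.zeros(1)), [2, 3])
        syse = CRMSystem(c=[[0.5, 0.3]], m=[1.0], kind="external",
                         kappa=[2.0, 3.0], omega=[2.0, 1.0])
        assert np.allclose(resource_equilibrium(syse, np.zeros(1)), [1, 3])

    def test_overdepletion_clamps_to_zero(self):
        sysm = _mcrm([[1.0, 0.1]], [0.5], [1.0, 1.0], r=[0.5, 2.0])
        R = resource_equilibrium(sysm, np.array([1.0]))
        assert R[0] == 0.0 and R[1] > 0

    def test_reduced_growth_matches_full_dynamics(self):
        # plugging R(N) into the consumer equation reproduces dN/dt
        rng = np.random.default_rng(0)
        sysm = _mcrm(rng.uniform(0, 0.3, (6, 8)), rng.uniform(0.2, 0.6, 6),
                     rng.uniform(0.5, 2.0, 8))
        N = rng.uniform(0, 1.0, 6)
        R = resource_equilibrium(sysm, N)
        dN_direct, _ = sysm.rhs(N, R)
        eff = effective_glv(sysm, N)
        alive = R > 0
        dN_reduced = N * (eff.r_eff - eff.alpha @ N)
        assert np.max(np.abs(dN_direct - dN_reduced)) < 1e-8

    def test_essential_resources_unsupported(self):
        syse = CRMSystem(c=[[1, 1]], m=[1.0], kind="essential", kappa=[1, 1],
                         omega=[1, 1], v=[[1, 1]], liebig=True)
        with pytest.raises(ValueError):
            resource_equilibrium(syse, np.zeros(1))


class TestEffectiveGLV:
    def test_orthogonal_consumers_give_identity_competition(self):
        sysm = _mcrm([[1, 0], [0, 1]], [0.3, 0.6], [1.0, 1.0])
        eff = effective_glv(sysm)
        assert np.allclose(eff.alpha, np.eye(2))
        assert np.allclose(eff.r_eff, [0.7, 0.4])
        assert eff.exactness == "exact"

    def test_reciprocal_depletion_gives_symmetric_alpha(self):
        rng = np.random.default_rng(1)
        sysm = _mcrm(rng.uniform(0, 0.5, (4, 6)), rng.uniform(0.2, 0.5, 4),
                     rng.uniform(0.5, 2, 6))
        eff = effective_glv(sysm)
        assert np.allclose(eff.alpha, eff.alpha.T)
        evals = np.linalg.eigvalsh(eff.alpha)
        assert evals.min() > -1e-12  # positive semidefinite

    def test_external_alpha_matches_finite_difference(self):
        rng = np.random.default_rng(2)
        syse = CRMSystem(c=rng.uniform(0, 0.4, (3, 5)), m=rng.uniform(0.2, 0.5, 3),
                         kind="external", kappa=rng.uniform(0.5, 1.5, 5),
                         omega=rng.uniform(0.5, 1.5, 5))
        Nref = rng.uniform(0.1, 1.0, 3)
        eff = effective_glv(syse, Nref)
        assert eff.exactness == "local"

        def growth(N):
            R = resource_equilibrium(syse, N)
            return syse.c @ (syse.w * R) - syse.m

        h = 1e-6
        fd = np.zeros((3, 3))
        for j in range(3):
            up, dn = Nref.copy(), Nref.copy()
            up[j] += h
            dn[j] -= h
            fd[:, j] = -(growth(up) - growth(dn)) / (2 * h)
        assert np.max(np.abs(fd - eff.alpha)) < 1e-6

    def test_exactness_when_no_resource_extinct(self):
        # the effective-GLV fixed point coincides with the full CRM one
        rng = np.random.default_rng(3)
        for _ in range(20):
            sysm = _mcrm(rng.uniform(0, 0.15, (5, 8)), rng.uniform(0.1, 0.3, 5),
                         rng.uniform(0.8, 1.5, 8))
            state = integrate_to_steady_state(sysm)
            if not np.all(state.R > 0):
                continue
            eff = effective_glv(sysm)
            N_eff, info = glv_support_iteration(eff.alpha, eff.r_eff)
            assert info["converged"]
            assert np.max(np.abs(N_eff - state.N)) < 1e-7

    def test_empty_resource_set_rejected(self):
        sysm = _mcrm([[1.0]], [0.5], [1.0])
        with pytest.raises(ValueError):
            effective_glv(sysm, np.array([5.0]))


class TestInvasionAnalysis:
    def test_moderate_overlap_coexists(self):
        rep = invasion_analysis(np.ones(2), np.array([[1, 0.5], [0.5, 1]]))
        assert rep["label"] == "mutual-coexistence"
        assert np.allclose(rep["invasion_products"], 2.0)

    def test_identical_species_marginal(self):
        rep = invasion_analysis(np.ones(2), np.ones((2, 2)))
        assert rep["label"] == "marginal"
        assert np.allclose(rep["invasion_growth_rates"], 0.0)

    def test_strong_overlap_bistable(self):
        rep = invasion_analysis(np.ones(2), np.array([[1, 2.0], [2.0, 1]]))
        assert rep["label"] == "bistable-priority-effect"
        assert np.allclose(rep["invasion_products"], 0.5)

    def test_nonpositive_self_interaction_rejected(self):
        with pytest.raises(ValueError):
            invasion_analysis(np.ones(2), np.array([[0.0, 1], [1, 1]]))

    def test_labels_match_direct_integration(self):
        # invasion labels agree with 2-species GLV runs from both
        # single-resident starts
        rng = np.random.default_rng(4)
        checked = 0
        while checked < 100:
            r = rng.uniform(0.5, 1.5, 2)
            off = rng.uniform(0.1, 1.9, 2)
            alpha = np.array([[1.0, off[0]], [off[1], 1.0]])
            rep = invasion_analysis(r, alpha)
            if rep["label"] == "marginal":
                continue
            sysg = GLVSystem(r=r, A=alpha)
            outcomes = []
            for resident in (0, 1):
                x0 = np.array([1e-6, 1e-6])
                x0[resident] = r[resident]  # resident at its equilibrium
                state = integrate_to_steady_state(
                    sysg, initial_condition=x0,
                    options=IntegrationOptions(method="ode"))
                outcomes.append(frozenset(np.flatnonzero(state.N > 0)))
            if rep["label"] == "mutual-coexistence":
                assert outcomes[0] == outcomes[1] == frozenset({0, 1})
            elif rep["label"] == "0-excludes-1":
                assert outcomes[0] == outcomes[1] == frozenset({0})
            elif rep["label"] == "1-excludes-0":
                assert outcomes[0] == outcomes[1] == frozenset({1})
            else:  # bistable: each resident repels the invader
                assert outcomes[0] == frozenset({0})
                assert outcomes[1] == frozenset({1})
            checked += 1


class TestNicheOverlap:
    def test_band_from_symmetric_competition(self):
        out = niche_overlap(np.array([[1, 0.5], [0.5, 1]]), np.array([1.0, 1.0]))
        assert out["rho"] == pytest.approx(0.5)
        assert out["band"] == (0.5, 2.0)
        assert out["coexists"]

    def test_orthogonal_consumers_have_zero_overlap(self):
        out = niche_overlap(np.eye(2))
        assert out["rho"] == 0.0 and out["band"][1] == np.inf

    def test_identical_consumers_leave_no_room(self):
        out = niche_overlap(np.ones((2, 2)), np.array([1.0, 1.2]))
        assert out["rho"] == pytest.approx(1.0)
        assert not out["coexists"]

    def test_negative_product_flagged_complex(self):
        out = niche_overlap(np.array([[1, -0.5], [0.5, 1]]))
        assert out["complex_overlap"] and out["band"] is None

    def test_band_test_equivalent_to_two_sided_inequality(self):
        # with context-independent, reciprocal competition and equal
        # self-limitation the overlap band (rho, 1/rho) reproduces the
        # two-sided invasion inequality exactly
        rng = np.random.default_rng(5)
        for _ in range(200):
            r = rng.uniform(0.5, 1.5, 2)
            diag = rng.uniform(0.5, 1.5)
            a = rng.uniform(0.05, diag * 0.99)
            alpha = np.array([[diag, a], [a, diag]])
            band = niche_overlap(alpha, r)
            two_sided = (alpha[0, 0] / alpha[1, 0] > r[0] / r[1]
                         > alpha[0, 1] / alpha[1, 1])
            assert band["coexists"] == two_sided
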