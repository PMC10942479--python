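"""Two-resource graphical theory: ZNGIs, cones, classification, stability."""
import numpy as np
import pytest

from ecocavity.dynamics import IntegrationOptions, integrate_to_steady_state
from ecocavity.niche_geometry import (build_diagram, classify_supply_point,
                                      fixed_point_stability)
from ecocavity.systems import CRMSystem, SteadyState


def _orthogonal_pair(K=(2.0, 2.0)):
    return CRMSystem(c=[[1, 0], [0, 1]], m=[1, 1], kind="self_renewing",
                     K=list(K), r_res=[1, 1])


def _generic_pair(kind="self_renewing", **kw):
    base = dict(c=[[0.5, 0.3], [0.3, 0.6]], m=[1.0, 1.0])
    if kind == "self_renewing":
        return CRMSystem(**base, kind=kind, K=kw.get("K", [4, 4]), r_res=[1, 1])
    return CRMSystem(**base, kind="external", kappa=kw.get("kappa", [4, 4]),
                     omega=[1, 1])


class TestDiagram:
    def test_requires_two_resources(self):
        sysm = CRMSystem(c=np.ones((2, 3)), m=[1, 1], kind="self_renewing",
                         K=np.ones(3), r_res=np.ones(3))
        with pytest.raises(ValueError):
            build_diagram(sysm)

    def test_mcrm_impacts_perpendicular_to_zngis(self):
        d = build_diagram(_generic_pair())
        for i in range(2):
            q = d.impact_vector(i, np.array([1.0, 1.0]))
            g = d.zngi_gradient(i, np.array([1.0, 1.0]))
            cosang = q @ g / np.linalg.norm(q) / np.linalg.norm(g)
            assert abs(abs(cosang) - 1.0) < 1e-12  # (anti)parallel to gradient

    def test_mcrm_neighboring_cone_inner_boundaries_parallel(self):
        d = build_diagram(_generic_pair())
        coex = next(c for c in d.cones if len(c.species) == 2)
        for b in d.cones:
            if len(b.species) != 1:
                continue
            i = b.species[0]
            shared_col = list(coex.species).index(i)
            v1 = coex.generators[:, shared_col]
            v2 = b.generators[:, 0]
            cross = v1[0] * v2[1] - v1[1] * v2[0]
            assert abs(cross) < 1e-12

    def test_liebig_zngi_corner_avoids_axes(self):
        sysm = CRMSystem(c=[[1.0, 1.0]], m=[1.0], kind="essential",
                         kappa=[2, 2], omega=[1, 1], v=[[1, 1]], liebig=True)
        d = build_diagram(sysm)
        # the L-shaped isocline min(R1, R2) = 1: growth changes sign across
        # the corner arms and is negative near both axes
        assert d.zngi_residual(0, [1.0, 5.0]) == pytest.approx(0.0, abs=1e-12)
        assert d.zngi_residual(0, [5.0, 1.0]) == pytest.approx(0.0, abs=1e-12)
        assert d.zngi_residual(0, [0.01, 100.0]) < 0
        assert d.zngi_residual(0, [100.0, 0.01]) < 0


class TestClassification:
    def test_orthogonal_consumers_coexist_at_balanced_supply(self):
        d = build_diagram(_orthogonal_pair())
        assert classify_supply_point(d, np.array([2.0, 2.0]))["label"] == "coexistence"

    def test_unreachable_zngi_gives_exclusion(self):
        d = build_diagram(_orthogonal_pair())
        out = classify_supply_point(d, np.array([2.0, 0.5]))
        assert out["label"] == "exclusion"
        assert out["winner"] == 0

    def test_supply_below_both_zngis_starves_everyone(self):
        d = build_diagram(_orthogonal_pair())
        assert classify_supply_point(
            d, np.array([0.5, 0.5]))["label"] == "no-species-survives"

    def test_boundary_cone_label_for_lopsided_supply(self):
        # rescaled resources (r_a = K_a): a very lopsided supply drives the
        # scarce resource extinct and leaves a single survivor
        sysm = CRMSystem(c=[[0.5, 0.3], [0.3, 0.6]], m=[1.0, 1.0],
                         kind="self_renewing", K=[12.0, 0.1], r_res=[12.0, 0.1])
        out = classify_supply_point(build_diagram(sysm))
        assert out["label"] == "single-species-resource-extinction"
        assert out["winner"] == 0
        state = integrate_to_steady_state(sysm)
        assert set(np.flatnonzero(state.N > 0)) == {0}
        assert np.sum(state.R > 0) == 1

    def test_degenerate_parallel_zngis_flagged(self):
        sysm = CRMSystem(c=[[1, 1], [2, 2]], m=[1, 2], kind="self_renewing",
                         K=[2, 2], r_res=[1, 1])
        d = build_diagram(sysm)
        assert classify_supply_point(d, np.array([2.0, 2.0]))["label"] == "degenerate"

    def test_labels_match_integration_on_random_instances(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 100:
            sysm = CRMSystem(
                c=rng.uniform(0.2, 1.5, (2, 2)), m=rng.uniform(0.5, 1.5, 2),
                kind="self_renewing", K=rng.uniform(0.5, 3.0, 2),
                r_res=np.ones(2))
            out = classify_supply_point(build_diagram(sysm))
            if out["label"] in ("boundary", "degenerate"):
                continue
            state = integrate_to_steady_state(sysm)
            surv = set(np.flatnonzero(state.N > 0))
            if out["label"] == "coexistence":
                assert surv == set(out["cone"].species)
            elif out["label"] == "exclusion":
                assert surv == {out["winner"]} and np.all(state.R > 0)
            elif out["label"] == "single-species-resource-extinction":
                assert surv == {out["winner"]} and np.sum(state.R > 0) == 1
            else:
                assert not surv
            checked += 1

    def test_mcrm_cones_cover_distant_supply_directions(self):
        # competitive exclusion saturates for large supply: distant supply
        # points essentially always land inside some cone
        d = build_diagram(_generic_pair())
        rng = np.random.default_rng(2)
        theta = rng.uniform(0.02, np.pi / 2 - 0.02, 400)
        inside = 0
        for t in theta:
            R0 = 60.0 * np.array([np.cos(t), np.sin(t)])
            label = classify_supply_point(d, R0)["label"]
            inside += label in ("coexistence", "single-species-resource-extinction",
                                "boundary")
        assert inside / theta.size > 0.97

    def test_external_supply_leaves_finite_fraction_uncovered(self):
        d = build_diagram(_generic_pair(kind="external"))
        rng = np.random.default_rng(3)
        theta = rng.uniform(0.02, np.pi / 2 - 0.02, 400)
        outside = 0
        for t in theta:
            R0 = 60.0 * np.array([np.cos(t), np.sin(t)])
            outside += classify_supply_point(d, R0)["label"] == "exclusion"
        assert outside / theta.size > 0.1


class TestStability:
    def test_mcrm_coexistence_point_is_stable(self, macarthur_pair):
        state = integrate_to_steady_state(macarthur_pair)
        rep = fixed_point_stability(macarthur_pair, state)
        assert rep["stable"]

    def test_essential_stoichiometry_orientation_decides_stability(self):
        # same ZNGIs and cone; impact aligned with own limiting resource is
        # stable, the swapped assignment is not
        def make(v):
            return CRMSystem(c=[[1, 2], [2, 1]], m=[1, 1], kind="essential",
                             kappa=[3, 3], omega=[1, 1], v=v, liebig=True)

        labels = {}
        for name, v in (("aligned", [[1, 0.2], [0.2, 1]]),
                        ("swapped", [[0.2, 1], [1, 0.2]])):
            sysm = make(v)
            N = np.linalg.solve(np.array(v).T, np.array([2.0, 2.0]))
            state = SteadyState(N=N, R=np.array([1.0, 1.0]))
            rep = fixed_point_stability(sysm, state)
            labels[name] = rep["stable"]
            assert rep["graphical_agrees"]
        assert labels["aligned"] and not labels["swapped"]

    def test_invadable_boundary_point_is_unstable(self, macarthur_pair):
        resident = CRMSystem(c=macarthur_pair.c[[1]], m=macarthur_pair.m[[1]],
                             kind="self_renewing", K=macarthur_pair.K,
                             r_res=macarthur_pair.r_res)
        st1 = integrate_to_steady_state(resident, options=IntegrationOptions(method="ode"))
        state = SteadyState(N=np.array([0.0, st1.N[0]]), R=st1.R)
        rep = fixed_point_stability(macarthur_pair, state)
        assert not rep["stable"]

    def test_non_fixed_point_rejected(self, macarthur_pair):
        with pytest.raises(ValueError):
            fixed_point_stability(
                macarthur_pair, SteadyState(N=np.array([5.0, 5.0]), R=np.array([1.0, 1.0])))
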