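"""Two-resource graphical niche theory.

Builds the classical diagram in the plane of resource abundances: each
species' zero net growth isocline (ZNGI, the set of environments where its
growth rate vanishes), its impact vector, the supply point, and the
coexistence cones spanned by the negative impact vectors at ZNGI
intersections.  A supply point inside a cone admits a feasible equilibrium
with the anchoring species set; the classifier also verifies positivity
and noninvasibility so that its label matches the outcome of direct
integration.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .systems import CRMSystem, SteadyState

__all__ = [
    "NicheDiagram2D",
    "Cone",
    "build_diagram",
    "classify_supply_point",
    "fixed_point_stability",
]

_CONE_TOL = 1e-8


@dataclass
class Cone:
    """Coexistence cone anchored at a ZNGI intersection or axis crossing.

    ``generators`` are the column directions spanning the cone (negative
    impact vectors of the anchoring species, plus the axis direction of the
    extinct resource for boundary cones).
    """

    anchor: np.ndarray
    species: tuple
    extinct_resources: tuple
    generators: np.ndarray  # 2 x n_generators

    def contains(self, h: np.ndarray, tol: float = _CONE_TOL):
        """Nonnegative-least-squares membership test: h = sum_k x_k g_k,
        x >= 0.  Returns (inside, coefficients, residual)."""
        x, res = nnls(self.generators, np.asarray(h, dtype=float))
        inside = res <= tol * max(1.0, float(np.linalg.norm(h)))
        return inside, x, res


@dataclass
class NicheDiagram2D:
    system: CRMSystem
    cones: list = field(default_factory=list)
    supply_point: np.ndarray | None = None

    def zngi_residual(self, i: int, R: np.ndarray) -> float:
        return float(self.system.growth_rates(np.asarray(R, float))[i])

    def impact_vector(self, i: int, R: np.ndarray) -> np.ndarray:
        return _impact(self.system, i, np.asarray(R, dtype=float))

    def zngi_gradient(self, i: int, R: np.ndarray) -> np.ndarray:
        return _growth_gradient(self.system, i, np.asarray(R, dtype=float))


def _impact(system: CRMSystem, i: int, R: np.ndarray) -> np.ndarray:
    """Per-capita impact vector q_i(R) on the (rescaled) resource dynamics.

    MacArthur uses the conventional rescaling of the resource equilibrium
    condition by w/R, which makes q_i = -w * c_i independent of R and
    perpendicular to the ZNGI; the external-supply model keeps the bare
    q_i = -c_i * R; essential resources deplete in stoichiometric
    proportion to total uptake.
    """
    if system.kind == "self_renewing":
        return -system.w * system.c[i]
    if system.kind == "external":
        return -system.c[i] * R
    return -system.v[i] * float(system.uptake(R)[i])


def _growth_gradient(system: CRMSystem, i: int, R: np.ndarray) -> np.ndarray:
    if system.kind != "essential":
        return system.e[i] * system.w * system.c[i]
    beta = int(system.limiting_resource(R)[i])
    grad = np.zeros(system.M)
    grad[beta] = system.e[i] * system.c[i, beta]
    return grad


def _supply_vector(system: CRMSystem, R: np.ndarray) -> np.ndarray:
    """Supply component of the (rescaled, for MacArthur) resource dynamics."""
    if system.kind == "self_renewing":
        return system.w * (system.r_res / system.K) * (system.K - R)
    return system.kappa - system.omega * R


def _zngi_points(system: CRMSystem, i: int):
    """Anchor-relevant points of species i's ZNGI: axis crossings for
    substitutable resources, the corner for Liebig essential resources."""
    w, c, m = system.w, system.c[i], system.m[i]
    if system.kind != "essential":
        pts = []
        for a in range(2):
            if w[a] * c[a] > 0:
                R = np.zeros(2)
                R[a] = m / (w[a] * c[a])
                pts.append(("axis", 1 - a, R))  # resource 1-a extinct there
        return pts
    corner = np.array([m / c[0], m / c[1]])
    return [("corner", None, corner)]


def _pairwise_intersection(system: CRMSystem, i: int, j: int):
    if system.kind != "essential":
        Aw = np.vstack([system.w * system.c[i], system.w * system.c[j]])
        b = np.array([system.m[i], system.m[j]])
        try:
            R = np.linalg.solve(Aw, b)
        except np.linalg.LinAlgError:
            return None
        return R if np.all(R > 0) else None
    # Liebig L-curves: intersection of the two corners' arms; generic case is
    # each species limited by a different resource
    ci, cj = system.c[i], system.c[j]
    mi, mj = system.m[i], system.m[j]
    for lim_i in (0, 1):
        lim_j = 1 - lim_i
        R = np.zeros(2)
        R[lim_i] = mi / ci[lim_i]
        R[lim_j] = mj / cj[lim_j]
        if ci[lim_i] * R[lim_i] <= ci[lim_j] * R[lim_j] + 1e-12 and \
           cj[lim_j] * R[lim_j] <= cj[lim_i] * R[lim_i] + 1e-12:
            return R
    return None


def build_diagram(system: CRMSystem) -> NicheDiagram2D:
    """Construct the two-resource niche diagram with its coexistence cones."""
    if system.M != 2:
        raise ValueError("the graphical construction requires exactly M = 2 resources")
    diagram = NicheDiagram2D(system=system)
    if system.kind == "self_renewing":
        diagram.supply_point = system.K.copy()
    else:
        diagram.supply_point = system.kappa / system.omega
    S = system.S
    # two-species cones at ZNGI intersections not shaded by a third species
    for i in range(S):
        for j in range(i + 1, S):
            R = _pairwise_intersection(system, i, j)
            if R is None:
                continue
            others = [k for k in range(S) if k not in (i, j)]
            if others and np.any(system.growth_rates(R)[others] > _CONE_TOL):
                continue  # a third species re-invades here
            gens = np.column_stack([-_impact(system, i, R), -_impact(system, j, R)])
            diagram.cones.append(Cone(anchor=R, species=(i, j),
                                      extinct_resources=(), generators=gens))
    # single-species boundary cones at ZNGI-axis crossings (resource extinct)
    for i in range(S):
        for tag, extinct, R in _zngi_points(system, i):
            if tag != "axis":
                continue
            others = [k for k in range(S) if k != i]
            if others and np.any(system.growth_rates(R)[others] > _CONE_TOL):
                continue
            # at a boundary equilibrium the extinct resource's supply must be
            # over-absorbed (r_b <= sum_j d_jb N_j), so the slack generator
            # points along MINUS the extinct-resource axis
            axis_dir = np.zeros(2)
            axis_dir[extinct] = -1.0
            gens = np.column_stack([-_impact(system, i, R), axis_dir])
            diagram.cones.append(Cone(anchor=R, species=(i,),
                                      extinct_resources=(extinct,), generators=gens))
    return diagram


def classify_supply_point(diagram: NicheDiagram2D, supply_point=None, tol: float = _CONE_TOL) -> dict:
    """Outcome of competition for a given supply point.

    Returns a dict with ``label`` in {'coexistence', 'exclusion',
    'single-species-resource-extinction', 'no-species-survives',
    'boundary'} plus the matching cone (if any) and the winner for
    exclusion outcomes.
    """
    system = diagram.system
    R0 = np.asarray(
        diagram.supply_point if supply_point is None else supply_point, dtype=float)
    if np.any(R0 <= 0):
        raise ValueError("supply point must have positive coordinates")
    # degenerate (parallel) ZNGIs
    if system.kind != "essential" and system.S >= 2:
        G = system.w * system.c  # gradients
        for i in range(system.S):
            for j in range(i + 1, system.S):
                cross = G[i, 0] * G[j, 1] - G[i, 1] * G[j, 0]
                norm = np.linalg.norm(G[i]) * np.linalg.norm(G[j])
                if norm > 0 and abs(cross) < 1e-12 * norm:
                    return {"label": "degenerate", "cone": None, "winner": None,
                            "detail": f"parallel ZNGIs for species {i} and {j}"}
    growth_at_supply = system.growth_rates(R0)
    if np.all(growth_at_supply < -tol):
        return {"label": "no-species-survives", "cone": None, "winner": None,
                "detail": "supply point lies below every ZNGI"}
    hits = []
    for cone in diagram.cones:
        # the anchoring species must be able to grow somewhere reachable:
        # their ZNGIs must lie below the supply point
        if system.kind != "essential" and \
           np.any(system.growth_rates(R0)[list(cone.species)] < -tol):
            continue
        inside, x, res = cone.contains(_supply_vector_at(system, cone.anchor, R0), tol)
        if inside:
            hits.append((cone, x, res))
    if not hits:
        # exclusion: the winner is the feasible species whose single-species
        # equilibrium no other species can invade
        winner = _exclusion_winner(system, R0, growth_at_supply, tol)
        return {"label": "exclusion", "cone": None, "winner": winner,
                "detail": "supply point outside all cones"}
    # boundary tie: supply on the common face of two cones
    if len(hits) > 1:
        interior = [h for h in hits if np.all(h[1] > tol)]
        if len(interior) != 1:
            return {"label": "boundary", "cone": [h[0] for h in hits],
                    "winner": None, "detail": "supply point on a cone boundary"}
        hits = interior
    cone, x, res = hits[0]
    if np.any(x <= tol):
        return {"label": "boundary", "cone": cone, "winner": None,
                "detail": "supply point on a cone boundary"}
    if cone.extinct_resources:
        return {"label": "single-species-resource-extinction", "cone": cone,
                "winner": cone.species[0],
                "detail": f"resource {cone.extinct_resources[0]} driven extinct"}
    return {"label": "coexistence", "cone": cone, "winner": None,
            "detail": f"species {cone.species} coexist"}


def _exclusion_winner(system: CRMSystem, R0: np.ndarray, growth_at_supply, tol: float):
    """Winner when the supply point lies outside every cone: the species
    whose single-species equilibrium is uninvadable by all others."""
    from scipy.optimize import brentq

    candidates = np.flatnonzero(growth_at_supply > tol)

    def equilibrium_R(i):
        def g_of_n(n):
            N = np.zeros(system.S)
            N[i] = n
            if system.kind == "self_renewing":
                R = np.maximum(0.0, R0 * (1.0 - n * system.d[i] / system.r_res))
            else:
                R = system.omega * R0 / (system.omega + n * system.c[i])
            return float(system.growth_rates(R)[i]), R

        lo, hi = 0.0, 1.0
        while g_of_n(hi)[0] > 0 and hi < 1e12:
            hi *= 2.0
        n_star = brentq(lambda n: g_of_n(n)[0], lo, hi, xtol=1e-14)
        return g_of_n(n_star)[1]

    for i in candidates:
        R_star = equilibrium_R(i)
        others = [k for k in range(system.S) if k != i]
        if not others or np.all(system.growth_rates(R_star)[others] <= tol):
            return int(i)
    return int(np.argmax(growth_at_supply)) if candidates.size else None


def _supply_vector_at(system: CRMSystem, anchor: np.ndarray, R0: np.ndarray) -> np.ndarray:
    """Supply vector evaluated at the anchor, for the candidate supply point
    R0 (the diagram's own supply parameters are overridden by R0)."""
    if system.kind == "self_renewing":
        return system.w * (system.r_res / system.K) * (R0 - anchor)
    return system.omega * (R0 - anchor)


def plot_diagram(diagram: NicheDiagram2D, path=None, r_max: float | None = None):
    """Render the diagram (ZNGIs, negative impact vectors at cone anchors,
    supply point) to vector graphics.  Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    system = diagram.system
    sp = diagram.supply_point
    r_max = r_max or 1.5 * float(np.max(sp))
    fig, ax = plt.subplots(figsize=(5, 5))
    grid = np.linspace(1e-3, r_max, 250)
    X, Y = np.meshgrid(grid, grid)
    for i in range(system.S):
        G = np.array([
            system.growth_rates(np.array([x, y]))[i]
            for x, y in zip(X.ravel(), Y.ravel())]).reshape(X.shape)
        ax.contour(X, Y, G, levels=[0.0], colors=[f"C{i}"])
    for cone in diagram.cones:
        for k in range(cone.generators.shape[1]):
            g = cone.generators[:, k]
            g = g / max(np.linalg.norm(g), 1e-12) * 0.15 * r_max
            ax.annotate("", xy=cone.anchor + g, xytext=cone.anchor,
                        arrowprops=dict(arrowstyle="->", color="0.4"))
        ax.plot(*cone.anchor, "ko", ms=3)
    ax.plot(*sp, "k*", ms=10, label="supply point")
    ax.set_xlim(0, r_max)
    ax.set_ylim(0, r_max)
    ax.set_xlabel(r"$R_1$")
    ax.set_ylabel(r"$R_2$")
    ax.legend(loc="upper right", frameon=False)
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def _numerical_jacobian(system: CRMSystem, N: np.ndarray, R: np.ndarray, eps: float = 1e-7):
    S, M = system.S, system.M

    def f(x):
        dN, dR = system.rhs(x[:S], x[S:])
        return np.concatenate([dN, dR])

    x0 = np.concatenate([N, R])
    n = x0.size
    J = np.zeros((n, n))
    for k in range(n):
        h = eps * max(1.0, abs(x0[k]))
        xp, xm = x0.copy(), x0.copy()
        xp[k] += h
        xm[k] -= h
        J[:, k] = (f(xp) - f(xm)) / (2 * h)
    return J


def fixed_point_stability(system: CRMSystem, state: SteadyState, tol: float = 1e-6) -> dict:
    """Linear stability of a converged fixed point.

    The authoritative test is the sign of the leading real part of the full
    (N, R) Jacobian restricted to the non-extinct coordinates.  For
    two-species/two-resource interior points the classical graphical
    criterion (orientation of the impact vectors versus the ZNGI
    gradients) is evaluated as a cross-check.
    """
    N, R = state.N, state.R
    dN, dR = system.rhs(N, R)
    if max(np.max(np.abs(dN)), np.max(np.abs(dR))) > 1e-5:
        raise ValueError("fixed_point_stability requires a fixed point")
    # full (N, R) Jacobian: extinct coordinates contribute their diagonal
    # invasion/renewal rates, so instability against re-invasion is visible
    J = _numerical_jacobian(system, N, R)
    eig = np.linalg.eigvals(J)
    lam = float(np.max(eig.real))
    report = {
        "lambda_max": lam,
        "stable": lam < tol,
        "eigenvalues": eig,
        "graphical_stable": None,
        "graphical_agrees": None,
    }
    surv = np.flatnonzero(N > 0)
    if surv.size == 2 and system.M == 2 and np.all(R > 0):
        i, j = surv
        Q = np.column_stack([_impact(system, i, R), _impact(system, j, R)])
        G = np.column_stack([_growth_gradient(system, i, R),
                             _growth_gradient(system, j, R)])
        graphical = np.sign(np.linalg.det(Q)) == np.sign(np.linalg.det(G))
        report["graphical_stable"] = bool(graphical)
        report["graphical_agrees"] = bool(graphical == report["stable"])
    return report
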