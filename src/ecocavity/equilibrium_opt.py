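"""Uninvadable equilibria as constrained optimization problems.

Reciprocal consumer-resource communities admit two equivalent variational
characterizations of their unique uninvadable equilibrium:

* population space -- MacArthur's convex quadratic Q(N), minimized over
  N >= 0;
* environmental space -- a dissimilarity d(R0, R) between the resource
  state and the supply point R0, minimized subject to the noninvasibility
  constraints g_i(R) <= 0, with the scaled population sizes N_i/e_i
  appearing as the KKT multipliers of the constraints.

The dissimilarity is a weighted Euclidean distance for self-renewing
(logistic) resources and a weighted Kullback-Leibler divergence for
externally supplied resources.  For essential (Liebig) resources the
interactions are non-reciprocal; the equilibrium still minimizes the KL
objective but against an *effective* supply point that itself depends on
the solution, handled by an EM-style alternating iteration.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, nnls, root

log = logging.getLogger(__name__)

from . import _solvers
from .systems import CRMSystem, SteadyState

__all__ = [
    "OptimizationResult",
    "objective_value",
    "solve_equilibrium",
    "kkt_residuals",
    "em_essential",
]

KKT_TOL = 1e-6


@dataclass
class OptimizationResult:
    objective_kind: str  # 'Q_population' | 'd_euclidean' | 'd_KL'
    N_opt: np.ndarray
    R_opt: np.ndarray
    objective_value: float
    kkt: dict
    supply_point: np.ndarray
    converged: bool = True
    n_iter: int = 0
    tie_flag: bool = False

    @property
    def kkt_ok(self) -> bool:
        return all(v < KKT_TOL for v in self.kkt.values())


def objective_value(kind: str, system: CRMSystem, point: np.ndarray,
                    supply_override: np.ndarray | None = None) -> float:
    """Evaluate one of the variational objectives at a point.

    ``Q_population`` expects species abundances N; the environmental
    objectives expect a resource state R (positive for the KL kind).
    """
    point = np.asarray(point, dtype=float)
    if kind == "Q_population":
        N = point
        R = np.maximum(0.0, system.K * (1.0 - (system.d.T @ N) / system.r_res))
        alive = R > 0
        w, K, r = system.w[alive], system.K[alive], system.r_res[alive]
        resid = r - (system.c[:, alive].T @ N)
        return float(0.5 * np.sum(w * K / r * resid ** 2) + np.sum(system.m * N))
    R = point
    if kind == "d_euclidean":
        R0 = system.K if supply_override is None else supply_override
        return float(0.5 * np.sum(system.w * system.r_res / system.K * (R - R0) ** 2))
    if kind == "d_KL":
        if np.any(R <= 0):
            raise ValueError("the KL objective requires strictly positive R")
        R0 = system.supply_point if supply_override is None else supply_override
        return float(np.sum(system.omega * system.w *
                            (R0 * np.log(R0 / R) - (R0 - R))))
    raise ValueError(f"unknown objective kind {kind!r}")


def _stationarity_residual(system, N, R, R0_eff=None):
    """Residual of the steady-environment KKT condition
    0 = -dd/dR_a - sum_j (N_j/e_j) dg_j/dR_a, with one-sided slack at R=0."""
    if system.kind == "self_renewing":
        grad_d = system.w * system.r_res / system.K * (R - system.K)
        impact = system.c.T @ N * system.w  # sum_j N_j w c_ja
    elif system.kind == "external":
        R0 = system.supply_point if R0_eff is None else R0_eff
        Rsafe = np.maximum(R, 1e-300)
        grad_d = system.omega * system.w * (1.0 - R0 / Rsafe)
        impact = system.c.T @ N * system.w
    else:  # essential / Liebig: dg_j/dR_a = c_ja on the limiting resource
        R0 = system.supply_point if R0_eff is None else R0_eff
        Rsafe = np.maximum(R, 1e-300)
        grad_d = system.omega * system.w * (1.0 - R0 / Rsafe)
        beta = system.limiting_resource(R)
        impact = np.zeros(system.M)
        lam = N * np.take_along_axis(system.v, beta[:, None], axis=1).ravel()
        np.add.at(impact, beta, lam * system.c[np.arange(system.S), beta])
    s = -grad_d - impact
    res = np.where(R > 0, np.abs(s), np.maximum(0.0, s))
    return float(np.max(res, initial=0.0))


def kkt_residuals(system: CRMSystem, state: SteadyState | tuple,
                  R0_eff: np.ndarray | None = None) -> dict:
    """The four Karush-Kuhn-Tucker residuals of a candidate state:
    steady populations (complementary slackness), steady environment
    (stationarity), noninvasibility (dual of primal feasibility g <= 0),
    and population feasibility N >= 0.  All four vanish exactly at an
    uninvadable equilibrium."""
    if isinstance(state, SteadyState):
        N, R = state.N, state.R
    else:
        N, R = state
    g = system.growth_rates(R)
    return {
        "steady_populations": float(np.max(np.abs(N * g), initial=0.0)),
        "stationarity": _stationarity_residual(system, N, R, R0_eff),
        "noninvasibility": float(np.max(g, initial=0.0)),
        "feasibility": float(np.max(-N, initial=0.0)),
    }


def solve_equilibrium(system: CRMSystem, objective: str | None = None) -> OptimizationResult:
    """Compute the uninvadable equilibrium by constrained minimization.

    self_renewing -> d_euclidean with R0 = K (via the dual quadratic
    program in population space); external -> d_KL with R0 = kappa/omega;
    essential (Liebig) -> EM iteration (see :func:`em_essential`).
    The result is accepted only if all KKT residuals are below 1e-6.
    """
    if system.kind == "essential":
        return em_essential(system)
    if system.kind == "self_renewing":
        if objective is None:
            objective = "d_euclidean"
        N, R, info = _solvers.mcrm_fixed_point(system)
        kkt = kkt_residuals(system, (N, R))
        value = objective_value(objective, system,
                                N if objective == "Q_population" else R)
        return OptimizationResult(
            objective_kind=objective, N_opt=N, R_opt=R, objective_value=value,
            kkt=kkt, supply_point=system.supply_point,
            converged=info["converged"] and all(v < KKT_TOL for v in kkt.values()),
        )
    return _solve_external(system)


def _solve_external(system: CRMSystem) -> OptimizationResult:
    """KL minimization for externally supplied resources: SLSQP locates the
    active constraint set, then a Newton polish solves the equilibrium
    equations on that set to full precision."""
    R0 = system.supply_point
    w, om = system.w, system.omega
    scale = float(np.mean(R0))

    def f(R):
        Rs = np.maximum(R, 1e-12 * scale)
        return float(np.sum(om * w * (R0 * np.log(R0 / Rs) - (R0 - Rs))))

    def grad(R):
        Rs = np.maximum(R, 1e-12 * scale)
        return om * w * (1.0 - R0 / Rs)

    G = system.e[:, None] * (system.c * w[None, :])  # dg_i/dR
    cons = [{"type": "ineq",
             "fun": lambda R: -(system.growth_rates(R)),
             "jac": lambda R: -G}]
    bounds = [(1e-10 * scale, None)] * system.M
    res = minimize(f, 0.9 * R0, jac=grad, method="SLSQP", bounds=bounds,
                   constraints=cons, options={"maxiter": 500, "ftol": 1e-14})
    R = np.maximum(res.x, 1e-12 * scale)
    # recover multipliers (N/e) by nonnegative least squares on stationarity
    g = system.growth_rates(R)
    gtol = 1e-6 * max(1.0, float(np.max(np.abs(system.m))))
    active = np.flatnonzero(g > -gtol)
    N = np.zeros(system.S)
    if active.size:
        lam, _ = nnls(G[active].T, -grad(R))
        N[active] = lam * system.e[active]
    N, R, n_iter = _polish_external(system, N, R)
    kkt = kkt_residuals(system, (N, R))
    log.info("external KL solve: slsqp_iters=%d polish_rounds=%d kkt_max=%.3e",
             res.nit, n_iter, max(kkt.values()))
    # acceptance is solver-independent: the state is accepted iff the KKT
    # residuals vanish, regardless of the SLSQP status flag
    return OptimizationResult(
        objective_kind="d_KL", N_opt=N, R_opt=R,
        objective_value=f(R), kkt=kkt, supply_point=R0,
        converged=all(v < KKT_TOL for v in kkt.values()),
        n_iter=n_iter,
    )


def _polish_external(system: CRMSystem, N, R, max_rounds: int = 30):
    """Active-set Newton polish: on a candidate survivor set solve
    g_i(R(N)) = 0 with R(N) = kappa/(omega + c' N); drop negative species,
    admit invadable ones, repeat until uninvadable."""
    support = N > 1e-10 * max(1.0, float(np.max(N, initial=0.0)))
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        idx = np.flatnonzero(support)

        def eqs(x):
            Nf = np.zeros(system.S)
            Nf[idx] = x
            Rf = system.kappa / (system.omega + system.c.T @ Nf)
            return system.growth_rates(Rf)[idx]

        if idx.size:
            sol = root(eqs, np.maximum(N[idx], 1e-8), method="hybr", tol=1e-13)
            Nn = np.zeros(system.S)
            Nn[idx] = sol.x
        else:
            Nn = np.zeros(system.S)
        Rn = system.kappa / (system.omega + system.c.T @ Nn)
        neg = support & (Nn < 0)
        if neg.any():
            j = np.flatnonzero(neg)[np.argmin(Nn[neg])]
            support[j] = False
            continue
        g = system.growth_rates(Rn)
        inv = (~support) & (g > 1e-10)
        if inv.any():
            j = np.flatnonzero(inv)[np.argmax(g[inv])]
            support[j] = True
            continue
        return np.maximum(Nn, 0.0), Rn, rounds
    return np.maximum(N, 0.0), R, rounds


def em_essential(system: CRMSystem, tol: float = 1e-8, max_iter: int = 200) -> OptimizationResult:
    """Equilibrium of the Liebig (law-of-the-minimum) model by alternating
    minimization.

    E-step: from the current state, assign each species its limiting
    resource beta_i = argmin_b c_ib R_b and build the effective supply
    point, which discounts the external supply of every resource by the
    stoichiometric drain from species limited *elsewhere*.  M-step:
    minimize d_KL(R0_eff, R) subject to the (now linear) constraints
    c_i,beta_i R_beta_i <= m_i -- with frozen assignments the constraints
    are per-coordinate caps, so the minimizer is available in closed form
    -- and recover N from the binding multipliers.  Iterate until the
    effective supply point stops moving.
    """
    if system.kind != "essential" or not system.liebig:
        raise ValueError("em_essential handles the Liebig branch of essential resources")
    R0 = system.supply_point
    om, c, v, m = system.omega, system.c, system.v, system.m
    S, M = system.S, system.M
    R = R0.copy()
    N = np.zeros(S)
    R0_eff = R0.copy()
    tie_flag = False
    converged = False
    for it in range(1, max_iter + 1):
        beta = system.limiting_resource(R)
        cr = c * R[None, :]
        ties = np.sum(np.isclose(cr, cr.min(axis=1, keepdims=True)), axis=1) > 1
        tie_flag = tie_flag or bool(ties.any())
        # M-step: per-coordinate caps R_a <= min over species limited by a
        caps = np.full(M, np.inf)
        for a in range(M):
            members = np.flatnonzero(beta == a)
            if members.size:
                caps[a] = np.min(m[members] / c[members, a])
        R_new = np.minimum(R0_eff, caps)
        # multipliers of the binding caps -> populations
        N_new = np.zeros(S)
        for a in range(M):
            if not np.isfinite(caps[a]) or R_new[a] < caps[a] - 1e-14 * max(1.0, caps[a]):
                continue
            members = np.flatnonzero(beta == a)
            binding = members[np.isclose(m[members] / c[members, a], caps[a])]
            lam_total = om[a] * (R0_eff[a] / R_new[a] - 1.0)
            # generically one species binds; degenerate ties split evenly
            share = lam_total / (binding.size * c[binding, a])
            N_new[binding] = share / v[binding, a]
        # E-step: effective supply accounting for drains from species
        # limited by a different resource (uptake of the limiting one)
        uptake = np.array([c[i, beta[i]] * R_new[beta[i]] for i in range(S)])
        R0_eff_new = R0.copy()
        for a in range(M):
            drain = sum(N_new[i] * v[i, a] * uptake[i]
                        for i in range(S) if beta[i] != a and N_new[i] > 0)
            R0_eff_new[a] = R0[a] - drain / om[a]
        shift = float(np.max(np.abs(R0_eff_new - R0_eff)))
        R, N, R0_eff = R_new, N_new, R0_eff_new
        if shift < tol and it > 1:
            converged = True
            break
    kkt = kkt_residuals(system, (N, R), R0_eff=R0_eff)
    return OptimizationResult(
        objective_kind="d_KL", N_opt=N, R_opt=R,
        objective_value=objective_value("d_KL", system, np.maximum(R, 1e-300),
                                        supply_override=np.maximum(R0_eff, 1e-300)),
        kkt=kkt, supply_point=R0_eff, converged=converged,
        n_iter=it, tie_flag=tie_flag,
    )
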