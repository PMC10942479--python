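"""Integration of community dynamics to uninvadable steady states.

The generic route integrates the ODEs with a stiff-capable solver, clamps
species that fall below an extinction threshold to exactly zero, polishes
the candidate fixed point algebraically, and then enforces uninvadability
by reintroducing every extinct species at low abundance and re-integrating
until no reintroduction succeeds.

Fast paths (``method='auto'``) replace the integration by direct
fixed-point solvers where the dynamics admit one: a linear-complementarity
support iteration for GLV systems and MacArthur's quadratic program for
reciprocal consumer-resource systems.  These are cross-validated against
the ODE route in the test-suite.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import _solvers
from .systems import CRMSystem, EnsembleSummary, GLVSystem, SteadyState

log = logging.getLogger(__name__)

__all__ = [
    "IntegrationOptions",
    "integrate_to_steady_state",
    "check_uninvadable",
    "run_ensemble",
]


@dataclass
class IntegrationOptions:
    """Tolerances and guards for steady-state integration.

    extinction_rtol: abundances below extinction_rtol * (mean carrying
        capacity) after a transient are clamped to exactly zero.
    reintroduction: abundance at which extinct species are re-injected when
        enforcing uninvadability.
    unbounded_factor: abort and flag when any abundance exceeds
        unbounded_factor * (mean carrying capacity).
    """

    t_chunk: float = 100.0
    max_chunks: int = 60
    rtol: float = 1e-10
    atol: float = 1e-12
    deriv_tol: float = 1e-9
    polish_tol: float = 1e-5
    extinction_rtol: float = 1e-8
    reintroduction: float = 1e-6
    max_reintroduction_rounds: int = 20
    unbounded_factor: float = 1e6
    method: str = "auto"  # 'auto' | 'ode'
    seed: int = 0


def _scales(system) -> float:
    if isinstance(system, GLVSystem):
        return float(np.mean(np.abs(system.r))) or 1.0
    sp = system.supply_point
    return float(np.mean(np.abs(sp))) or 1.0


def _default_initial(system, rng: np.random.Generator):
    """Seeded positive initial condition: abundances uniform in
    (0.1, 1) x natural scale."""
    scale = _scales(system)
    if isinstance(system, GLVSystem):
        return scale * rng.uniform(0.1, 1.0, system.S)
    N0 = scale * rng.uniform(0.1, 1.0, system.S)
    R0 = np.maximum(system.supply_point * rng.uniform(0.5, 1.0, system.M), 1e-6)
    return np.concatenate([N0, R0])


def _pack_rhs(system):
    if isinstance(system, GLVSystem):
        return lambda t, N: system.rhs(np.maximum(N, 0.0))
    S = system.S

    def rhs(t, x):
        N = np.maximum(x[:S], 0.0)
        R = np.maximum(x[S:], 0.0)
        dN, dR = system.rhs(N, R)
        return np.concatenate([dN, dR])

    return rhs


def _polish_glv(system: GLVSystem, N, opts) -> tuple[np.ndarray, bool]:
    support = N > 0
    idx = np.flatnonzero(support)
    out = np.zeros_like(N)
    if idx.size:
        try:
            sol = np.linalg.solve(system.A[np.ix_(idx, idx)], system.r[idx])
        except np.linalg.LinAlgError:
            return N, False
        if np.any(sol < 0):
            return N, False
        out[idx] = sol
    return out, True


def _polish_crm(system: CRMSystem, N, R, opts, max_rounds: int = 200):
    """Complementarity polish of a near-steady state: Newton-solve the
    fixed-point equations on the current survivor supports, then drop
    negative abundances and admit profitable invaders (species or, for
    self-renewing resources, resources) until the state is uninvadable."""
    from scipy.optimize import root

    tol = 1e-10
    scale_R = max(float(np.mean(np.abs(system.supply_point))), 1e-12)
    floor = 1e-8 * scale_R
    sN = N > 0
    # near-zero resources are left out of the Newton support: R = 0 is a
    # degenerate root of the multiplicative dynamics and Newton sticks to
    # it; the regrow step below re-admits them at their clamp equilibrium
    sR = R > floor if system.kind == "self_renewing" else np.ones(system.M, bool)
    for _ in range(max_rounds):
        iN, iR = np.flatnonzero(sN), np.flatnonzero(sR)

        def eqs(x, iN=iN, iR=iR):
            Nf = np.zeros(system.S)
            Rf = np.zeros(system.M)
            Nf[iN] = x[: iN.size]
            Rf[iR] = x[iN.size:]
            dN, dR = system.rhs(Nf, Rf)
            g = system.growth_rates(Rf)
            return np.concatenate([g[iN], dR[iR]])

        x0 = np.concatenate([N[iN], R[iR]])
        if x0.size:
            sol = root(eqs, x0, method="hybr", tol=1e-13)
            if not sol.success and np.max(np.abs(eqs(sol.x))) > 1e-9:
                return N, R, False
            Nf = np.zeros(system.S)
            Rf = np.zeros(system.M)
            Nf[iN] = sol.x[: iN.size]
            Rf[iR] = sol.x[iN.size:]
        else:
            Nf = np.zeros(system.S)
            Rf = np.zeros(system.M)
            if system.kind != "self_renewing":
                Rf = system.supply_point.copy()
            else:
                Rf[iR] = system.K[iR]
        negN = sN & (Nf < -tol)
        if negN.any():
            sN[np.flatnonzero(negN)[np.argmin(Nf[negN])]] = False
            N = np.maximum(Nf, 0.0)
            R = np.maximum(Rf, 0.0)
            continue
        negR = sR & (Rf < floor)
        if negR.any() and system.kind == "self_renewing":
            sR[np.flatnonzero(negR)[np.argmin(Rf[negR])]] = False
            N, R = np.maximum(Nf, 0.0), np.maximum(Rf, 0.0)
            continue
        Nf = np.maximum(Nf, 0.0)
        Rf = np.maximum(Rf, 0.0)
        g = system.growth_rates(Rf)
        invN = (~sN) & (g > tol)
        if invN.any():
            sN[np.flatnonzero(invN)[np.argmax(g[invN])]] = True
            N, R = Nf, Rf
            N = N.copy()
            continue
        if system.kind == "self_renewing":
            # extinct resource alpha regrows iff r_alpha - sum_j d_ja N_j > 0
            renewal = system.r_res - system.d.T @ Nf
            regrow = (~sR) & (renewal > tol)
            if regrow.any():
                a = np.flatnonzero(regrow)[0]
                sR[a] = True
                N, R = Nf, Rf.copy()
                # seed at the clamp equilibrium so Newton leaves the R=0 root
                R[a] = max(system.K[a] * renewal[a] / system.r_res[a], 10 * floor)
                continue
        return Nf, Rf, True
    return N, R, False


def _residual(system, N, R):
    if isinstance(system, GLVSystem):
        return float(np.max(np.abs(system.rhs(N))))
    dN, dR = system.rhs(N, R)
    return float(max(np.max(np.abs(dN), initial=0.0), np.max(np.abs(dR), initial=0.0)))


def integrate_to_steady_state(
    system: GLVSystem | CRMSystem,
    initial_condition: np.ndarray | None = None,
    options: IntegrationOptions | None = None,
) -> SteadyState:
    """Integrate the dynamics to an uninvadable fixed point.

    Species whose abundance falls below the extinction threshold are set to
    exactly zero; extinct species are then reintroduced at low abundance and
    the system re-integrated until no reintroduction succeeds.  Unbounded
    trajectories are flagged rather than raised.
    """
    opts = options or IntegrationOptions()
    rng = np.random.default_rng(opts.seed)
    scale = _scales(system)
    ext = opts.extinction_rtol * scale
    cap = opts.unbounded_factor * scale

    if opts.method == "auto":
        state = _try_fast_path(system, opts, ext)
        if state is not None:
            return state

    is_glv = isinstance(system, GLVSystem)
    S = system.S
    x = (
        np.asarray(initial_condition, float)
        if initial_condition is not None
        else _default_initial(system, rng)
    )
    if np.any(x[:S] <= 0):
        raise ValueError("initial species abundances must be positive")
    rhs = _pack_rhs(system)

    total_t = 0.0
    converged = False
    unbounded = False
    for round_ in range(opts.max_reintroduction_rounds):
        t_chunk = opts.t_chunk
        for _ in range(opts.max_chunks):
            sol = solve_ivp(
                rhs, (0.0, t_chunk), x, method="LSODA",
                rtol=opts.rtol, atol=opts.atol,
            )
            total_t += t_chunk
            t_chunk = min(2.0 * t_chunk, 100.0 * opts.t_chunk)  # slow decays
            if not sol.success:
                break
            x = np.maximum(sol.y[:, -1], 0.0)
            if np.max(x) > cap:
                unbounded = True
                break
            x[:S][x[:S] < ext] = 0.0
            # per-capita rates for present coordinates (a rare invader moves
            # the absolute residual imperceptibly but must keep integrating)
            dx = np.abs(rhs(0.0, x))
            present = x > ext
            rel = (
                np.max(dx[present] / np.maximum(x[present], ext))
                if present.any() else 0.0
            )
            deriv = max(rel, np.max(dx[~present], initial=0.0) / scale)
            if deriv < opts.polish_tol:
                break
        if unbounded:
            break
        # algebraic polish on the settled support; species whose growth rate
        # is clearly negative are transients still decaying -- drop them
        # here and let the reintroduction loop correct any mistake
        g_now = (
            system.growth_rates(x[:S]) if is_glv
            else system.growth_rates(np.maximum(x[S:], 0.0))
        )
        dying = (
            (x[:S] > 0)
            & (g_now < -1e-6 * max(1.0, scale))
            & (x[:S] < 1e-3 * scale)
        )
        x = x.copy()
        x[:S][dying] = 0.0
        # a polish may only clean up an almost-converged state, never jump
        # to a different basin: reject it if it moves established
        # coordinates materially (raising a coordinate the clamped
        # trajectory pinned near zero is an artifact fix, not a jump)
        move_cap = 0.02 * max(scale, float(np.max(x, initial=0.0)))

        def _accept(new, old):
            established = old > 1e-6 * scale
            return np.max(np.abs(new - old)[established], initial=0.0) < move_cap

        if is_glv:
            N, ok = _polish_glv(system, x[:S], opts)
            R = np.empty(0)
            if ok and _accept(N, x[:S]):
                x = N
        else:
            N, R, ok = _polish_crm(system, x[:S], np.maximum(x[S:], 0.0), opts)
            if ok and _accept(np.concatenate([N, R]), x):
                x = np.concatenate([N, R])
        # uninvadability: reintroduce profitable extinct species (and, for
        # self-renewing resources, resources that a clamped trajectory
        # pinned at zero although their net renewal rate is positive --
        # the multiplicative dynamics cannot recover them on their own)
        N = x[:S]
        R = np.empty(0) if is_glv else x[S:]
        growth = (
            system.growth_rates(N) if is_glv else system.growth_rates(R)
        )
        invaders = (N <= 0) & (growth > opts.deriv_tol)
        r_floor = 1e-12 * scale
        if not is_glv and system.kind == "self_renewing":
            regrow = (R <= r_floor) & (
                (system.r_res - system.d.T @ N) > opts.deriv_tol
            )
        else:
            regrow = np.zeros(0, bool)
        resid = _residual(system, N, R)
        if (not invaders.any() and not regrow.any()
                and resid < opts.deriv_tol * max(1.0, scale)):
            converged = True
            break
        x = x.copy()
        x[:S][invaders] = opts.reintroduction * scale
        x[:S][(x[:S] > 0) & (x[:S] < ext)] = ext
        if not is_glv:
            x[S:] = np.maximum(x[S:], opts.atol)
            if regrow.any():
                x[S:][regrow] = opts.reintroduction * scale
    N = np.maximum(x[:S], 0.0)
    N[N < ext] = 0.0
    R = np.empty(0) if is_glv else np.maximum(x[S:], 0.0)
    state = SteadyState(
        N=N,
        R=R,
        converged=converged and not unbounded,
        residual=_residual(system, N, R),
        integration_time=total_t,
        unbounded=unbounded,
        extinction_threshold=ext,
    )
    state.uninvadable = converged and check_uninvadable(system, state)["uninvadable"]
    return state


def _try_fast_path(system, opts, ext) -> SteadyState | None:
    """Direct fixed-point solvers for GLV and reciprocal MacArthur systems."""
    if isinstance(system, GLVSystem):
        sym = np.allclose(system.A, system.A.T)
        if sym:
            H = 0.5 * (system.A + system.A.T)
            N, info = _solvers.nnqp(H, system.r)
        else:
            N, info = _solvers.glv_support_iteration(system.A, system.r)
        if info["unbounded"]:
            return SteadyState(
                N=N, converged=False, uninvadable=False,
                residual=np.inf, unbounded=True, extinction_threshold=ext)
        if not info["converged"]:
            return None  # fall back to integration
        N = N.copy()
        N[N < ext] = 0.0
        state = SteadyState(N=N, residual=_residual(system, N, np.empty(0)),
                            extinction_threshold=ext)
        state.uninvadable = check_uninvadable(system, state)["uninvadable"]
        return state
    if system.kind == "self_renewing" and np.allclose(system.d, system.c):
        N, R, info = _solvers.mcrm_fixed_point(system)
        if not info["converged"]:
            return None
        N = N.copy()
        N[N < ext] = 0.0
        state = SteadyState(N=N, R=R, residual=_residual(system, N, R),
                            extinction_threshold=ext)
        state.uninvadable = check_uninvadable(system, state)["uninvadable"]
        return state
    return None


def check_uninvadable(system, state: SteadyState, tol: float = 1e-7) -> dict:
    """Per-species invasion report at a fixed point.

    A state is uninvadable when every extinct species has invasion growth
    rate <= tol; surviving species sit on their zero-growth manifold.
    Lists reintroduction candidates when the condition is violated.
    """
    if isinstance(system, GLVSystem):
        growth = system.growth_rates(state.N)
    else:
        growth = system.growth_rates(state.R)
    scale = max(1.0, _scales(system))
    extinct = state.N <= 0
    candidates = np.flatnonzero(extinct & (growth > tol * scale))
    survivors_ok = (
        np.max(np.abs(growth[~extinct]), initial=0.0) <= 1e2 * tol * scale
    )
    return {
        "growth_rates": growth,
        "uninvadable": candidates.size == 0,
        "survivors_at_zero_growth": bool(survivors_ok),
        "reintroduction_candidates": candidates,
    }


def _observables(state: SteadyState, is_crm: bool) -> dict:
    obs = {
        "phi_N": state.phi_N,
        "mean_N": float(np.mean(state.N)),
        "q_N": float(np.mean(state.N ** 2)),
    }
    if is_crm:
        obs.update(
            phi_R=state.phi_R,
            mean_R=float(np.mean(state.R)),
            q_R=float(np.mean(state.R ** 2)),
        )
    return obs


def run_ensemble(
    spec,
    n_realizations: int,
    options: IntegrationOptions | None = None,
    collect_states: bool = False,
) -> EnsembleSummary:
    """Sample and solve ``n_realizations`` systems from an ensemble spec.

    Per-realization seeds are ``spec.seed + k``.  Moments average over all
    S (or M) slots, zeros included.  Non-converged realizations are counted
    in ``n_failed`` and excluded from the statistics.
    """
    from .ensembles import CRMEnsembleSpec, GLVEnsembleSpec, sample_crm_system, sample_glv_system

    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    opts = options or IntegrationOptions()
    is_crm = isinstance(spec, CRMEnsembleSpec)
    rows: list[dict] = []
    seeds = []
    states = []
    n_failed = 0
    for k in range(n_realizations):
        seed = spec.seed + k
        seeds.append(seed)
        system = (
            sample_crm_system(spec, seed=seed)
            if is_crm
            else sample_glv_system(spec, seed=seed)
        )
        state = integrate_to_steady_state(system, options=opts)
        if not (state.converged and state.uninvadable):
            n_failed += 1
            log.info("realization %d did not converge (unbounded=%s)", k, state.unbounded)
            continue
        rows.append(_observables(state, is_crm))
        if collect_states:
            states.append((system, state))
    keys = rows[0].keys() if rows else (
        ["phi_N", "mean_N", "q_N"] + (["phi_R", "mean_R", "q_R"] if is_crm else [])
    )
    observables = {k: np.array([row[k] for row in rows]) for k in keys}
    n_ok = len(rows)
    mean = {k: float(np.mean(v)) if n_ok else np.nan for k, v in observables.items()}
    sd = {k: float(np.std(v, ddof=1)) if n_ok > 1 else 0.0 for k, v in observables.items()}
    se = {k: (s / np.sqrt(n_ok) if n_ok else np.nan) for k, s in sd.items()}
    summary = EnsembleSummary(
        observables=observables, mean=mean, sd=sd, se=se,
        n_realizations=n_realizations, seeds=seeds, n_failed=n_failed,
    )
    if collect_states:
        summary.states = states
    return summary
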