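"""Random-matrix stability diagnostics.

Classical community-matrix stability (eigenvalues of a random Jacobian
with self-regulation -1 and i.i.d. off-diagonal entries, whose spectrum
fills a disk of radius sigma*sqrt(S)), the minimum eigenvalue of the
interaction matrix restricted to surviving species (whose pinning at zero
signals loss of the replica-symmetric phase and marginal stability), and
a finite-difference susceptibility oracle dN/dr = (A*)^-1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._solvers import glv_support_iteration, nnqp
from .systems import GLVSystem, SteadyState

__all__ = [
    "StabilityReport",
    "may_spectrum",
    "surviving_submatrix_mineig",
    "susceptibility_oracle",
]

MARGINALITY_TOL = 1e-3


@dataclass
class StabilityReport:
    min_eig_Astar: float
    min_real_Astar: float
    susceptibility_trace: float | None
    lambda_max: float | None
    marginal: bool
    unstable: bool
    S_star: int


def may_spectrum(S: int, sigma: float, n_draws: int = 1, seed: int = 0) -> dict:
    """Eigenvalues of random community matrices J with J_ii = -1 and
    i.i.d. off-diagonal entries of variance sigma^2.

    Returns the per-draw largest real part, its mean, and the circular-law
    edge estimate -1 + sigma*sqrt(S).
    """
    if S < 2:
        raise ValueError("S must be >= 2")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    lam_max = np.empty(n_draws)
    radii = np.empty(n_draws)
    all_eigs = []
    for k in range(n_draws):
        J = sigma * rng.standard_normal((S, S))
        np.fill_diagonal(J, -1.0)
        eigs = np.linalg.eigvals(J)
        all_eigs.append(eigs)
        lam_max[k] = float(np.max(eigs.real))
        radii[k] = float(np.max(np.abs(eigs + 1.0)))
    return {
        "lambda_max": lam_max,
        "lambda_max_mean": float(np.mean(lam_max)),
        "predicted_edge": -1.0 + sigma * np.sqrt(S),
        "circular_radius": sigma * np.sqrt(S),
        "empirical_radius_mean": float(np.mean(radii)),
        "eigenvalues": np.concatenate(all_eigs),
        "sigma_critical": 1.0 / np.sqrt(S),
    }


def surviving_submatrix_mineig(
    system: GLVSystem, state: SteadyState, marginality_tol: float = MARGINALITY_TOL
) -> StabilityReport:
    """Minimum eigenvalue of the interaction matrix restricted to the
    surviving species.

    For symmetric systems this eigenvalue controls both dynamical
    stability and the susceptibility to changes in the carrying
    capacities; its approach to zero signals divergent susceptibility and
    the breakdown of the replica-symmetric description.  For
    non-symmetric systems the minimum eigenvalue of the symmetrized part
    is reported alongside the minimum real part of the spectrum.
    """
    surv = np.flatnonzero(state.N > 0)
    if surv.size == 0:
        raise ValueError("no surviving species")
    Astar = system.A[np.ix_(surv, surv)]
    sym_eigs = np.linalg.eigvalsh(0.5 * (Astar + Astar.T))
    min_eig = float(sym_eigs[0])
    min_real = float(np.min(np.linalg.eigvals(Astar).real))
    trace = None
    if abs(np.linalg.det(Astar)) > 1e-300:
        try:
            trace = float(np.trace(np.linalg.inv(Astar)) / surv.size)
        except np.linalg.LinAlgError:
            trace = None
    # dynamical community matrix -N_i A*_ik
    J = -state.N[surv][:, None] * Astar
    lam_max = float(np.max(np.linalg.eigvals(J).real))
    return StabilityReport(
        min_eig_Astar=min_eig,
        min_real_Astar=min_real,
        susceptibility_trace=trace,
        lambda_max=lam_max,
        marginal=abs(min_eig) < marginality_tol,
        unstable=min_eig < -marginality_tol,
        S_star=int(surv.size),
    )


def _resolve(system: GLVSystem) -> np.ndarray:
    if np.allclose(system.A, system.A.T):
        N, info = nnqp(0.5 * (system.A + system.A.T), system.r)
    else:
        N, info = glv_support_iteration(system.A, system.r)
    if not info["converged"]:
        raise RuntimeError("fixed-point solve failed during susceptibility probe")
    return N


def susceptibility_oracle(
    system: GLVSystem, state: SteadyState, dr: float = 1e-6, max_retries: int = 3
) -> dict:
    """Central finite differences of the steady state with respect to each
    surviving carrying capacity, compared entrywise to (A*)^-1.

    If a perturbation changes the survivor set the step is shrunk; if that
    keeps happening the comparison is flagged (the state sits on a
    selection boundary).
    """
    surv = np.flatnonzero(state.N > 0)
    Astar = system.A[np.ix_(surv, surv)]
    analytic = np.linalg.inv(Astar)
    n = surv.size
    fd = np.zeros((n, n))
    step = dr * max(1.0, float(np.mean(np.abs(system.r))))
    flagged = False
    for attempt in range(max_retries):
        ok = True
        for b, j in enumerate(surv):
            rp = system.r.copy()
            rp[j] += step
            Np = _resolve(GLVSystem(r=rp, A=system.A))
            rm = system.r.copy()
            rm[j] -= step
            Nm = _resolve(GLVSystem(r=rm, A=system.A))
            if not (np.array_equal(Np > 0, state.N > 0)
                    and np.array_equal(Nm > 0, state.N > 0)):
                ok = False
                break
            fd[:, b] = (Np[surv] - Nm[surv]) / (2 * step)
        if ok:
            break
        step /= 10.0
    else:
        flagged = True
    max_dev = float(np.max(np.abs(fd - analytic)))
    return {
        "finite_difference": fd,
        "analytic": analytic,
        "max_abs_deviation": max_dev,
        "survivor_set_changed": flagged,
        "trace_over_S": float(np.trace(analytic)) / system.S,
    }
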