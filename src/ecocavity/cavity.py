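"""Replica-symmetric cavity solutions for random GLV and MacArthur ensembles.

In the large-S limit the distribution of steady-state abundances is a
truncated Gaussian ``max(0, (a + c z)/b)`` with z standard normal, so every
self-consistency equation can be written with the moments

    w_j(D) = int_{-D}^{inf} (z + D)^j  exp(-z^2/2)/sqrt(2 pi) dz,

which have closed forms in the standard normal CDF Phi and density phi:
w0 = Phi(D), w1 = D Phi(D) + phi(D), w2 = (1 + D^2) Phi(D) + D phi(D).

The GLV solver finds the macroscopic order parameters (survival fraction
phi_N, first two abundance moments, mean susceptibility nu); the MacArthur
solver finds the eight coupled species/resource order parameters.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import root
from scipy.stats import norm

log = logging.getLogger(__name__)

__all__ = [
    "w_moment",
    "CavityGLVSolution",
    "CavityCRMSolution",
    "solve_glv_cavity",
    "solve_crm_cavity",
    "continuation_scan",
]


def w_moment(j: int, delta):
    """j-th truncated-Gaussian moment w_j(delta), j in {0, 1, 2}."""
    delta = np.asarray(delta, dtype=float)
    Phi = norm.cdf(delta)
    phi = norm.pdf(delta)
    if j == 0:
        out = Phi
    elif j == 1:
        out = delta * Phi + phi
    elif j == 2:
        out = (1.0 + delta ** 2) * Phi + delta * phi
    else:
        raise ValueError("w_moment supports orders 0, 1, 2")
    return out if out.shape else float(out)


@dataclass
class CavityGLVSolution:
    phi_N: float
    mean_N: float
    q_N: float
    nu: float
    delta: float
    residual_norm: float
    converged: bool
    rs_valid: bool

    def as_dict(self) -> dict:
        return {
            "phi_N": self.phi_N, "mean_N": self.mean_N, "q_N": self.q_N,
            "nu": self.nu, "delta": self.delta,
            "residual_norm": self.residual_norm,
            "converged": self.converged, "rs_valid": self.rs_valid,
        }


@dataclass
class CavityCRMSolution:
    phi_N: float
    mean_N: float
    q_N: float
    phi_R: float
    mean_R: float
    q_R: float
    chi: float
    nu: float
    residual_norm: float
    converged: bool

    def as_dict(self) -> dict:
        return {
            "phi_N": self.phi_N, "mean_N": self.mean_N, "q_N": self.q_N,
            "phi_R": self.phi_R, "mean_R": self.mean_R, "q_R": self.q_R,
            "chi": self.chi, "nu": self.nu,
            "residual_norm": self.residual_norm, "converged": self.converged,
        }


def _glv_nu(phi: float, rho: float, sigma: float) -> float:
    """Solve nu = phi / (1 - rho sigma^2 nu) on the branch continuous with
    nu = phi at sigma -> 0 (the RS-valid root)."""
    a = rho * sigma ** 2
    if abs(a) < 1e-14:
        return phi
    disc = 1.0 - 4.0 * a * phi
    if disc < 0:
        return np.nan
    return (1.0 - np.sqrt(disc)) / (2.0 * a)


def solve_glv_cavity(
    mu: float,
    sigma: float,
    rho: float,
    r_mean: float = 1.0,
    sigma_r: float = 0.1,
    x0: np.ndarray | None = None,
    tol: float = 1e-12,
) -> CavityGLVSolution:
    """Solve the GLV cavity self-consistency equations.

    Unknowns are (mean_N, q_N); phi_N and nu follow analytically from the
    truncated-Gaussian argument Delta = (r - mu<N>) / sqrt(sigma_r^2 +
    sigma^2 q_N).  Requires a non-degenerate argument (sigma_r > 0 or
    sigma > 0).
    """
    if sigma <= 0 and sigma_r <= 0:
        raise ValueError("need sigma > 0 or sigma_r > 0 for a non-degenerate cavity field")

    def unpack(x):
        mean_N, q_N = x
        q_N = max(q_N, 0.0)
        denom = np.sqrt(sigma_r ** 2 + sigma ** 2 * q_N)
        delta = (r_mean - mu * mean_N) / denom
        phi = float(np.clip(w_moment(0, delta), 0.0, 1.0))
        nu = _glv_nu(phi, rho, sigma)
        return mean_N, q_N, denom, delta, phi, nu

    def residuals(x):
        mean_N, q_N, denom, delta, phi, nu = unpack(x)
        if not np.isfinite(nu):
            return np.array([1e3, 1e3])
        b = 1.0 - rho * sigma ** 2 * nu
        if b <= 0:
            return np.array([1e3, 1e3])
        r1 = mean_N - (denom / b) * w_moment(1, delta)
        r2 = q_N - (denom / b) ** 2 * w_moment(2, delta)
        return np.array([r1, r2])

    if x0 is None:
        n0 = max(r_mean / (1.0 + mu), 1e-3)
        x0 = np.array([n0, n0 ** 2])
    best = None
    for guess in (x0, np.array([0.1, 0.02]), np.array([0.5, 0.5])):
        sol = root(residuals, guess, method="hybr", tol=1e-14)
        res = float(np.max(np.abs(residuals(sol.x))))
        if best is None or res < best[1]:
            best = (sol.x, res)
        if res < 1e-10:
            break
    x, res = best
    log.info("glv cavity: sigma=%g rho=%g residual=%.3e", sigma, rho, res)
    mean_N, q_N, denom, delta, phi, nu = unpack(x)
    rs_valid = bool(
        np.isfinite(nu) and (1.0 - rho * sigma ** 2 * nu) > 0 and res < 1e-10
    )
    return CavityGLVSolution(
        phi_N=phi, mean_N=float(mean_N), q_N=float(q_N), nu=float(nu),
        delta=float(delta), residual_norm=res,
        converged=res < 1e-10, rs_valid=rs_valid,
    )


SIGMA_C_MIN = 1e-6


def solve_crm_cavity(
    mu: float,
    sigma_c: float,
    gamma: float = 1.0,
    K_mean: float = 1.0,
    sigma_K: float = 0.1,
    m_mean: float = 0.1,
    sigma_m: float = 0.01,
    x0: np.ndarray | None = None,
) -> CavityCRMSolution:
    """Solve the MacArthur consumer-resource cavity equations.

    Unknowns are (mean_N, q_N, mean_R, q_R); the survival fractions follow
    from the truncated-Gaussian arguments, and the susceptibilities from
    the closed forms chi = phi_R - phi_N / gamma and
    nu = -(1/sigma_c^2) phi_N / (phi_R - phi_N / gamma).
    """
    if sigma_c <= SIGMA_C_MIN:
        raise ValueError("sigma_c below the solver's degenerate limit")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    g_inv = 1.0 / gamma
    s2 = sigma_c ** 2

    def unpack(x):
        mean_N, q_N, mean_R, q_R = x
        q_N, q_R = max(q_N, 0.0), max(q_R, 0.0)
        cN = np.sqrt(s2 * q_R + sigma_m ** 2)
        dN = (mu * mean_R - m_mean) / cN
        phi_N = float(np.clip(w_moment(0, dN), 0.0, 1.0))
        cR = np.sqrt(s2 * g_inv * q_N + sigma_K ** 2)
        dR = (K_mean - g_inv * mu * mean_N) / cR
        phi_R = float(np.clip(w_moment(0, dR), 0.0, 1.0))
        chi = phi_R - g_inv * phi_N
        nu = -phi_N / (s2 * chi) if chi > 0 else np.nan
        return mean_N, q_N, mean_R, q_R, cN, dN, phi_N, cR, dR, phi_R, chi, nu

    def residuals(x):
        (mean_N, q_N, mean_R, q_R, cN, dN, phi_N,
         cR, dR, phi_R, chi, nu) = unpack(x)
        if not np.isfinite(nu) or chi <= 0:
            return np.full(4, 1e3)
        bN = s2 * chi
        bR = 1.0 - g_inv * s2 * nu  # equals phi_R / chi at the solution
        if bR <= 0:
            return np.full(4, 1e3)
        return np.array([
            mean_N - (cN / bN) * w_moment(1, dN),
            q_N - (cN / bN) ** 2 * w_moment(2, dN),
            mean_R - (cR / bR) * w_moment(1, dR),
            q_R - (cR / bR) ** 2 * w_moment(2, dR),
        ])

    if x0 is None:
        R0 = min(max(m_mean / max(mu, 1e-12), 1e-3), K_mean)
        N0 = max(gamma * (K_mean - R0) / max(mu, 1e-12), 1e-3)
        x0 = np.array([N0, 1.2 * N0 ** 2, R0, 1.5 * R0 ** 2])
    best = None
    guesses = [x0,
               np.array([0.5, 0.5, 0.5, 0.5]),
               np.array([0.1, 0.05, 0.1, 0.05])]
    for guess in guesses:
        sol = root(residuals, guess, method="hybr", tol=1e-14)
        res = float(np.max(np.abs(residuals(sol.x))))
        if best is None or res < best[1]:
            best = (sol.x, res)
        if res < 1e-10:
            break
    x, res = best
    log.info("crm cavity: sigma_c=%g gamma=%g residual=%.3e", sigma_c, gamma, res)
    (mean_N, q_N, mean_R, q_R, cN, dN, phi_N,
     cR, dR, phi_R, chi, nu) = unpack(x)
    return CavityCRMSolution(
        phi_N=phi_N, mean_N=float(mean_N), q_N=float(q_N),
        phi_R=phi_R, mean_R=float(mean_R), q_R=float(q_R),
        chi=float(chi), nu=float(nu),
        residual_norm=res, converged=res < 1e-10,
    )


def continuation_scan(solver, parameter_grid, warm_key: str = "x0", **kwargs):
    """Solve along a monotone parameter grid, warm-starting each point from
    the previous converged solution.  Convergence failures are recorded in
    place, never interpolated.

    ``solver`` is called as ``solver(value, x0=..., **kwargs)``; it must
    return an object with ``converged`` and the unknown vector recoverable
    via ``_warm_start_from``.
    """
    grid = list(parameter_grid)
    if not grid:
        raise ValueError("empty parameter grid")
    solutions = []
    x0 = None
    for value in grid:
        sol = solver(value, **{warm_key: x0}, **kwargs)
        solutions.append(sol)
        if getattr(sol, "converged", False):
            x0 = _warm_start_from(sol)
    return solutions


def _warm_start_from(sol):
    if isinstance(sol, CavityGLVSolution):
        return np.array([sol.mean_N, sol.q_N])
    if isinstance(sol, CavityCRMSolution):
        return np.array([sol.mean_N, sol.q_N, sol.mean_R, sol.q_R])
    return None
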