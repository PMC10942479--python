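"""Reduction of consumer-resource models to effective Lotka-Volterra form,
and two-species invasion / niche-overlap analysis.

For the MacArthur model the reduction is *exact* as long as the surviving
resource set M* is unchanged: substituting the resource equilibrium
R(N) into the consumer dynamics yields GLV dynamics with

    r_i      = sum_{b in M*} w_b c_ib K_b  -  m_i
    alpha_ij = sum_{b in M*} (w_b K_b / r_b) c_ib d_jb .

For externally supplied resources the exact reduced dynamics are not of
GLV form; the reduction is a local linearization around a reference
equilibrium and is tagged ``exactness='local'``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .systems import CRMSystem

__all__ = [
    "EffectiveGLV",
    "resource_equilibrium",
    "effective_glv",
    "invasion_analysis",
    "niche_overlap",
]


@dataclass
class EffectiveGLV:
    r_eff: np.ndarray
    alpha: np.ndarray
    M_star: np.ndarray
    exactness: str  # 'exact' | 'local'
    reference_point: np.ndarray | None = None


def resource_equilibrium(system: CRMSystem, N: np.ndarray) -> np.ndarray:
    """Stable resource equilibrium R(N) at fixed species abundances.

    MacArthur:  R_a = max(0, K_a (1 - sum_j d_ja N_j / r_a))
    external:   R_a = kappa_a / (omega_a + sum_j c_ja N_j)
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("N must be nonnegative")
    if system.kind == "self_renewing":
        return np.maximum(0.0, system.K * (1.0 - (system.d.T @ N) / system.r_res))
    if system.kind == "external":
        return system.kappa / (system.omega + system.c.T @ N)
    raise ValueError("resource_equilibrium is not defined for essential resources; "
                     "use equilibrium_opt.em_essential")


def effective_glv(system: CRMSystem, reference: np.ndarray | None = None) -> EffectiveGLV:
    """Effective GLV parameters of a consumer-resource system.

    ``reference`` is the species abundance vector defining the surviving
    resource set M* (MacArthur) or the expansion point (external supply).
    Defaults to the empty community, where M* is all resources.
    """
    S = system.S
    ref = np.zeros(S) if reference is None else np.asarray(reference, dtype=float)
    R = resource_equilibrium(system, ref)
    if system.kind == "self_renewing":
        alive = R > 0
        if not alive.any():
            raise ValueError("empty surviving-resource set M*")
        w, K, r = system.w[alive], system.K[alive], system.r_res[alive]
        cS = system.c[:, alive]
        dS = system.d[:, alive]
        r_eff = cS @ (w * K) - system.m
        alpha = (cS * (w * K / r)[None, :]) @ dS.T
        return EffectiveGLV(r_eff=r_eff, alpha=alpha, M_star=np.flatnonzero(alive),
                            exactness="exact", reference_point=ref)
    if system.kind == "external":
        # local linearization of the exact reduced dynamics
        # dN_i/dt = N_i [sum_b w_b c_ib kappa_b / (omega_b + sum_j c_jb N_j) - m_i]
        # around the reference point: alpha_ij = -dg_i/dN_j at R* = R(ref),
        # r_i extrapolated back to N = 0 with those slopes.
        w, kap, om = system.w, system.kappa, system.omega
        alpha = (system.c * (w * R ** 2 / kap)[None, :]) @ system.c.T
        r_eff = system.c @ (w * R * (2.0 * kap - om * R) / kap) - system.m
        return EffectiveGLV(r_eff=r_eff, alpha=alpha, M_star=np.flatnonzero(R > 0),
                            exactness="local", reference_point=ref)
    raise ValueError("effective_glv supports self_renewing and external kinds")


def warn_if_survivor_sets_differ(system: CRMSystem, reference: np.ndarray,
                                 evaluated: np.ndarray) -> bool:
    """The reduction freezes M* at the reference point; adding or removing a
    species can change M*, invalidating the frozen parameters.  Emits a
    warning and returns True when the surviving-resource sets differ."""
    ref_alive = resource_equilibrium(system, reference) > 0
    ev_alive = resource_equilibrium(system, evaluated) > 0
    if not np.array_equal(ref_alive, ev_alive):
        warnings.warn(
            "surviving-resource set M* differs between the reference and the "
            "evaluated community; the frozen GLV reduction is not exact there",
            stacklevel=2,
        )
        return True
    return False


def invasion_analysis(r_eff: np.ndarray, alpha: np.ndarray) -> dict:
    """Mutual-invasion analysis of a two-species effective GLV system.

    Single-resident equilibria are N_i = r_i / alpha_ii; the invader's
    per-capita growth rate is g_j = r_j - alpha_ji r_i / alpha_ii.  The
    outcome label follows the signs of the two invasion rates:
    both positive -> mutual coexistence; both negative -> bistable priority
    effect; mixed -> competitive exclusion by the successful invader.
    """
    r_eff = np.asarray(r_eff, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if r_eff.shape != (2,) or alpha.shape != (2, 2):
        raise ValueError("invasion_analysis is a two-species analysis")
    if np.any(np.diag(alpha) <= 0):
        raise ValueError("self-interaction alpha_ii must be positive")
    resident_N = r_eff / np.diag(alpha)
    g01 = r_eff[0] - alpha[0, 1] * resident_N[1]  # species 0 invading resident 1
    g10 = r_eff[1] - alpha[1, 0] * resident_N[0]  # species 1 invading resident 0
    # invasion products r_j alpha_ii / (r_i alpha_ji), Eq-25 style
    with np.errstate(divide="ignore", invalid="ignore"):
        prod01 = (r_eff[0] * alpha[1, 1]) / (r_eff[1] * alpha[0, 1])
        prod10 = (r_eff[1] * alpha[0, 0]) / (r_eff[0] * alpha[1, 0])
    tol = 1e-12 * max(1.0, float(np.max(np.abs(r_eff))))
    if abs(g01) <= tol and abs(g10) <= tol:
        label = "marginal"
    elif g01 > tol and g10 > tol:
        label = "mutual-coexistence"
    elif g01 <= tol and g10 <= tol:
        label = "bistable-priority-effect"
    elif g01 > tol:
        label = "0-excludes-1"
    else:
        label = "1-excludes-0"
    return {
        "resident_equilibria": resident_N,
        "invasion_growth_rates": np.array([g01, g10]),
        "invasion_products": np.array([prod01, prod10]),
        "label": label,
    }


def niche_overlap(alpha: np.ndarray, r_eff: np.ndarray | None = None) -> dict:
    """Symmetrized niche overlap rho = sqrt(a12 a21 / (a11 a22)) and the
    coexistence band (rho, 1/rho) for the fitness ratio r1/r2."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (2, 2) or np.any(np.diag(alpha) <= 0):
        raise ValueError("niche_overlap needs a 2x2 alpha with positive diagonal")
    prod = alpha[0, 1] * alpha[1, 0]
    if prod < 0:
        return {"rho": complex(0, np.sqrt(-prod / (alpha[0, 0] * alpha[1, 1]))),
                "complex_overlap": True, "band": None, "fitness_ratio": None,
                "coexists": None}
    rho = float(np.sqrt(prod / (alpha[0, 0] * alpha[1, 1])))
    band = (rho, np.inf if rho == 0 else 1.0 / rho)
    out = {"rho": rho, "complex_overlap": False, "band": band,
           "fitness_ratio": None, "coexists": None}
    if r_eff is not None:
        r_eff = np.asarray(r_eff, dtype=float)
        ratio = r_eff[0] / r_eff[1]
        out["fitness_ratio"] = float(ratio)
        out["coexists"] = bool(band[0] < ratio < band[1])
    return out
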