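"""Reproducible ensemble experiments: cavity-versus-simulation scans,
replica-symmetry breakdown location, and optimization-versus-dynamics
cross-validation.

Each function builds its random instances from an integer seed, runs the
package end to end, and returns plain dictionaries/DataFrame-ready rows.
"""
from __future__ import annotations

import numpy as np

from .cavity import solve_crm_cavity, solve_glv_cavity
from .dynamics import IntegrationOptions, integrate_to_steady_state, run_ensemble
from .ensembles import (CRMEnsembleSpec, GLVEnsembleSpec, effective_moments,
                        sample_glv_system)
from .equilibrium_opt import solve_equilibrium
from .stability_rmt import surviving_submatrix_mineig
from .systems import CRMSystem

__all__ = [
    "glv_cavity_vs_simulation",
    "crm_cavity_vs_simulation",
    "rs_breakdown",
    "optimization_vs_dynamics",
]

GLV_DEFAULTS = dict(mu=2.0, r_mean=1.0, sigma_r=0.1)
CRM_DEFAULTS = dict(mu=1.0, K_mean=1.0, sigma_K=0.1, m_mean=0.1, sigma_m=0.01)


def glv_cavity_vs_simulation(
    rho: float,
    sigmas,
    S: int = 100,
    n_realizations: int = 100,
    seed: int = 0,
    **params,
) -> list[dict]:
    """Cavity solution versus simulated ensemble averages of the GLV model,
    one row per heterogeneity value; deviations are reported in units of
    the ensemble standard error."""
    p = {**GLV_DEFAULTS, **params}
    rows = []
    for k, sigma in enumerate(sigmas):
        cav = solve_glv_cavity(p["mu"], sigma, rho, p["r_mean"], p["sigma_r"])
        spec = GLVEnsembleSpec(S=S, mu=p["mu"], sigma=sigma, rho=rho,
                               r_mean=p["r_mean"], sigma_r=p["sigma_r"],
                               seed=seed + 10_000 * k)
        summ = run_ensemble(spec, n_realizations)
        row = {"sigma": sigma, "rho": rho, "S": S,
               "n_realizations": n_realizations,
               "n_failed": summ.n_failed, "cavity_converged": cav.converged,
               "rs_valid": cav.rs_valid}
        for key in ("phi_N", "mean_N", "q_N"):
            row[f"sim_{key}"] = summ.mean[key]
            row[f"sim_{key}_sd"] = summ.sd[key]
            row[f"sim_{key}_se"] = summ.se[key]
            row[f"cavity_{key}"] = getattr(cav, key)
            se = summ.se[key]
            row[f"dev_{key}_se"] = (
                abs(summ.mean[key] - getattr(cav, key)) / se if se > 0 else np.inf
            )
        rows.append(row)
    return rows


def crm_cavity_vs_simulation(
    sigma_cs=None,
    S: int = 100,
    M: int = 100,
    n_realizations: int = 50,
    seed: int = 0,
    family: str = "gaussian",
    family_params_grid=None,
    **params,
) -> list[dict]:
    """MacArthur cavity solution versus simulated ensembles.

    For the gaussian family iterate over ``sigma_cs``; for uniform /
    bernoulli iterate over ``family_params_grid`` and compare against the
    *Gaussian* cavity theory at the moment-matched (mu_eff, sigma_c_eff).
    """
    p = {**CRM_DEFAULTS, **params}
    rows = []
    if family == "gaussian":
        grid = [({"mu": p["mu"], "sigma_c": s}, p["mu"], s) for s in sigma_cs]
    else:
        grid = []
        for fp in family_params_grid:
            mu_eff, sc_eff = effective_moments(family, fp, M)
            grid.append((fp, mu_eff, sc_eff))
    for k, (fp, mu_eff, sc_eff) in enumerate(grid):
        cav = solve_crm_cavity(mu_eff, sc_eff, gamma=M / S,
                               K_mean=p["K_mean"], sigma_K=p["sigma_K"],
                               m_mean=p["m_mean"], sigma_m=p["sigma_m"])
        spec = CRMEnsembleSpec(
            S=S, M=M, mu=mu_eff, sigma_c=sc_eff,
            K_mean=p["K_mean"], sigma_K=p["sigma_K"],
            m_mean=p["m_mean"], sigma_m=p["sigma_m"],
            family=family, family_params=dict(fp) if family != "gaussian" else {},
            seed=seed + 10_000 * k,
        )
        summ = run_ensemble(spec, n_realizations)
        row = {"family": family, "mu_eff": mu_eff, "sigma_c_eff": sc_eff,
               "S": S, "M": M, "n_realizations": n_realizations,
               "n_failed": summ.n_failed, "cavity_converged": cav.converged}
        for key in ("phi_N", "mean_N", "q_N", "phi_R", "mean_R", "q_R"):
            row[f"sim_{key}"] = summ.mean[key]
            row[f"sim_{key}_se"] = summ.se[key]
            row[f"cavity_{key}"] = getattr(cav, key)
            se = summ.se[key]
            row[f"dev_{key}_se"] = (
                abs(summ.mean[key] - getattr(cav, key)) / se if se > 0 else np.inf
            )
        rows.append(row)
    return rows


def rs_breakdown(
    S: int = 200,
    n_realizations: int = 100,
    sigma_grid=None,
    seed: int = 0,
    marginality_tol: float = 1e-3,
    **params,
) -> dict:
    """Locate the replica-symmetry breakdown of the symmetric (rho = 1) GLV
    ensemble on a heterogeneity grid by two independent signatures:

    * ``sigma_phi``: smallest sigma where the simulated survival fraction
      deviates from the cavity phi_N by more than 3 ensemble standard
      errors;
    * ``sigma_eig``: smallest sigma where the ensemble-median minimum
      eigenvalue of the surviving-species interaction matrix A* falls
      below ``marginality_tol`` (pinning at zero = marginal stability).
    """
    if sigma_grid is None:
        sigma_grid = np.round(np.arange(0.1, 0.8001, 0.05), 10)
    p = {**GLV_DEFAULTS, **params}
    rows = []
    for k, sigma in enumerate(sigma_grid):
        cav = solve_glv_cavity(p["mu"], sigma, rho=1.0,
                               r_mean=p["r_mean"], sigma_r=p["sigma_r"])
        phis, mineigs = [], []
        for j in range(n_realizations):
            spec = GLVEnsembleSpec(S=S, mu=p["mu"], sigma=float(sigma), rho=1.0,
                                   r_mean=p["r_mean"], sigma_r=p["sigma_r"],
                                   seed=seed + 10_000 * k + j)
            system = sample_glv_system(spec)
            state = integrate_to_steady_state(system)
            if not (state.converged and state.uninvadable):
                continue
            phis.append(state.phi_N)
            rep = surviving_submatrix_mineig(system, state, marginality_tol)
            mineigs.append(rep.min_eig_Astar)
        phis = np.asarray(phis)
        se = phis.std(ddof=1) / np.sqrt(phis.size) if phis.size > 1 else np.inf
        rows.append({
            "sigma": float(sigma),
            "sim_phi_N": float(phis.mean()) if phis.size else np.nan,
            "phi_se": float(se),
            "cavity_phi_N": cav.phi_N,
            # no convergent RS root = the RS description has already broken
            "phi_dev_se": (
                float(abs(phis.mean() - cav.phi_N) / se)
                if phis.size and cav.converged and cav.rs_valid
                else np.inf
            ),
            "median_min_eig": float(np.median(mineigs)) if mineigs else np.nan,
            "n_ok": int(phis.size),
        })
    sigma_phi = next((r["sigma"] for r in rows if r["phi_dev_se"] > 3.0), np.nan)
    sigma_eig = next((r["sigma"] for r in rows
                      if r["median_min_eig"] < marginality_tol), np.nan)
    return {"rows": rows, "sigma_phi": sigma_phi, "sigma_eig": sigma_eig}


def _random_mcrm(rng: np.random.Generator, S: int, M: int) -> CRMSystem:
    """A well-posed random MacArthur instance with strictly positive
    consumer preferences."""
    c = rng.uniform(0.0, 2.0 / M, size=(S, M))
    K = rng.uniform(0.5, 1.5, size=M)
    m = rng.uniform(0.05, 0.15, size=S)
    return CRMSystem(c=c, m=m, kind="self_renewing", K=K, r_res=K.copy())


def _random_external(rng: np.random.Generator, S: int, M: int) -> CRMSystem:
    c = rng.uniform(0.0, 2.0 / M, size=(S, M))
    kappa = rng.uniform(0.5, 1.5, size=M)
    m = rng.uniform(0.05, 0.15, size=S)
    return CRMSystem(c=c, m=m, kind="external", kappa=kappa, omega=np.ones(M))


def optimization_vs_dynamics(
    n_instances: int = 100,
    S: int = 20,
    M: int = 20,
    seed: int = 0,
    kinds=("self_renewing", "external"),
) -> list[dict]:
    """Cross-validate the constrained-optimization equilibria against ODE
    integration on random instances; one row per instance with relative
    deviations in N and R and the worst KKT residual."""
    rows = []
    ode_opts = IntegrationOptions(method="ode")
    for kind in kinds:
        rng = np.random.default_rng(seed + (0 if kind == "self_renewing" else 1))
        for j in range(n_instances):
            system = (_random_mcrm if kind == "self_renewing" else _random_external)(rng, S, M)
            opt = solve_equilibrium(system)
            ode = integrate_to_steady_state(system, options=ode_opts)
            scale_N = max(np.max(opt.N_opt), np.max(ode.N), 1e-12)
            scale_R = max(np.max(opt.R_opt), np.max(ode.R), 1e-12)
            rows.append({
                "kind": kind,
                "instance": j,
                "rel_dev_N": float(np.max(np.abs(opt.N_opt - ode.N)) / scale_N),
                "rel_dev_R": float(np.max(np.abs(opt.R_opt - ode.R)) / scale_R),
                "kkt_max": float(max(opt.kkt.values())),
                "opt_converged": opt.converged,
                "ode_converged": bool(ode.converged and ode.uninvadable),
                "S_star": int(np.sum(opt.N_opt > 0)),
                "M_star": int(np.sum(opt.R_opt > 0)),
            })
    return rows
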