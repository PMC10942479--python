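"""Fixed-point solvers used as fast paths by the dynamics module.

* :func:`nnqp` -- minimize 1/2 x'Hx - f'x over x >= 0 (active-set with a
  projected-gradient fallback for indefinite H).  For symmetric GLV systems
  and for the MacArthur model this quadratic is (minus) the Lyapunov
  function of the dynamics, so its constrained minimizers are exactly the
  uninvadable fixed points.
* :func:`glv_support_iteration` -- direct solution of the complementarity
  form of the GLV fixed-point equations for general (non-symmetric)
  interaction matrices.
* :func:`mcrm_fixed_point` -- uninvadable equilibrium of the MacArthur model
  by nonnegative quadratic programming with iterative resolution of the set
  of surviving resources.
"""
from __future__ import annotations

import numpy as np

__all__ = ["nnqp", "glv_support_iteration", "mcrm_fixed_point"]


def _polish_support(H, f, support, x):
    """Solve the equality-constrained KKT system on the current support.
    Near-singular subsystems (rank-deficient PSD Hessians) fall back to the
    minimum-norm least-squares solution."""
    x = np.zeros_like(f)
    idx = np.flatnonzero(support)
    if idx.size:
        sub = H[np.ix_(idx, idx)]
        fs = f[idx]
        cap = 1e5 * (1.0 + float(np.max(np.abs(f)))) / max(
            1e-12, float(np.min(np.abs(np.diag(sub)))) if idx.size else 1.0)
        try:
            z = np.linalg.solve(sub, fs)
        except np.linalg.LinAlgError:
            z = None
        if z is None or not np.all(np.isfinite(z)) or np.max(np.abs(z)) > cap:
            z = np.linalg.lstsq(sub, fs, rcond=1e-10)[0]
        x[idx] = z
    return x


def nnqp(
    H: np.ndarray,
    f: np.ndarray,
    x0: np.ndarray | None = None,
    tol: float = 1e-12,
    max_rounds: int = 500,
    unbounded_cap: float = 1e8,
):
    """Minimize ``1/2 x'Hx - f'x`` subject to ``x >= 0`` (H symmetric).

    Active-set iteration: solve on the current support, drop negative
    coordinates, then admit the most profitable excluded coordinate
    (most negative KKT gradient).  For positive-definite H this is Murty's
    method and terminates at the global minimum; for indefinite H it
    terminates at a stationary uninvadable point or reports unboundedness.

    Returns (x, info) where info has keys 'converged', 'unbounded', 'residual'.
    """
    n = f.size
    scale = max(1.0, float(np.max(np.abs(f))))
    x = np.zeros(n)
    support = np.zeros(n, bool)
    outer = 0
    while outer < max_rounds:
        grad = H @ x - f
        viol = (~support) & (grad < -tol * scale)
        if not viol.any():
            res = _kkt_residual(x, grad, scale)
            return x, {"converged": res < 1e-8 * scale, "unbounded": False, "residual": res}
        support[np.flatnonzero(viol)[np.argmin(grad[viol])]] = True
        # inner feasibility loop (Lawson-Hanson): step towards the support
        # solution, removing coordinates that hit zero on the way
        for _ in range(n + 1):
            outer += 1
            z = _polish_support(H, f, support, x)
            if np.max(np.abs(z)) > unbounded_cap * scale:
                return z, {"converged": False, "unbounded": True, "residual": np.inf}
            idx = np.flatnonzero(support)
            if np.all(z[idx] > tol * scale):
                x = np.maximum(z, 0.0)
                break
            bad = idx[z[idx] <= tol * scale]
            denom = x[bad] - z[bad]
            with np.errstate(divide="ignore", invalid="ignore"):
                steps = np.where(denom > 0, x[bad] / denom, 0.0)
            alpha = float(np.min(steps)) if steps.size else 0.0
            x = x + alpha * (z - x)
            x[~support] = 0.0
            drop = bad[steps <= alpha + 1e-300]
            if drop.size == 0:
                drop = bad[: 1]
            support[drop] = False
            x[drop] = 0.0
            if not support.any():
                x = np.zeros(n)
                break
    return _nnqp_projected_gradient(H, f, x, tol, unbounded_cap * scale)


def _kkt_residual(x, grad, scale):
    # stationarity on the support, dual feasibility off it, complementarity
    r1 = np.max(np.abs(grad[x > 0])) if (x > 0).any() else 0.0
    r2 = -min(0.0, float(np.min(grad))) if grad.size else 0.0
    return max(r1, r2)


def _nnqp_projected_gradient(H, f, x, tol, cap, max_iter=200_000):
    """Projected gradient descent; emulates the relaxational dynamics for
    indefinite H.  Polishes with a support solve once the support settles."""
    evals = np.linalg.eigvalsh(H)
    L = float(np.max(np.abs(evals)))
    step = 1.0 / max(L, 1e-12)
    scale = max(1.0, float(np.max(np.abs(f))))
    x = np.maximum(x, 0.0)
    last_support = x > 0
    settled = 0
    for _ in range(max_iter):
        grad = H @ x - f
        x_new = np.maximum(0.0, x - step * grad)
        if np.max(np.abs(x_new)) > cap:
            return x_new, {"converged": False, "unbounded": True, "residual": np.inf}
        moved = np.max(np.abs(x_new - x))
        x = x_new
        support = x > 0
        if support.tobytes() == last_support.tobytes():
            settled += 1
        else:
            settled = 0
            last_support = support
        if settled > 50:
            cand = _polish_support(H, f, support, x)
            if np.all(cand >= -tol * scale):
                cand = np.maximum(cand, 0.0)
                grad = H @ cand - f
                res = _kkt_residual(cand, grad, scale)
                if res < 1e-8 * scale:
                    return cand, {"converged": True, "unbounded": False, "residual": res}
            settled = 0
        if moved < 1e-14 * scale:
            break
    grad = H @ x - f
    res = _kkt_residual(x, grad, scale)
    return x, {"converged": res < 1e-6 * scale, "unbounded": False, "residual": res}


def glv_support_iteration(
    A: np.ndarray,
    r: np.ndarray,
    tol: float = 1e-12,
    max_rounds: int = 2000,
    unbounded_cap: float = 1e8,
):
    """Uninvadable fixed point of ``0 = N_i (r_i - (A N)_i)``, ``N >= 0``,
    with every excluded species having nonpositive invasion growth rate.

    This is a linear complementarity problem; the support iteration solves
    the linear system on a candidate survivor set, removes infeasible
    species and admits the most profitable invader until uninvadable.
    """
    S = r.size
    scale = max(1.0, float(np.max(np.abs(r))))
    support = r > 0
    N = np.zeros(S)
    seen: set[bytes] = set()
    for _ in range(max_rounds):
        N = np.zeros(S)
        idx = np.flatnonzero(support)
        if idx.size:
            try:
                N[idx] = np.linalg.solve(A[np.ix_(idx, idx)], r[idx])
            except np.linalg.LinAlgError:
                N[idx] = np.linalg.lstsq(A[np.ix_(idx, idx)], r[idx], rcond=None)[0]
        if np.max(np.abs(N), initial=0.0) > unbounded_cap * scale:
            return N, {"converged": False, "unbounded": True, "residual": np.inf}
        neg = support & (N < -tol * scale)
        if neg.any():
            j = np.flatnonzero(neg)[np.argmin(N[neg])]
            support[j] = False
            continue
        N = np.maximum(N, 0.0)
        growth = r - A @ N
        viol = (~support) & (growth > tol * scale)
        if not viol.any():
            res = float(np.max(np.abs(growth[support]), initial=0.0))
            return N, {"converged": True, "unbounded": False, "residual": res}
        key = support.tobytes()
        if key in seen:
            return N, {"converged": False, "unbounded": False, "residual": np.inf}
        seen.add(key)
        j = np.flatnonzero(viol)[np.argmax(growth[viol])]
        support[j] = True
    return N, {"converged": False, "unbounded": False, "residual": np.inf}


def mcrm_fixed_point(system, tol: float = 1e-12, max_outer: int = 200):
    """Uninvadable equilibrium (N, R) of the MacArthur model by minimizing
    MacArthur's quadratic Q(N) over N >= 0, iteratively restricting the sum
    to the surviving-resource set M* (equivalent to the R >= 0 constraint).

    Valid for ``kind='self_renewing'``.  Returns (N, R, info).
    """
    if system.kind != "self_renewing":
        raise ValueError("mcrm_fixed_point requires a self-renewing (MacArthur) system")
    if not np.allclose(system.d, system.c):
        raise ValueError("the quadratic fast path requires reciprocal interactions (d = c)")
    c, d, w, K, r_res, m = system.c, system.d, system.w, system.K, system.r_res, system.m
    M = system.M
    alive = np.ones(M, bool)
    info = {"converged": False, "unbounded": False, "residual": np.inf}
    N = None
    seen: set[bytes] = set()
    for _ in range(max_outer):
        u = w[alive] * K[alive] / r_res[alive]
        Ca = c[:, alive]
        Da = d[:, alive]
        H = (Ca * u[None, :]) @ Da.T
        H = 0.5 * (H + H.T)  # exact for d = c; removes roundoff asymmetry
        f = Ca @ (w[alive] * K[alive]) - m
        N, info = nnqp(H, f, x0=N, tol=tol)
        if info["unbounded"]:
            break
        R = np.maximum(0.0, K * (1.0 - (d.T @ N) / r_res))
        new_alive = R > 0
        if new_alive.tobytes() == alive.tobytes():
            return N, R, info
        key = new_alive.tobytes()
        if key in seen:
            # the surviving-resource set oscillates; fall back to descent
            # on the exact clamped objective, which is convex
            return _mcrm_clamped_descent(system, N, tol)
        seen.add(key)
        alive = new_alive
        if not alive.any():
            return np.zeros(system.S), np.zeros(M), {
                "converged": True, "unbounded": False, "residual": 0.0}
    return _mcrm_clamped_descent(system, N, tol)


def _mcrm_clamped_descent(system, N0, tol, max_iter=200_000):
    """Accelerated projected-gradient minimization of the exact
    population-space objective with resource clamping,

        Q(N) = sum_i m_i N_i
             + 1/2 sum_a (w_a K_a / r_a) max(0, r_a - (d'N)_a)^2,

    whose gradient is minus the per-capita growth rate; convex because
    each term is a clamped squared affine function.  Finishes with an
    exact solve on the identified supports."""
    c, d, w, K, r_res, m = system.c, system.d, system.w, system.K, system.r_res, system.m
    u = w * K / r_res
    L = float(np.linalg.eigvalsh((c * u[None, :]) @ d.T).max())
    step = 1.0 / max(L, 1e-12)

    def grad(N):
        R = np.maximum(0.0, K * (1.0 - (d.T @ N) / r_res))
        return m - c @ (w * R)

    x = np.maximum(N0, 0.0) if N0 is not None else np.zeros(system.S)
    y, t = x.copy(), 1.0
    for _ in range(max_iter):
        x_new = np.maximum(0.0, y - step * grad(y))
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = x_new + (t - 1.0) / t_new * (x_new - x)
        moved = np.max(np.abs(x_new - x))
        x, t = x_new, t_new
        if moved < 1e-13 * max(1.0, float(np.max(x))):
            break
    # exact polish on the identified supports
    R = np.maximum(0.0, K * (1.0 - (d.T @ x) / r_res))
    alive = R > 1e-12 * max(1.0, float(np.max(K)))
    surv = x > 1e-10 * max(1.0, float(np.max(x, initial=0.0)))
    idx = np.flatnonzero(surv)
    N = np.zeros(system.S)
    if idx.size:
        Ca = c[np.ix_(idx, np.flatnonzero(alive))]
        Da = d[np.ix_(idx, np.flatnonzero(alive))]
        Ha = (Ca * u[alive][None, :]) @ Da.T
        fa = Ca @ (w[alive] * K[alive]) - m[idx]
        try:
            N[idx] = np.linalg.solve(Ha, fa)
        except np.linalg.LinAlgError:
            N[idx] = np.linalg.lstsq(Ha, fa, rcond=1e-10)[0]
    if np.any(N < 0):
        N = x  # keep the descent iterate if the polish is infeasible
    R = np.maximum(0.0, K * (1.0 - (d.T @ N) / r_res))
    growth = c @ (w * R) - m
    res = max(
        float(np.max(np.abs(growth[N > 0]), initial=0.0)),
        float(np.max(growth[N <= 0], initial=0.0)),
    )
    scale = max(1.0, float(np.max(np.abs(m))), float(np.max(np.abs(K))))
    return N, R, {"converged": res < 1e-7 * scale, "unbounded": False,
                  "residual": res}
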