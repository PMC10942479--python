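"""Concrete model instances and steady-state containers.

Two model families are represented:

* :class:`GLVSystem` -- generalized Lotka-Volterra dynamics
  ``dN_i/dt = g_i N_i (r_i - (A N)_i)`` with unit self-interaction folded
  into the diagonal of ``A``.
* :class:`CRMSystem` -- consumer-resource dynamics in one of three
  resource-supply variants (``self_renewing``, ``external``, ``essential``).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = ["GLVSystem", "CRMSystem", "SteadyState", "EnsembleSummary"]


@dataclass
class GLVSystem:
    """An S-species Lotka-Volterra community.

    Parameters
    ----------
    r : carrying capacities r_i.
    A : S x S interaction matrix with A_ii = 1 (the self-interaction term).
    g : per-species timescale factors (must be positive); they do not affect
        fixed points, only the approach to them.
    """

    r: np.ndarray
    A: np.ndarray
    g: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        S = self.r.size
        if self.A.shape != (S, S):
            raise ValueError(f"A must be {S}x{S}, got {self.A.shape}")
        if not np.allclose(np.diag(self.A), 1.0):
            raise ValueError("GLVSystem requires unit diagonal A_ii = 1")
        if self.g is None:
            self.g = np.ones(S)
        else:
            self.g = np.asarray(self.g, dtype=float)
            if np.any(self.g <= 0):
                raise ValueError("timescale factors g_i must be positive")
        if not (np.all(np.isfinite(self.r)) and np.all(np.isfinite(self.A))):
            raise ValueError("non-finite GLV parameters")

    @property
    def S(self) -> int:
        return self.r.size

    def rhs(self, N: np.ndarray) -> np.ndarray:
        return self.g * N * (self.r - self.A @ N)

    def growth_rates(self, N: np.ndarray) -> np.ndarray:
        """Per-capita growth rates g_i(N) = r_i - (A N)_i (timescale factors
        do not change signs and are omitted)."""
        return self.r - self.A @ N


ResourceKind = Literal["self_renewing", "external", "essential"]


@dataclass
class CRMSystem:
    """An S-species / M-resource consumer-resource community.

    ``kind`` selects the resource dynamics:

    * ``self_renewing`` (MacArthur): logistic resources with carrying
      capacities ``K`` and renewal rates ``r_res``; depletion rates ``d``
      default to the consumption preferences ``c``.
    * ``external`` (chemostat): supply fluxes ``kappa`` and dilution rates
      ``omega``.
    * ``essential``: chemostat supply with non-substitutable resources,
      biomass stoichiometry ``v`` and CES aggregation exponent ``n`` (with
      ``liebig=True`` selecting the n -> -inf law of the minimum).
    """

    c: np.ndarray
    m: np.ndarray
    kind: ResourceKind = "self_renewing"
    w: np.ndarray | None = None
    e: np.ndarray | None = None
    K: np.ndarray | None = None
    r_res: np.ndarray | None = None
    kappa: np.ndarray | None = None
    omega: np.ndarray | None = None
    d: np.ndarray | None = None
    v: np.ndarray | None = None
    n: float | None = None
    liebig: bool = False

    def __post_init__(self) -> None:
        self.c = np.atleast_2d(np.asarray(self.c, dtype=float))
        self.m = np.asarray(self.m, dtype=float)
        S, M = self.c.shape
        if self.m.size != S:
            raise ValueError("m must have one entry per species")

        def _vec(x, default, name, size):
            if x is None:
                if default is None:
                    raise ValueError(f"{name} is required for kind={self.kind}")
                x = np.full(size, float(default))
            x = np.broadcast_to(np.asarray(x, dtype=float), (size,)).copy()
            if not np.all(np.isfinite(x)):
                raise ValueError(f"non-finite {name}")
            return x

        self.w = _vec(self.w, 1.0, "w", M)
        self.e = _vec(self.e, 1.0, "e", S)
        if self.kind == "self_renewing":
            self.K = _vec(self.K, None, "K", M)
            self.r_res = _vec(self.r_res, None, "r_res", M)
            self.d = self.c.copy() if self.d is None else np.asarray(self.d, float)
            if self.d.shape != (S, M):
                raise ValueError("d must be S x M")
        else:
            self.kappa = _vec(self.kappa, None, "kappa", M)
            self.omega = _vec(self.omega, 1.0, "omega", M)
            if np.any(self.omega <= 0):
                raise ValueError("dilution rates omega must be positive")
        if self.kind == "essential":
            if self.v is None:
                raise ValueError("stoichiometry v is required for essential resources")
            self.v = np.asarray(self.v, dtype=float)
            if self.v.shape != (S, M):
                raise ValueError("v must be S x M")
            if not self.liebig and (self.n is None or self.n >= 0):
                raise ValueError("essential resources need n < 0 or liebig=True")

    @property
    def S(self) -> int:
        return self.c.shape[0]

    @property
    def M(self) -> int:
        return self.c.shape[1]

    @property
    def supply_point(self) -> np.ndarray:
        """Resource state reached in the absence of consumers."""
        if self.kind == "self_renewing":
            return self.K.copy()
        return self.kappa / self.omega

    # --- growth / uptake -------------------------------------------------
    def uptake(self, R: np.ndarray) -> np.ndarray:
        """Per-capita total resource uptake rate of each species at R."""
        if self.kind != "essential":
            return self.c @ (self.w * R)
        cr = self.c * R[None, :]
        if self.liebig:
            return cr.min(axis=1)
        return (np.sum(cr ** self.n, axis=1)) ** (1.0 / self.n)

    def growth_rates(self, R: np.ndarray) -> np.ndarray:
        """Per-capita growth rates g_i(R)."""
        return self.e * (self.uptake(R) - self.m)

    def limiting_resource(self, R: np.ndarray) -> np.ndarray:
        """Index of the scarcest (limiting) resource per species (Liebig);
        ties broken by lowest index."""
        cr = self.c * R[None, :]
        return np.argmin(cr, axis=1)

    def rhs(self, N: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dN = N * self.growth_rates(R)
        if self.kind == "self_renewing":
            dR = (self.r_res / self.K) * R * (self.K - R) - (self.d.T @ N) * R
        elif self.kind == "external":
            dR = self.kappa - self.omega * R - (self.c.T @ N) * R
        else:
            dR = self.kappa - self.omega * R - self.v.T @ (N * self.uptake(R))
        return dN, dR

    def with_params(self, **kwargs) -> "CRMSystem":
        return replace(self, **kwargs)


@dataclass
class SteadyState:
    """Species/resource abundances at a (candidate) uninvadable fixed point."""

    N: np.ndarray
    R: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    uninvadable: bool = True
    residual: float = 0.0
    integration_time: float = 0.0
    unbounded: bool = False
    multistable_suspected: bool = False
    extinction_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        self.R = np.asarray(self.R, dtype=float)

    @property
    def survivors_N(self) -> np.ndarray:
        return self.N > 0

    @property
    def survivors_R(self) -> np.ndarray:
        return self.R > 0

    @property
    def phi_N(self) -> float:
        return float(np.mean(self.survivors_N))

    @property
    def phi_R(self) -> float:
        return float(np.mean(self.survivors_R)) if self.R.size else float("nan")


@dataclass
class EnsembleSummary:
    """Across-realization summary of steady-state observables.

    ``mean``, ``sd`` and ``se`` map observable names (phi_N, mean_N, q_N and,
    for consumer-resource models, phi_R, mean_R, q_R) to statistics over
    realizations.  Moments average over *all* S (or M) slots including zeros.
    """

    observables: dict
    mean: dict
    sd: dict
    se: dict
    n_realizations: int
    seeds: list
    n_failed: int = 0

    def __getitem__(self, key: str):
        return np.asarray(self.observables[key])
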