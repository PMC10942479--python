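"""Random community ensembles with the statistics assumed by the cavity theory.

GLV interaction matrices have off-diagonal entries with mean ``mu/S``,
variance ``sigma^2/S`` and pair correlation ``corr(A_ij, A_ji) = rho``
(reciprocity); consumer matrices have i.i.d. entries with mean ``mu/M`` and
variance ``sigma_c^2/M``, drawn from a Gaussian, uniform or Bernoulli family.
Non-Gaussian families are mapped to effective cavity parameters by moment
matching (:func:`effective_moments`).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .systems import CRMSystem, GLVSystem

__all__ = [
    "GLVEnsembleSpec",
    "CRMEnsembleSpec",
    "sample_glv_system",
    "sample_crm_system",
    "effective_moments",
]


@dataclass(frozen=True)
class GLVEnsembleSpec:
    """Ensemble statistics of a random GLV community.

    mu      mean interaction scale (entries have mean mu/S)
    sigma   interaction heterogeneity (entries have variance sigma^2/S);
            this is the sigma_c of the phase-diagram axes
    rho     reciprocity correlation in [-1, 1] (1 = symmetric)
    r_mean, sigma_r   moments of the Gaussian carrying capacities
    """

    S: int
    mu: float = 0.0
    sigma: float = 0.0
    rho: float = 1.0
    r_mean: float = 1.0
    sigma_r: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if self.sigma < 0 or self.sigma_r < 0:
            raise ValueError("sigma and sigma_r must be nonnegative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_mapping(cls, mapping: dict) -> "GLVEnsembleSpec":
        return cls(**mapping)


@dataclass(frozen=True)
class CRMEnsembleSpec:
    """Ensemble statistics of a random consumer-resource community.

    For the gaussian family (mu, sigma_c) are free parameters; for the
    uniform and bernoulli families they are *derived* from the family
    parameters by moment matching and any supplied values are ignored.
    """

    S: int
    M: int
    mu: float = 1.0
    sigma_c: float = 0.1
    K_mean: float = 1.0
    sigma_K: float = 0.0
    m_mean: float = 0.1
    sigma_m: float = 0.0
    family: str = "gaussian"
    family_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 1 or self.M < 1:
            raise ValueError("S and M must be >= 1")
        if min(self.sigma_c, self.sigma_K, self.sigma_m) < 0:
            raise ValueError("all s.d. fields must be nonnegative")
        if self.family not in ("gaussian", "uniform", "bernoulli"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family != "gaussian":
            mu_eff, sc_eff = effective_moments(self.family, self.family_params, self.M)
            object.__setattr__(self, "mu", mu_eff)
            object.__setattr__(self, "sigma_c", sc_eff)

    @property
    def gamma(self) -> float:
        """Resource-to-species ratio M/S."""
        return self.M / self.S

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_mapping(cls, mapping: dict) -> "CRMEnsembleSpec":
        return cls(**mapping)


def effective_moments(family: str, family_params: dict | None, M: int) -> tuple[float, float]:
    """Map a consumer-matrix distribution family to the (mu, sigma_c) pair
    the Gaussian cavity solver expects, i.e. so that entry mean = mu/M and
    entry variance = sigma_c^2/M.

    gaussian:  params {mu, sigma_c}        -> identity
    uniform:   entries ~ U(low, b)         -> mu = M(low+b)/2, sigma_c = (b-low) sqrt(M/12)
    bernoulli: entries = b * Bernoulli(p)  -> mu = M b p,      sigma_c = b sqrt(M p (1-p))
    """
    p = dict(family_params or {})
    if family == "gaussian":
        return float(p.get("mu", 1.0)), float(p.get("sigma_c", 0.1))
    if family == "uniform":
        b = float(p["b"])
        low = float(p.get("low", 0.0))
        if b <= low:
            raise ValueError("uniform family needs b > low")
        return M * (low + b) / 2.0, (b - low) * np.sqrt(M / 12.0)
    if family == "bernoulli":
        prob = float(p["p"])
        b = float(p.get("b", 1.0))
        if not 0.0 <= prob <= 1.0:
            raise ValueError("bernoulli probability must lie in [0, 1]")
        return M * b * prob, b * np.sqrt(M * prob * (1.0 - prob))
    raise ValueError(f"unknown family {family!r}")


def sample_glv_system(spec: GLVEnsembleSpec, seed: int | None = None) -> GLVSystem:
    """Draw a GLV instance: pairs (a_ij, a_ji), i<j, from a bivariate normal
    with correlation rho so that the reciprocity statistics are realized
    exactly; the diagonal self-interaction is fixed to 1."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    S = spec.S
    iu, ju = np.triu_indices(S, k=1)
    x = rng.standard_normal(iu.size)
    y = rng.standard_normal(iu.size)
    rho = spec.rho
    upper = x
    lower = rho * x + np.sqrt(max(0.0, 1.0 - rho * rho)) * y
    a = np.zeros((S, S))
    a[iu, ju] = upper
    a[ju, iu] = lower
    A = spec.mu / S + spec.sigma * a / np.sqrt(S)
    np.fill_diagonal(A, 1.0)
    r = spec.r_mean + spec.sigma_r * rng.standard_normal(S)
    return GLVSystem(r=r, A=A)


def sample_consumer_matrix(spec: CRMEnsembleSpec, rng: np.random.Generator) -> np.ndarray:
    S, M = spec.S, spec.M
    if spec.family == "gaussian":
        return spec.mu / M + (spec.sigma_c / np.sqrt(M)) * rng.standard_normal((S, M))
    p = dict(spec.family_params)
    if spec.family == "uniform":
        return rng.uniform(float(p.get("low", 0.0)), float(p["b"]), size=(S, M))
    b = float(p.get("b", 1.0))
    return b * (rng.random((S, M)) < float(p["p"])).astype(float)


def sample_crm_system(spec: CRMEnsembleSpec, seed: int | None = None) -> CRMSystem:
    """Draw a MacArthur consumer-resource instance with logistic resources.

    The sampled model is the rescaled MacArthur form used in the
    high-dimensional analysis: w_alpha = 1 and r_alpha = K_alpha, so the
    resource dynamics read dR/dt = R (K - R - sum_j N_j c_j).
    Gaussian consumer matrices may contain negative entries; they are not
    clipped (the cavity assumptions are about moments, not support).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    c = sample_consumer_matrix(spec, rng)
    K = spec.K_mean + spec.sigma_K * rng.standard_normal(spec.M)
    m = spec.m_mean + spec.sigma_m * rng.standard_normal(spec.S)
    return CRMSystem(c=c, m=m, kind="self_renewing", K=K, r_res=K.copy())
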