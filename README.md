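# ecocavity

Community-ecology models from niche theory to statistical mechanics: a
tested toolkit for the two workhorse model families of theoretical
ecology — the **generalized Lotka-Volterra model (GLV)** and **consumer
resource models (CRM)** — covering low-dimensional graphical niche
theory, the equivalence between ecological equilibria and constrained
optimization, and the replica-symmetric **cavity** solution of large
random ecosystems with its simulation cross-validation.

It is written for theoretical ecologists and statistical physicists who
want to (i) simulate random communities to uninvadable steady states,
(ii) solve the cavity self-consistency equations for the macroscopic
order parameters of those ensembles, and (iii) check one against the
other, reproducibly, from a seed.

## Models

**GLV** (S species; unit self-regulation, random interactions):

```
dN_i/dt = g_i N_i ( r_i − N_i − Σ_{j≠i} A_ij N_j ),
A_ij ~ mean μ/S, variance σ²/S, corr(A_ij, A_ji) = ρ,   r_i ~ N(r, σ_r²)
```

**MacArthur CRM** (S species, M self-renewing resources):

```
dN_i/dt = N_i e_i ( Σ_β w_β c_iβ R_β − m_i )
dR_α/dt = (r_α/K_α) R_α (K_α − R_α) − Σ_j d_jα N_j R_α
```

plus the externally supplied (chemostat) variant
`dR/dt = κ − ωR − Σ_j c_j N_j R` and essential resources under Liebig's
law of the minimum.

Three levels of analysis:

* **niche geometry** (M = 2): zero net growth isoclines, impact vectors,
  supply points, coexistence cones, and graphical/spectral stability;
* **optimization**: uninvadable equilibria as constrained minimizers —
  MacArthur's convex quadratic Q(N) in population space, or a weighted
  Euclidean / Kullback-Leibler dissimilarity d(R⁰, R) in environment
  space with populations as KKT multipliers; an EM-style iteration
  handles the non-reciprocal Liebig case;
* **cavity method**: for S, M → ∞ the abundance distribution is a
  truncated Gaussian; closed self-consistency equations determine the
  survival fractions φ_N (= S*/S), φ_R, the moments ⟨N⟩, ⟨N²⟩, ⟨R⟩,
  ⟨R²⟩ and the susceptibilities, solved numerically and compared with
  seeded ensembles. Random-matrix diagnostics (circular-law community
  spectra, the minimum eigenvalue of the surviving-species interaction
  matrix A*) locate the loss of the replica-symmetric phase.

## Worked example

```python
import numpy as np
from ecocavity import (GLVEnsembleSpec, run_ensemble, solve_glv_cavity)

spec = GLVEnsembleSpec(S=100, mu=2.0, sigma=0.3, rho=0.0,
                       r_mean=1.0, sigma_r=0.1, seed=5)
sim = run_ensemble(spec, n_realizations=100)
cav = solve_glv_cavity(mu=2.0, sigma=0.3, rho=0.0, r_mean=1.0, sigma_r=0.1)

print(f"simulated  phi_N = {sim.mean['phi_N']:.4f} "
      f"(SE {sim.se['phi_N']:.4f})")
print(f"cavity     phi_N = {cav.phi_N:.4f}")
print(f"simulated  <N>   = {sim.mean['mean_N']:.4f}")
print(f"cavity     <N>   = {cav.mean_N:.4f}")
```

prints

```
simulated  phi_N = 0.9867 (SE 0.0010)
cavity     phi_N = 0.9877
simulated  <N>   = 0.3358
cavity     <N>   = 0.3335
```

The ensemble of 100 random 100-species communities keeps ~99% of its
species at this heterogeneity, within one standard error of the cavity
prediction; the mean abundance sits within ~0.7% of the infinite-size
theory (the small excess is the documented O(1/S) finite-size
correction). The same pattern — simulation tracking theory across a
heterogeneity scan until replica symmetry breaks — is what the
validation experiments in `tests/test_acceptance.py` assert.

A consumer-resource equilibrium via optimization:

```python
from ecocavity import CRMSystem, solve_equilibrium

system = CRMSystem(c=[[0.5, 0.3], [0.4, 0.6]], m=[1, 1],
                   kind="self_renewing", K=[4.8, 2.85], r_res=[1, 1])
res = solve_equilibrium(system)
print(res.N_opt)   # [0.38688542 1.14833767]
print(res.R_opt)   # [1.66666667 0.55555556]
print(max(res.kkt.values()) < 1e-6)   # True
```

Both species coexist; the abundances equal the KKT multipliers of the
environmental minimization, and integrating the ODEs reproduces them to
machine precision.

## Command line

```
ecocavity simulate   --config cfg.yaml       # seeded ensemble runs -> CSV
ecocavity cavity     --config cfg.yaml       # one cavity solution
ecocavity scan       --config cfg.yaml       # continuation over a sigma grid
ecocavity classify   --config cfg.yaml       # 2-resource supply-point outcome
ecocavity reduce     --config cfg.yaml       # effective-GLV + invasion report
ecocavity phase-scan --config cfg.yaml       # RS-breakdown sweep
```

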