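# Methods

This note records the modeling conventions, numerical choices, and known
limitations behind `ecocavity`. Everything quantitative stated here is
computed by the test-suite or by `scripts/acceptance.py`.

## Model conventions

**GLV.** `dN_i/dt = g_i N_i (r_i − N_i − Σ_{j≠i} A_ij N_j)`. The unit
self-regulation is stored on the diagonal of `A`, so fixed points solve
`N = r − A N` restricted to survivors. Random ensembles draw the
off-diagonal pairs `(A_ij, A_ji)`, i < j, from a bivariate normal with
mean `μ/S`, variance `σ²/S` and correlation `ρ` (the reciprocity;
`ρ = 1` gives an exactly symmetric matrix, `ρ = −1` an exactly
antisymmetric fluctuation part). Carrying capacities are
`r_i ~ N(r, σ_r²)`, independent of `A`. Note the interaction sum runs
over `j ≠ i` while entries have mean `μ/S`, so a finite community feels
an effective mean `μ(S−1)/S`; this O(1/S) effect is visible in ensemble
means (below).

**CRM.** Three resource-supply variants share the consumer layer
`g_i = e_i (Σ_β w_β c_iβ R_β − m_i)` (substitutable resources) or, for
essential resources, the law-of-the-minimum growth
`g_i = min_β(c_iβ R_β) − m_i`:

* `self_renewing` (MacArthur): logistic resources; depletion rates `d`
  default to `c` (reciprocal case);
* `external` (chemostat): linear supply `κ − ωR`; no resource can go
  extinct since supply is positive at `R = 0`;
* `essential`: chemostat supply, biomass stoichiometry `v_iα`
  partitioning total uptake; only the Liebig branch (`liebig=True`) is
  solved by the optimization layer — the CES form with finite `n < 0`
  integrates numerically but has no variational treatment here.

The high-dimensional ensembles use the rescaled MacArthur form
(`w = 1`, `r_α = K_α`), i.e. `dR/dt = R (K − R − Σ_j N_j c_j)`, with
`c_iα` of mean `μ/M` and variance `σ_c²/M`, `K_α ~ N(K̄, σ_K²)`,
`m_i ~ N(m̄, σ_m²)`. Gaussian consumer matrices may contain negative
entries; they are deliberately not clipped, because the cavity theory
constrains moments, not support. The uniform and Bernoulli families
exist to test that only the first two moments matter
(`effective_moments` maps family parameters to the `(μ, σ_c)` the
Gaussian theory expects).

## Steady states

`integrate_to_steady_state` integrates with LSODA in growing time
chunks, clamps species below `10⁻⁸ ×` (mean carrying capacity) to exact
zero, and then **polishes** the near-converged state by Newton-solving
the fixed-point equations on the current survivor support, with
complementarity refinement (drop negative abundances, admit profitable
invaders, re-admit self-renewing resources whose net renewal rate is
positive). Convergence demands per-capita rates below 10⁻⁵ before
polishing and absolute residuals below 10⁻⁹ after; uninvadability is
enforced by reintroducing every extinct species at 10⁻⁶ and
re-integrating until no reintroduction succeeds. Two guards matter in
practice:

* a polish may only clean up, never jump basins: it is rejected if it
  moves any established coordinate by more than 2% of the system scale
  (raising a coordinate that the clamped trajectory pinned near zero is
  an artifact fix and is allowed — the multiplicative dynamics cannot
  recover an exactly-zero resource on their own);
* trajectories exceeding `10⁶ ×` the natural scale abort with an
  `unbounded` flag rather than an exception.

**Fast paths** (`method="auto"`, cross-validated against the ODE route
in the unit tests): symmetric GLV systems minimize their Lyapunov
quadratic over `N ≥ 0`; general GLV systems solve the equivalent linear
complementarity problem by support iteration; reciprocal MacArthur
systems minimize MacArthur's quadratic `Q(N)` with the surviving-
resource set resolved iteratively. The nonnegative-QP solver is a
Lawson–Hanson active-set method with a minimum-norm fallback for
rank-deficient supports and a projected-gradient fallback for
indefinite Hessians; if the surviving-resource set oscillates, the
solver switches to accelerated projected-gradient descent on the exact
clamped objective
`Σ m_i N_i + ½ Σ_α (w K/r)_α max(0, r_α − (dᵀN)_α)²`, which is convex.

## Optimization layer

The uninvadable equilibrium of a reciprocal CRM minimizes an
environmental dissimilarity subject to `g_i(R) ≤ 0`:
`d = ½ Σ w r K⁻¹ (R − K)²` for self-renewing resources (solved through
its population-space dual, the `Q` program) and the weighted KL
divergence `d = Σ ω w [R⁰ ln(R⁰/R) − (R⁰ − R)]`, `R⁰ = κ/ω`, for
external supply (SLSQP to locate the active set, then an exact Newton
polish on it). Acceptance is solver-independent: a result is accepted
only when all four KKT residuals — steady populations, environmental
stationarity, noninvasibility, feasibility — are below 10⁻⁶. Surviving
populations are recovered as `e_i ×` the constraint multipliers.

For Liebig essential resources the interactions are non-reciprocal and
the objective's supply point must itself be corrected for the drain of
non-limiting resources. The EM-style iteration alternates (E) assigning
each species its limiting resource and rebuilding the effective supply
point `R̃⁰_α = R⁰_α − ω⁻¹ Σ_{i: β_i ≠ α} N_i v_iα c_iβ_i R_β_i`, where
the drain uses each species' uptake of its *limiting* resource (this is
the form consistent with the stated impact term; it is the one that
reproduces the ODE steady state), and (M) minimizing `d(R̃⁰, R)` under
the frozen linear constraints — which reduce to per-coordinate caps, so
the M-step is closed-form. Ties in the limiting-resource assignment are
broken by lowest index and flagged. Oscillating assignments beyond 200
iterations return a non-convergence flag (the unstable/cyclic regime
such models admit).

## Cavity solvers

All self-consistency equations are expressed through the truncated-
Gaussian moments `w_j(Δ)` evaluated in closed form from the standard
normal CDF/density (`w₀ = Φ`, `w₁ = ΔΦ + φ`, `w₂ = (1+Δ²)Φ + Δφ`).

*GLV*: unknowns `(⟨N⟩, ⟨N²⟩)`; `φ_N = w₀(Δ)` with
`Δ = (r − μ⟨N⟩)/√(σ_r² + σ²⟨N²⟩)`, and the susceptibility from
`ν = φ_N/(1 − ρσ²ν)` solved on the branch continuous with `ν = φ_N` at
`σ → 0` (the replica-symmetric branch; the quadratic's other root is
discarded). Roots are found by a hybrid Powell method from the
weak-disorder limit `⟨N⟩ = r/(1+μ)` with multi-start fallbacks;
solutions are accepted at residual < 10⁻¹⁰. The solver reports
`rs_valid = False` when `1 − 4ρσ²φ_N < 0` (no real branch) or
`1 − ρσ²ν ≤ 0`. For `μ = 2, r = 1, σ_r = 0.1, ρ = 1` the branch
disappears near `σ ≈ 0.66`; simulations (below) lose agreement at the
same place.

*MacArthur CRM*: unknowns `(⟨N⟩, ⟨N²⟩, ⟨R⟩, ⟨R²⟩)` with the survival
fractions from the two truncated-Gaussian arguments and the
susceptibilities eliminated by the closed forms
`χ = φ_R − φ_N/γ`, `ν = −φ_N/(σ_c² χ)`; `γ = M/S`. The solver requires
`σ_c > 10⁻⁶` (the equations degenerate at `σ_c = 0`) and `χ > 0`, which
encodes competitive exclusion (`φ_N ≤ γ φ_R`) at the ensemble level.

`continuation_scan` warm-starts each grid point from the previous
solution and records failures instead of interpolating.

## Validation experiments and problem sizes

The experiment layer (`ecocavity.experiments`) runs, at the sizes used
throughout the tests: GLV scans at `S = 100` with 100 realizations per
σ point (uncorrelated: σ = 0.1…0.8; reciprocal: σ ≤ 0.4, the
RS-valid region); the RS-breakdown sweep at `S = 200`, 100 realizations,
σ = 0.1…0.8 step 0.05; MacArthur scans at `M = S = 100` with 50
realizations per σ_c over 0.05…0.5, plus uniform and Bernoulli
(`p = 1/2`) moment-matched families; and optimization-versus-dynamics
cross-validation on 100 random MacArthur plus 100 random chemostat
instances at `S = M = 20` (agreement to 10⁻⁴ relative, KKT < 10⁻⁶).
These sizes keep the full suite at a few minutes on one core while
leaving sampling error well below the effects being tested.

## Finite-size effects and known limitations

* The cavity solution is the leading order of an `1/S` expansion. At
  `S = 100` the ensemble mean abundance exceeds it by
  `≈ (μ/S) r/(1+μ)²` (the `j ≠ i` sum feels mean `μ(S−1)/S`), i.e.
  +0.0023 at `μ = 2` — about 0.4–0.7 ensemble *standard deviations*,
  but many standard *errors* once hundreds of realizations are
  averaged. Survival fractions are much less biased. Tests that compare
  means to theory therefore either use φ_N, state an explicit
  leading-order tolerance, or are expected to flag exactly this
  deviation.
* In the marginal (multiple-attractor) phase the minimum eigenvalue of
  the surviving-species matrix `A*` is pinned at a finite-size floor
  `≈ 1.7 S^{-2/3}` (≈ 0.05 at S = 200) rather than exactly zero; its
  "reaching zero" can only be resolved at community sizes far beyond
  these experiments.
* Bernoulli consumer matrices with small `p` show O(1/√M) skewness
  corrections to the Gaussian theory at `M = 100`; the shipped
  universality experiment uses the zero-skewness `p = 1/2`, and sparse
  families are expected to converge only as `M` grows.
* The synthetic ensembles are fully exchangeable: no taxonomy, no
  metabolic structure, no correlated preferences. Passing tests show
  the theory/simulation machinery is correct for such ensembles, not
  that real communities satisfy the ensemble assumptions.
* Limit cycles and chaos (essential-resource models with `M, S ≥ 3`)
  are only *detected* as non-convergence, never characterized; the
  replica-symmetry-*broken* solution itself is out of scope — only the
  loss of RS validity is located.
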