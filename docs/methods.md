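# Methods

## Model and assumptions

The package implements the four-dimensional stochastic SIVS system

```
dS = [(1-g)A - (β+m)SI - (η+p)S + γI + αV] dt
dI = [(β+m)SI - (η+γ+ε)I] dt
dV = [Ag + pS - (η+α)V] dt
dm = -k m dt + θ dB
```

The only stochastic ingredient is the OU perturbation `m(t)` of the
transmission coefficient.  Unlike a white-noise perturbation
`β dt + θ dB`, the OU form has bounded variance at small time increments,
continuous sample paths, and strong correlation between neighbouring
states, which is the modelling argument for using it here.  `m` reverts
to zero, so `β + m` has long-run mean `β`; all other parameters are
constant.  The total population satisfies
`d(S+I+V) = (A − η(S+I+V) − εI) dt` — the noise cancels exactly — so
`Γ = {S,I,V > 0, S+I+V ≤ A/η}` is positively invariant, a fact also used
as a discrete-time check on the integrator.

Parameter invariants enforced at construction: all rates nonnegative,
`A, η, k > 0`, `0 < g < 1`, `θ ≥ 0`.  `ε ≥ p` (lethality above the
vaccination rate) is a warning rather than an error: it breaks a
modelling assumption, not any formula.

## Thresholds and regimes

`R0E = R0 + c` and `R0S = R0 − c` with
`c = Aθ/(√(πk)·η(η+γ+ε))`: the shift is the ergodic mean `θ/√(πk)` of
`|m|`, amplified by the population bound `A/η` and scaled by the mean
infectious period factor `1/(η+γ+ε)`.  `R0E < 1` implies extinction
(`limsup ln I(t)/t ≤ (η+γ+ε)(R0E−1) < 0` and `(S,V) → (S0,V0)`);
`R0S > 1` implies persistence
(`liminf (1/t)∫I ≥ η(η+α+p)(η+γ+ε)(R0S−1)/(β(η+ε)(η+α))`).  Since
`R0S ≤ R0E` the two conditions never overlap, but a band
`R0S ≤ 1 ≤ R0E` satisfies neither; `classify_regime` reports it
explicitly as `indeterminate` — no unified stochastic threshold is known.

## Simulation scheme

Compartments are advanced by an explicit Euler update of the drift with
the *current* `m_i` in the `(β+m)` terms.  For `m` two schemes exist:

* `paper_milstein`:
  `m_{i+1} = m_i − k m_i Δt + θ h_i √Δt + (θ²/2)(h_i²−1)Δt`, with `h_i`
  standard normal.  The `(h²−1)` term is the Milstein correction written
  for this equation; because the OU noise is additive the term has zero
  mean and order `Δt`, so it contributes no strong-order improvement —
  it is kept verbatim for replicating published runs.
* `exact_ou` (recommended for quantitative work):
  `m_{i+1} = m_i e^{−kΔt} + θ√((1−e^{−2kΔt})/(2k)) h_i`, the exact
  Gaussian transition, bias-free at any step size.

Default `Δt = 0.01`; the coarse `Δt = 1` that published figures use is
available but not the default, since rate constants here are O(0.1–1)
and Euler at `Δt = 1` visibly distorts transients.  Negative compartment
excursions (possible at coarse steps) are handled by `clamp_policy`:
`truncate` floors at zero and counts the event (default), `reject`
aborts with the step index — useful as a diagnostic, since it is unknown
whether published trajectories involved clamping.  Non-finite states
abort with the step index.  Ensembles derive per-path seeds as
`seed + path_index` and draw one normal per step per path, so runs are
bit-reproducible and a one-path ensemble equals the single-path
simulator.  `record_stride` thins storage without changing the dynamics.

## Stationary Gaussian density

For `R0S > 1` the quasi-endemic equilibrium `(S*, I*, V*, 0)` equals the
deterministic endemic equilibrium.  Linearizing in the deviations `u`
gives `du = Au dt + G dB`, `G = diag(0,0,0,θ)`, with drift coefficients
`a11 = βI*+η+p`, `a12 = βS*−γ = η+ε`, `a13 = α`, `a14 = S*I*`,
`a21 = βI*`, `a31 = p`, `a33 = η+α`, `a44 = k`.  The stationary law is
`N(0, Σ)` with `G² + AΣ + ΣAᵀ = 0`.  Stability is decided by the
Routh–Hurwitz conditions on
`φ_A(λ) = (λ+a44)(λ³+b1λ²+b2λ+b3)` (`b1,b2,b3 > 0`, `b1b2−b3 > 0`,
`a44 > 0`) and cross-checked against a numeric eigendecomposition to
guard against coefficient transcription errors.

Two routes to Σ:

* **Direct Lyapunov solve** (`solve_lyapunov`), via
  `scipy.linalg.solve_continuous_lyapunov`, symmetrized; this is the
  package's ground truth.
* **Transformation chain** (`sigma_transform_chain`): permutation `J1`,
  shear `J2`, elimination `J3` and the scalar-built `M1` reduce `A` to
  the companion matrix `B` with top row `(−c1,−c2,−c3,−c4)`; in that
  frame the standardized covariance `Σ1` is explicit in `c1..c4`, and
  `Σ = (m1θ)² T⁻¹ Σ1 T⁻ᵀ` with `T = M1J3J2J1`.

Two circulating printed forms of the chain scalar `a7` —
`(a12+a8)a31/(a12+a21−a11)` and
`(a12−a33)a31/(a12+a21−a11) − a13a31²/(a12+a21−a11)²` — are algebraically
identical (substitute `a8`); one transcription of the first form shows
`a1` where `a21` belongs in the denominator, which is corrected here
(with `a1 = −a44` the chain demonstrably fails to reproduce Σ).  Both
variants are exposed and `validate_chain` reports each one's entrywise
discrepancy against the Lyapunov solve rather than silently picking one.
Similarly, the `(4,4)` entry of `Σ1` is implemented as
`(c1c2−c3)/(2c4(c1c2c3−c3²−c1²c4))`; a commonly printed version omits
the `c4` factor, which is inconsistent with the companion-form Lyapunov
equation the entry must solve (the corrected form agrees with a direct
numeric solve to machine precision, the uncorrected one does not).

Useful identities used as checks: `Σ[4,4] = θ²/(2k)` (the OU row is
decoupled); Σ scales exactly as `θ²`; Σ is positive definite iff the
drift is Hurwitz and `θ > 0`, decided by attempted Cholesky
factorization.  Marginals of `S, I, V` are `N(equilibrium, Σ[i,i])`.

One caveat on published numbers: a published 4×4 covariance estimate for
the high-transmission set has `Σ44 = 0.9124×10⁻²` where the analytic
stationary value is `θ²/(2k) = 0.7143×10⁻²`; that matrix is evidently a
Monte-Carlo estimate under the coarse `Δt = 1` scheme, not the Lyapunov
solution.  It is therefore used only as the input of the
marginal-prefactor worked examples, never as a target for Σ.

## Synthetic data / study conditions

There is no external data; the "data" are simulated ensembles under the
two fixture parameter sets (`group1`: A=0.05, g=0.6, η=0.05, p=0.2,
β=0.5, γ=0.2, α=0.1, ε=0.1, k=0.65, θ=0.14; `group2`: A=0.5, g=0.8,
η=0.1, p=0.6, β=0.9, γ=0.3, α=0.2, ε=0.15, k=0.7, θ=0.1) from the common
initial state `(0.04, 0.8, 0.03, −0.02)`.  The generator emulates
exactly the model above — it does not emulate demographic (jump) noise,
reporting error, or parameter heterogeneity, so passing tests show
internal consistency of the theory and code, not fit to real incidence
data.

Problem sizes used by the heavier checks, chosen to keep sampling error
an order of magnitude below each tolerance: extinction experiment 50
paths, `Δt = 0.01`, `T = 300`; persistence experiment 200 paths,
`T = 500`, burn-in 100, stationary window `[250, 500]`, 50-bin
histograms (the published versions of these experiments use 10,000
paths; the bounds being checked are path-wise, so smaller ensembles test
the same claims with wider Monte-Carlo error, which the 3·SE tolerances
absorb); OU ergodicity one path of `10⁶` steps (`t = 10⁴`); empirical
covariance versus Σ one exact-scheme path at `θ = 0.02`, `Δt = 0.1`,
`t = 5×10⁴`, which matches the Lyapunov diagonals within a few percent
(25% tolerance asserted).  Noise-sensitivity ordering uses 30-path
ensembles at `k ∈ {0.3, 0.7, 1.2}` and `θ ∈ {0.05, 0.1, 0.2}` with
common seeds.

## Numerical choices and limitations

* Burn-in defaults to the first 20% of the horizon and the stationary
  window to the last 50% where not stated; histogram bins default to 50
  over the observed range.
* The extinction-rate estimator fits `ln I(t)` by least squares; if a
  clamped path reaches `I = 0` the fit truncates at the last positive
  value and warns.
* Thresholds are kept at full precision internally; the CLI rounds to 4
  decimals only in the human-readable summary.
* Quadrature checks of the OU invariant density integrate over
  `±10θ/√(2k)` with tolerance `1e−8`.
* The Gaussian density is a linearization: it ignores skewness of the
  true stationary law (visible at large `θ`) and says nothing when
  `R0S ≤ 1`.  No inference from data, time-varying parameters (beyond
  the OU-perturbed β), jump noise or higher-order schemes are in scope.
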