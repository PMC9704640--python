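# Methods

## Model

A measurement is a vector **x** of 1–3 isotope signatures (‰) with
per-signature analytical sd **σx**. The forward model predicts

μ = μ₀ + μ_aux(A, r),  μ₀ = Σⱼ fⱼ Sⱼ,

with fractions **f** on the simplex, source signatures **S**, auxiliary
parameters **A** (per-signature values with Gaussian uncertainty) and
auxiliary variables **r** with uniform priors (default [0, 1]). The built-in
process terms (Rayleigh, open-system in residual- and reacted-fraction
conventions, equilibrium exchange with per-signature multipliers,
Craig–Gordon evaporation, the nitrite production/consumption balance) are
listed in the README; each validates its own convention for *r* rather than
imposing a single one, because the natural parameterisation genuinely
differs between processes (residual fraction for Rayleigh, reacted fraction
for steady-state denitrification, flux ratio for evaporation).

User-defined equations are compiled from expression strings with a
whitelisted `ast` walk (symbols `f1..fm`, `S1..Sm`, declared parameter and
variable names; `+ - * / **`, `ln/log/exp/sqrt`). Sensitivities
∂μᵢ/∂S(j,i), needed for uncertainty propagation, are analytic for the
builtins and central finite differences (relative step 1e-6) for
expressions.

## Likelihood

Two source declarations, chosen per source:

* **point** (mean ± sd): contributes to the Gaussian width. Per signature,
  σᵢ² = σxᵢ² + Σⱼ (∂μᵢ/∂S(j,i))² σ(S j,i)², which reduces to the familiar
  fⱼ²-weighted quadrature for plain mixing.
* **range** (mean ± half-range): a band of equally probable values.
  The band half-widths propagate linearly, Δᵢ = Σⱼ |∂μᵢ/∂S(j,i)| ΔS(j,i),
  and the likelihood per signature is the Gaussian convolved with the
  uniform band: erf((x−μ+Δ)/(σ√2)) − erf((x−μ−Δ)/(σ√2)), with the upper
  argument carrying +Δ so the difference is nonnegative. An optional
  analytical margin widens the band edges (`margin_mode="spread"`, default)
  or, alternatively, enters the sd in quadrature (`margin_mode="sigma"`).

Signatures multiply; signatures with Δᵢ = 0 fall back to the Gaussian
density. Sampling uses the un-normalised band form (constants cancel in
the acceptance ratio); `range_likelihood(..., normalized=True)` exposes the
proper density (erf difference / 4Δ), which integrates to one and tends to
the Gaussian as Δ → 0.

Auxiliary-parameter uncertainty is handled by **redrawing** each parameter
from N(mean, sd) at every proposal, so chains marginalise over it; the
alternative analytic quadrature route exists in `combine_sigma` for
diagnostics. Parameters that are physically bounded (e.g. an exchanged
fraction) carry clip bounds applied to the draws.

## Sampler

Independence Metropolis–Hastings: proposals are drawn from the prior
(flat Dirichlet over **f** — concentration configurable — and uniform
**r**), independent of the current state. A proposal with likelihood L is
accepted when L ≥ αT, α ~ U(0,1), where the running threshold T is the
likelihood of the current state and is set to L on acceptance. Since
P(L ≥ αT) = min(1, L/T), this *is* the textbook independence-MH acceptance
probability written as a threshold test. On rejection the current state is
recorded again — required for the chain to target the posterior. Setting
`accepted_only=True` records only distinct accepted states; that chain is
systematically flatter than the posterior (the jump chain of an MH sampler
down-weights sticky high-likelihood states) and is kept for comparison with
implementations that drop rejections, not for inference. On the
three-source 2D example the accepted-only marginal sd is inflated by
roughly 15% while the full chain matches a dense-grid posterior to
KS ≈ 0.01.

Defaults: chain_length 10,000 recorded entries, burn-in 1,000 *accepted*
states, max_iterations 2,000,000, all-ones Dirichlet. Proposals are
evaluated in vectorised blocks (65,536) with the sequential acceptance scan
preserving the Markov dependence; chains are bit-reproducible given a seed,
and batch runs derive per-sample seeds from the base seed and sample index.
A measurement no proposal can reach (zero likelihood everywhere probed)
raises an error pointing at the z-score diagnostic instead of looping
silently.

Because independence proposals come from the prior, the sampler's effective
sample size falls with the posterior's concentration; posteriors much
narrower than ~10⁻³ of the prior volume (e.g. all uncertainties ≈ 0.01 ‰ in
two dimensions) are out of its practical regime. The closed-form solvers
cover exactly those near-deterministic cases.

## Summaries and diagnostics

Posterior tables report mean, median, sd and central-mass credible
intervals around the median enclosing 68.28% and 95.45% of the chain
(empirical quantiles, linear interpolation); central-mass keeps the
interval inside [0, 1] by construction and was preferred over HDIs for
that reason. Pairwise Pearson correlations are reported over chain entries;
zero-variance variables yield an explicit NaN (undefined), never 0, so
degenerate models stay visible.

Model adequacy uses a z-score per signature: z = |x − μ̄| / (σ_μ/√N) with μ̄,
σ_μ the mean and sd of the chain-predicted signature and N the number of
entries, set to zero whenever μ̄ lies within ±Δ of the measurement and
measured from the nearest band edge otherwise. As a standard-error test it
grows with chain length by design; the report also carries the N-free ratio
|x − μ̄|/σ_μ, clearly labelled, for scale-free context. z converts to a
two-sided rejection probability erf(z/√2) (z = 2 → 95.45%, z = 3 → 99.73%).
Two-chain convergence checks compare per-variable means with a two-sample
z-test whose standard errors come from batch means (32 batches), because
rejection duplicates autocorrelate the entries and the naive sd/√N would
flag perfectly consistent chains.

## Closed forms

For two sources on one signature: f₁ = (S₂−x)/(S₂−S₁), first-order
(delta-method) sd propagation, and exact interval bounds for range-mode
sources — the endpoint pairing of the bounds is verified against a grid
oracle in the tests rather than trusted. For m = n+1 sources the square
system [Sᵀ; 1]f = [x; 1] is solved directly; solutions outside [0,1]
(measurement outside the mixing polygon) are returned flagged infeasible
rather than raised, since the distance to the polygon is itself
informative. The Craig–Gordon inversion r = (μ−μ₀)/(A(D−μ)) round-trips
with the forward form to 1e-10.

## Synthetic scenarios

`generate_scenario` forward-computes a measurement from known (f, r) at the
auxiliary-parameter means, plus optional i.i.d. Gaussian noise; zero noise
reproduces the forward value exactly. `random_scenarios` draws pure-mixing
recovery scenarios: 3 point-mode sources uniform on [−25, 25] ‰ (a typical
span of natural-abundance end-members), source sd 1 ‰ and measurement noise
0.5 ‰ (typical characterisation and analytical uncertainties), true
fractions from a flat Dirichlet; near-collinear source layouts are
redrawn because they are unidentifiable by construction. The generator
emulates well-separated end-members with honest error bars; it does not
emulate correlated errors across signatures, non-Gaussian analytical error,
or misspecified processes, so recovery results bound performance under a
correct model only. Because the generator adds noise around the mean-source
forward value while the likelihood also carries the source sds, posterior
intervals are conservative and the measured 95% coverage across scenarios
sits near 0.97–1.0 (the test requires ≥ 0.90).

## Numerical choices and sizes

* Simplex closure is exact: single-source models bypass the Dirichlet draw
  (numpy's single-component Dirichlet can be off by one ulp).
* Acceptance requires L > 0 as well as L ≥ αT, so zero-likelihood states
  can never enter the chain.
* Quantiles use numpy's default linear interpolation between order
  statistics.
* Stochastic test sizes were chosen for the statistical resolution they
  need: posterior-moment checks use 10⁵-entry chains; the grid-oracle KS
  comparison on the 2D problem uses a 10⁶-entry chain because at ~7%
  acceptance the rejection duplicates leave roughly one effective sample
  per 30 entries, and the KS noise floor at 10⁵ entries would be of the
  same order as the 0.02 band being tested; the coverage experiment uses
  100 scenarios at 3,000 entries each. All complete in seconds.

## Known limitations

* One measurement per chain; no hierarchical pooling across samples.
* No covariance between signatures in either the measurement error or the
  source declarations.
* Independence proposals: no adaptation, no tempering; concentrated
  posteriors mix slowly (see above).
* The nitrite builtin hard-codes the 0.7:0.3 consumption split as the
  published experimental constraint; other splits require an expression
  model.
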