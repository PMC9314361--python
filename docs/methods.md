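# Methods

## Model class and assumptions

A reaction network with species `X_1..X_d` and reactions `R_1..R_K` is
modelled as a continuous-time Markov chain on the non-negative integer
lattice.  Reaction `k` fires at propensity `λ_k(x)` — mass-action
(`θ_k Π_j C(x_j, ν_jk)`), clamped-affine (`max(c_0 + cᵀx, 0)`), Hill
(`b + a/(K + x_j^H)`), or an arbitrary callable clamped at zero — and
displaces the state either by a fixed stoichiometric vector or by a draw
from a state-dependent jump kernel.  Kernels model whole-cell events; the
shipped ones are symmetric-binomial and strict-binary partitioning at cell
division (an odd count `2m+1` splits as `m` or `m+1` with probability 1/2
each, which preserves the conditional mean exactly).

Everything downstream assumes the chain is exponentially ergodic with
stationary law `π`.  This is not verified by the package; for the shipped
fixtures it holds by standard drift arguments.  The output is a single
species `X_n`; frequencies are reported in rad per the time unit implied by
the rate constants.

## The spectral object and the rational approximation

With `f(x) = x_n − E_π(X_n)` and transition semigroup `T(t)`, the resolvent
transform `G(s) = E_π(f ∫ e^{−st} T(t) f dt)` is the Laplace transform of
the stationary autocovariance, and `S(ω) = 2 Re G(iω)` is the two-sided
PSD (so that `(1/2π)∫_ℝ S dω = Var_π(X_n)`; displayed curves use `ω ≥ 0`
without doubling).  The eigenmode expansion `G(s) = Σ_j α_j/(s−σ_j)`
truncated at `p` modes motivates the ansatz `G_p = N_{p−1}(s)/D_p(s)` with
monic denominator.

Matching the first `ρ_ℓ` series coefficients of `G` at points
`s_1..s_L ∈ (0,∞]` produces one linear block per point in the unknowns
`(κ, β)`.  At `s = ∞` the series is `Σ_m D_m s^{−(m+1)}` with
`D_m = E_π(f A^m f)`; the block's rows follow from equating coefficients of
`s^{p−1−j}` in `N(s) = D_p(s)·Σ_m D_m s^{−(m+1)}`, which places a single 1
in the numerator column `p−1−j` and entries `−D_{j+i−2p}` in denominator
columns `i = max(p, 2p−j)..2p−1` (the lower clamp at `p` matters for rows
`j ≥ p+1`).  Finite-point blocks carry binomial weights `C(i,j) s^{i−j}`.
The stacked system is solved by least squares: columns are norm-scaled and
the solution taken through a pseudoinverse with relative cutoff `1e-10`, so
under- and over-determined configurations and rank deficiency are all
handled the same way (rank deficiency additionally warns).

A known monic factor `B(s)` of degree `q ≤ p` in the denominator —
inherited from an upstream subsystem whose slow eigenvalues provably carry
over to the joint chain, e.g. the cell-cycle clock pair
`σ = −α(1 − e^{2πi/N})` giving `B(s) = |σ|² − 2Re(σ)s + s²` — is imposed
by the convolution-matrix change of variables `β = C β′ + shift(B)`.  With
`q = 0` this reduces bit-for-bit to the plain system.

Fitted approximants with denominator roots in the closed right half plane
are *flagged*, not rejected: the recourse is validation (below), and in
practice a marginally unstable fit can still trace the spectrum accurately
away from the offending pole.  Negative PSD evaluations are reported raw
with an optional clip at zero.

## Estimating the interpolation data

All estimators share one ensemble of `Q` exact SSA trajectories of the
*augmented* chain on `[0, T_f]`, discarding `[0, T_c]`:

* **Finite `s`.**  A constant-rate reaction per point drives a shift
  register block; at stationarity register `m+1` holds the output at an
  independent `Erlang(m+1, s)` lag, so the time average of
  `(Y_{m+1} − X_n)²` estimates `δ_m` and
  `D_m = (−1)^m s^{−(m+1)}(Var − δ_m/2)`.
* **`s = ∞`.**  `A^m f` is evaluated pointwise by the generator recursion,
  memoized in an LRU-capped table keyed by `(m, state)` — recurrent states
  make this cheap.  The default integrand is the covariate form `Ψ_m`,
  derived from the binomially weighted stationarity identity
  `0 = Σ_j C(m−1,j) E_π[A(A^j f · A^{m−1−j} f)]`, which expresses
  `E_π(f A^m f)` through products of intermediate generator powers and the
  carré-du-champ terms
  `γ_jl(x) = Σ_k λ_k E[(ΔA^j f)(ΔA^l f)]`.  For odd `m = 2r+1` the closing
  term is `(1/2) C(m−1, r) γ_rr`.  The naive integrand `f·A^m f` is kept as
  a diagnostic.  `D_0` is always the direct variance estimator (pooled
  second moment minus squared pooled mean), which is its exact meaning.
* **Validation points.**  Snapshot registers give direct estimates
  `Ĝ(s̄_r) = (Var − δ_0^{(r)}/2)/s̄_r` at held-out `s̄_r`; a fit passes when
  every point satisfies `|G_p(s̄) − Ĝ(s̄)| ≤ max(0.1·|Ĝ|, 3 SE)` (threshold
  configurable).  Order selection is manual by design: if validation fails,
  raise `p` or add interpolation points and rerun — the antithetic-feedback
  example in the test suite shows exactly this retry (`p = 2` fails,
  `p = 3` multipoint passes).

Standard errors come from batch means: each trajectory's window is split
into 20 equal batches (configurable ≤ 32), and the SE of any pooled time
average is the batch standard deviation over `√(Q·20)`.  Nonlinear
functionals (the variance, the `D_m` built from it) are linearised around
the pooled mean for their batch values; the resulting plug-in bias is
absorbed into the reported errors.  A single long trajectory (`Q = 1`)
therefore still yields usable error bars.  Note that `Ψ_m` for `m ≥ 1` does
not depend on the centering constant at all (the generator annihilates
constants), so the plug-in mean only touches `D_0`.

The ensemble engine accumulates integrals online — output moments, register
mismatches, and a state-occupancy measure over the base species (the
occupancy is all the `s = ∞` integrands need) — in a numba-compiled SSA
core; a pure-Python twin with identical semantics handles callable
propensities and custom kernels and doubles as a cross-check in the tests.
Occupancy keys pack the base state into 64-bit integers with automatic
capacity retry; networks too large to pack should use finite interpolation
points, which need no occupancy.

## Linear networks

For affine propensities `λ(x) = Λx + b̃`: drift `A = SΛ` (must be Hurwitz,
else an ergodicity error), mean `x̄ = −A^{−1}b`, covariance from the
Lyapunov equation `AΣ + ΣAᵀ + DDᵀ = 0` with
`DDᵀ = S diag(Λx̄ + b̃) Sᵀ` solved by the dense Bartels–Stewart routine
(`scipy.linalg.solve_continuous_lyapunov`; intended for `d ≲ 50`).  The
diffusion uses the *raw* affine rates even when an individual linearised
term is negative at the mean — the clamp `max(·, 0)` is applied only in
simulation, and for repression terms written as part of a total production
rate the clamp is applied to the total (which at the shipped parameters
essentially never binds, keeping simulation and closed form within a few
percent).

`G(s) = eₙᵀ(sI − A)^{−1}Σeₙ` gives exact Padé derivatives
(`D_m = eₙᵀA^mΣeₙ` at infinity), the exact PSD
`−2 eₙᵀ(ω²I + A²)^{−1}AΣeₙ`, and its rational form in `u = ω²` with monic
denominator `det(uI + A²)` (the numerator is recovered by a `d`-point
Vandermonde solve, exact up to floating point).  For a network driven by
independent signals through zeroth-order creation reactions, the output
spectrum decomposes as intrinsic (inputs frozen at their means) plus
`θ_j² |eₙᵀ(A + iωI)^{−1}c_j|² S_{Y_j}(ω)` per input; the composite
estimator feeds a nonlinear upstream network's *fitted* rational PSD into
this formula, so scanning coupling parameters costs no extra simulation.

The three-node negative-feedback circuit admits a closed-form oscillation
criterion (strict inequality on `k_o β_fb I_0` against a threshold in the
degradation/production rates); it is checked against the numerical peak
finder on a parameter grid in the tests.  The incoherent-feedforward
spectrum is a sum of two monotone Lorentzian-type terms and can never peak
— spectral shape discriminates the two adapting topologies.

## Periodogram baseline

`dft` samples the piecewise-constant path on a uniform grid (right
continuous), subtracts the mean, and scales `|DFT|²` by `Δt/N` so the
estimate targets the continuous-time two-sided PSD; the stored object is
two-sided, one-sided display doubles power.  Default
`Δt = 0.1/(total propensity at the reference state)` as an anti-aliasing
heuristic; rectangular window, no smoothing.  The per-bin estimator is
inconsistent — its relative scatter stays `O(1/√Q)` regardless of horizon,
which the test suite demonstrates and which is why curve-level comparisons
band-average first.

## Synthetic data and what the tests show

All inputs are generated programmatically; there is no external data.  The
four linear benchmarks (gene expression, RNA splicing with a telegraph
gene, IFF, NFB) carry parameter sets whose closed-form spectra have simple
printed coefficients, asserted exactly.  The two-state gene is represented
as a single 0/1 species with affine switching propensities — exact for the
CTMC and, unlike a two-conserved-species encoding, Hurwitz.  The nonlinear
circuits (repressilator ± sponge, antithetic integral feedback ± extra
feedback, self-regulating gene, dividing-cell hosts) use representative
defaults chosen once to sit in their qualitative regimes: the repressilator
oscillates near 1.3 rad/time (fast enough that its peak lies above the
driven circuit's 0.82 rad/time resonance, the regime where entrainment
grows monotonically with coupling and feedback); the AIF gains keep the
extra feedback from saturating the integral action
(`2 k_fb k_p < γ_r γ_p`), so the set-point survives; the dividing-cell
property test uses a high-expression host so the division sawtooth
dominates the intrinsic noise floor and the spectral peak sits at the
division frequency `2πα/N`.  "Experimental" traces for the inference
example are simulated trajectories scaled by an arbitrary constant —
normalised spectra are invariant to it, which is the point of the
inference scheme.

Consequently the tests certify the estimators against exact self-consistent
targets (truncated-generator oracles, closed forms, conservation of power),
not against features of real microscopy data: measurement noise,
photobleaching, segmentation errors and non-stationarity are all outside
the model.

Problem sizes: the benchmark pipelines use `Q = 10`, `T_f = 10⁴`,
`T_c = 10²`; the nonlinear circuit checks use horizons of 600–3000 time
units, which keeps the full suite under a minute of simulation while
leaving all stochastic assertions at ≥3-SE margins.

## Known limitations

* Ergodicity is assumed, not checked; absorbing states are simulated
  correctly (the path holds) but the stationary machinery is meaningless
  there.
* The covariate integrand is dramatically lower-variance than the naive one
  for `m = 1, 2` (~40× and ~4× on the gene-expression benchmark) but can be
  *higher*-variance for `m = 3`; both are unbiased, and the reported SEs
  make the comparison visible per run.
* Generator powers require fixed displacements; jump-kernel networks must
  use finite interpolation points (with a known factor where available).
  The kernel moment interface covers affine observables only.
* No automatic order selection for `p`; validation failure is surfaced, the
  retry is manual.
* Least-squares Padé fits can produce unstable or negative-dipping spectra
  when the interpolation data are noisy or the order is wrong; they are
  flagged rather than repaired.
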