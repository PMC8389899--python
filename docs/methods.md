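# Methods

`memperm` estimates the membrane permeability coefficient of a solute from
umbrella-sampling simulations of its transmembrane coordinate z, using the
inhomogeneous solubility–diffusion model

    1/P = R = ∫ exp(β W(z)) / D(z) dz,        β = 1/(k_B T),

where W(z) is the potential of mean force (PMF) along z referenced to bulk
water and D(z) the position-dependent diffusivity.  The package covers the
whole chain — biased sampling, WHAM unbiasing, diffusivity estimation,
integration — and ships a one-dimensional Langevin generator so every stage
can be validated by parameter recovery against a known landscape.

## The synthetic umbrella-sampling generator

### What it emulates

Real campaigns of this kind restrain a drug-like solute at a ladder of
depths spanning one bilayer leaflet (typically 35 windows, 1.0 Å apart,
harmonic force constant k = 2.5 kcal/(mol Å²)) and record the solute's
z-coordinate.  The generator reproduces exactly the statistical structure
those analyses consume: per-window stationary time series whose density is
∝ exp(−β(W + ½k(z − z₀)²)), with realistic autocorrelation set by the local
diffusivity.  Landscapes are sums of Gaussians; the bundled
`membrane_mimic()` has a −7 kcal/mol well at the bilayer center, a
+1.5 kcal/mol headgroup barrier at ±18 Å, a flat water plateau at 0, and a
diffusivity rising from 0.01 Å²/ps in the core to 0.1 Å²/ps
(10⁻⁶ → 10⁻⁵ cm²/s) in water — the magnitudes and ~10× water/core contrast
reported for small lipophilic drugs in phosphatidylcholine bilayers.

### What it does not emulate

It is a 1-D overdamped model: no lipids, no orientational or conformational
degrees of freedom, no slow collective membrane modes, no steered-MD
starting-state bias, and memoryless (Markovian) dynamics along z.  Passing
the recovery tests therefore demonstrates the *analysis* is correct and
well-calibrated — not that 100 ns per window suffices for any particular
real membrane system, where hidden slow variables can correlate samples far
beyond what the 1-D model produces.

### Integrator

Euler–Maruyama with the spurious-drift correction,

    z ← z + β D(z) F(z) Δt + D′(z) Δt + sqrt(2 D(z) Δt) ξ,   ξ ~ N(0,1),

with F = −d(W + bias)/dz.  The D′(z) term is required for the stationary
density to be Boltzmann when D varies with z; a regression test verifies
that a strong D gradient leaves the stationary moments unchanged.  Defaults
Δt = 0.05 ps and n = 2×10⁶ steps resolve the slowest window relaxation time
(k_BT/(kD) ≈ 24 ps in the core at 303 K) by ~500× and give ≈ 4000
independent samples per window.  Reflecting walls at the landscape domain
edges keep the chain in-domain; default domains place the walls ≥ 6 Å
beyond the outermost window so they are effectively never touched.  Each
window starts at its bias center (mirroring extraction of pulling snapshots
at the window centers) and the first 10% of each series is discarded as
burn-in — a fixed, reproducible convention.  Randomness is numpy PCG64 with
per-window `SeedSequence.spawn` substreams of a master seed, so campaigns
are bit-reproducible.

## WHAM

Histograms use 720 uniform bins over the union of window supports (padded
by one bin).  The self-consistency equations

    p_j = M_j / Σ_i N_i e^{β f_i} e^{−β b_ij},
    e^{−β f_i} = Σ_j p_j e^{−β b_ij}

are iterated directly in linear space (bias Boltzmann factors underflow
harmlessly to zero far from each window), with f initialized to 0 and
anchored at f₁ = 0.  Convergence is max_i |Δf_i| < 10⁻⁸ kcal/mol per
iteration — the offsets, not the profile, define the stopping rule.  For
the default 35-window campaign this takes ~7×10³ iterations and under two
seconds.  With a single window the fixed point is reached immediately and
equals bias-subtracted Boltzmann inversion, which is tested to machine
precision.  Empty bins get W = NaN (no pseudo-counts, which would bias well
depths); downstream interpolation bridges interior gaps linearly.  Raw
counts are used as WHAM weights with no autocorrelation-inefficiency
correction; correlation is instead respected where it matters for the
error bars, in the block bootstrap.

### Zero reference

Permeability needs W measured from bulk water, so profiles are shifted to
make the outermost 3 Å of the water plateau average zero.  The plateau edge
is pinned at the outermost bias center: the histogram range extends ~2 Å
beyond the sampled ladder, and those sparse tail bins would otherwise
contribute 0.1–0.2 kcal/mol of noise to the absolute reference — an error
that enters P exponentially.

### Symmetrization

For single-component symmetric bilayers the two leaflets are equivalent and
W(z) is averaged with W(−z) about the midplane (mirroring one-sided
coverage where only one side exists).  The operation is idempotent;
uncertainties of mirrored pairs combine in quadrature and halve.

### Bootstrap

Per-bin standard errors come from a moving-block bootstrap: within each
window, contiguous blocks (default 50 sampling intervals ≈ 2.5 ps,
comparable to the core relaxation time) are resampled with replacement and
WHAM is re-solved per trial, warm-started from the full-data offsets; 100
trials by default.  Blocks, rather than independent draws, preserve the
autocorrelation the raw series carries.  Each trial is re-referenced to the
water plateau before the per-bin standard deviation is taken, so the
arbitrary additive constant does not inflate the errors.

## Diffusivity

Per window, the positional-autocorrelation estimator for restrained
sampling:

    D(⟨Z⟩) = ⟨δZ²⟩² / ∫₀^∞ ⟨δZ(t) δZ(0)⟩ dt,   δZ = z − ⟨Z⟩,

attributed to the window's mean position ⟨Z⟩.  The ACF is computed by FFT
with the biased (1/n) normalization.  The integral is truncated at the
first zero-crossing or where the ACF falls below 1% of the variance,
whichever comes first: waiting for a zero-crossing alone conditions on the
noisy tail staying positive and systematically inflates the integral
(deflating D by up to ~20% on unlucky seeds at n = 2×10⁶), while the 1%
floor costs a known, bounded ~1% of the integral for an exponential ACF.
For an Ornstein–Uhlenbeck window (σ² = k_BT/k, τ = k_BT/(kD)) the estimator
is exact, which anchors the unit tests; on simulated OU windows it recovers
D within a few percent.

## Permeability integration

W and D are linearly interpolated onto a common uniform grid (1.0 Å by
default; linear interpolation cannot overshoot into exp(βW)) and the
resistivity integrand exp(βW)/D is integrated by composite trapezoid.
Internal units are Å, ps, kcal/mol; conversion (1 Å²/ps = 10⁻⁴ cm²/s,
1 Å = 10⁻⁸ cm) happens only at reporting.  Both integration conventions are
always emitted: `half` integrates from the bilayer center (z = 0) to the
water edge, and `full` over the full width of the symmetrized profile
(exactly 2× the half-membrane resistance for symmetric inputs, i.e.
log₁₀P lower by log₁₀2 ≈ 0.30).  P is reported in cm/s together with
log₁₀P, the conventional scale for permeability coefficients.

The default upper bound is detected as the start of the first run of ≥ 3
consecutive 1.0 Å grid points with |W| < 0.1 kcal/mol (the bulk-water
plateau), clipped to the span covered by window diffusivity estimates; the
lower bound defaults to z = 0.  Uncertainty on log₁₀P is the standard
deviation of log₁₀P over the bootstrap PMF replicas, holding D at its point
estimate — W enters exponentially and dominates the error budget.  Because
`half` and `full` resistances differ by a z-independent factor, the same
spread applies to both.

## Numerical and degenerate-input policies

- WHAM raises on non-convergence (with the residual), on all-empty
  histograms, and warns when adjacent windows share no occupied bin.
- The diffusivity estimator raises on zero-variance series and on
  non-positive ACF integrals (advising longer sampling).
- Grid alignment refuses extrapolation beyond either input's support.
- `compute_permeability` rejects zero total resistance.
- All profile/report files carry `#` headers echoing the parameters and
  seed that produced them; each pipeline stage writes a JSON manifest with
  SHA-256 digests of its outputs, stable across reruns.

## Default problem sizes

The shipped defaults — 35 windows × 2×10⁶ steps (70M samples), 720 bins,
100 bootstrap trials — run the full pipeline in roughly two minutes on one
core and recover the mimic's log₁₀P to within ≈ 0.05 of the dense-quadrature
value on the analytic landscape (the acceptance tolerance is ±0.3,
dominated by the exponential sensitivity of R to residual PMF error:
0.3 in log₁₀P corresponds to ~0.4 kcal/mol of systematic error near the
barrier).  The test suite uses smaller campaigns for unit-level checks and
the full default campaign for end-to-end recovery.

## Known limitations

- 1-D Markovian dynamics understate the sampling burden of real membranes;
  error bars calibrated here are a lower bound on what all-atom data need.
- The positional-ACF diffusivity estimator assumes the restrained
  fluctuations are locally harmonic and memoryless; strongly anharmonic
  wells or subdiffusive kinetics bias it.
- Bootstrap resamples within windows only; it cannot see between-window
  systematic error (e.g. hysteresis from the pulling direction).
- No 2-D reaction coordinates, no MBAR pathway, no Bayesian D(z)
  estimators.
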