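# Methods

## The model

A fluorescence-fluctuation measurement records photon counts from molecules
diffusing through a diffraction-limited illuminated volume. `cpch` models the
joint distribution of the counts in two bins of length `T` separated by a lag
`τ` — the correlated photon-counting histogram — for a mixture of independent
fluorescent species plus Poisson background. The joint distribution is
sensitive to molecular brightness (through the count amplitudes, as in PCH)
and to diffusion (through how the correlation decays with `τ`, as in FCS), so
species can be resolved by both properties from one dataset.

The observation volume is a 3D Gaussian per channel,
`I(x) = ε exp(−2(x²+y²)/r² − 2z²/z₀²)`, with radial/axial waists `r`, `z₀`
(structure factor `s = z₀/r`) and molecular brightness `ε` (counts/s from a
molecule at beam centre). Emission is conditionally Poisson given position;
positions evolve by free diffusion. The building blocks are then analytic:

- shape factors `γ_{m,n}` (normalised spatial moments of the PSF product;
  `(m+n)^{-3/2}` for identical channels),
- diffusion factors `κ_{m,n}(τ, D)` (Lorentzian-type radial and axial decay,
  with `τ_d = r²/4D`),
- flow/scanning factors `S_{m,n}` (Gaussian suppression by the displacement
  `vτ`),
- binning functions `B₂`, `B_{m,n}` correcting for motion during a long
  counting bin (`B_{m,n} ≈ B₂^{m-1}B₂^{n-1}`, the product approximation).

The number of molecules in the open observation volume is Poisson, so the
N-molecule distribution is compound Poisson over the single-molecule
distribution `p₁`: `g = exp(Σ_q N_q (g₁^{(q)} − 1) + background)`. Factorial
cumulants are therefore linear in species:
`(K)_{m,n}(τ,T) = γ_{m,n} Σ_i N_i (ε_A,i T)^m (ε_B,i T)^n κ_{m,n}(τ,D_i)
B_{m,n}(T)`, with the Poisson background entering only at first order.

Three routes compute the full distribution: the alternating factorial-moment
series for `p₁`; FFT evaluation of the generating function on the unit circle
(the workhorse); and the exact recursion seeded at
`p(0,0) = exp(−Σ N_i(1−p₁ⁱ(0,0)) − λ_A − λ_B)`. The FFT and recursion routes
agree elementwise to ≤1e−9 across occupancies 0.1–25 and brightnesses 0.1–1
counts/bin, which is how transcription of the recursion's printed indices was
verified. FCS, PCH, FCA and dual-colour PCH are recovered as special cases
(`G(τ) = 1 + (K)₁₁/((K)₁₀(K)₀₁)`; the marginal over one axis; the 1D
factorial cumulants; the `τ=0` joint distribution). At `τ=0` single-channel
data are one-dimensional (each bin compared with itself) and the second 1D
moment replaces the joint moment.

## Estimation

Empirical raw moments of the bin-pair ensemble are converted to factorial
cumulants with exact-rational Stirling-number/Leibniz recursions. Sampling
variances use the first-order delta method ("moments of moments"); because
neighbouring bins are correlated over `τ_d`, the independent-points
covariance badly undercounts the variance of low-order cumulants, so the
pipelines use a batch-means variant: the cumulant's influence function is
applied to per-batch raw moments (64 contiguous blocks by default) and the
variance of the batch means is used. The classic independent-points formula
remains available (`variance_mode="iid"`), optionally with a
long-run-variance inflation of the first cumulants.

Fits minimise the per-cumulant energy `E_K` (variance-normalised mean squared
residual over all orders `1 ≤ m+n ≤ 4` and lags; ≈1 when the model is
correct) or the per-histogram-cell energy `E_p`, using a nested-sampling-type
population Monte Carlo: the worst of ~100 live parameter vectors is recorded
and replaced by a Metropolis-refined copy of another (normal proposals,
log-normal for diffusion parameters, 20 inner iterations per parameter,
step sizes adapted by `exp(±1/n_acc or n_rej)`), subject to the nested hard
constraint (never above the energy of the point just removed) with
unconditional acceptance below `E_min = 2`. Each replacement also attempts
ensemble moves along the difference of two random live vectors
(differential-evolution style): one-parameter-at-a-time proposals alone mix
far too slowly along the curved, strongly correlated parameter ridges that
desk-scale data produce. For ill-conditioned problems (the two-species
mixture, and the raster-scan `(r, D)` pair) the protocols report the
optimizer's lowest-energy vector (restarting the two-species sampler and
keeping the better run); the well-conditioned single-species point protocol
reports the chain mean, with the chain std as the uncertainty. Estimates are the means of the
recorded vectors after burn-in (at least 25%, and always discarding points
with energy above `E_min`); their standard deviations serve as uncertainties.
The unit-temperature Metropolis step and the burn-in rule are our choices
where the procedure left them open; both are recorded in the fit metadata.
For two-species fits the live set is seeded from the analytic inversion of
the 1D factorial cumulants ((K)_n = γ_n(N₁ε₁ⁿ + N₂ε₂ⁿ), solved exactly via
the 2×2 Hankel system whose quadratic roots are the brightnesses), resampled
within the moments-of-moments errors; a label-ordering constraint
(ε₁ ≤ ε₂) removes the swap symmetry.

For raster-scanned images, a pixel offset `(d_x, d_y)` maps to the lag
`τ = τ_p(d_x + L_y d_y) + τ_L d_y` and the scanning acts as a known
displacement in the flow factor. Because that displacement is physical
(pixels × pixel size), spatial cPCH constrains the beam waist `r` and the
diffusion coefficient `D` separately, not only `τ_d`. The spatial protocol
uses fast-axis offsets (1–64 pixels) plus rows of next-line and
second-line offsets (`d_y = 1, 2`, mirrored in `d_x`) whose width across
`d_x` measures `r² + 4Dτ_line` directly; same-pixel (`τ=0`) information
enters through the 1D cumulants only. At 5–10 frames the diffusion
coefficient remains the noisiest quantity (single-run scatter of order
15–25%): the slow-row signal is a few counts per thousand pixels, and the
fast-axis decomposition of `τ_d` into `r²/4D` inherits the `τ_d`–`r`
correlation.

## The simulators and what they do (not) emulate

The trace simulator places `round(N V_box/V_AB)` molecules of each species
uniformly in a periodic box (4×4×8 µm for point measurements; 4X×4Y×8 µm for
an X×Y µm image), and per time step `Δt` draws Poisson photons per molecule
per channel with mean `I(x_i)` and then advances positions by Gaussian steps
of per-axis variance `2DΔt`, wrapping at the boundaries. Emission uses the
position at the start of the step — one consistent convention where the
discrete-time scheme leaves the ordering ambiguous; at lags that are
multiples of `Δt` the resulting correlation functions are exact. The raster
simulator moves the PSF across the pixel grid with the stated dwell, line-
and frame-retrace times; retrace intervals advance diffusion in dwell-sized
steps (with periodic wrapping, lumping sub-steps would be exactly equivalent
in law). Arrival-time mode distributes each bin's photons uniformly within
the bin at 50 ns resolution, which is adequate because the analysis only
uses bin-level counts.

Three finite-simulation effects are *not* part of the ideal open-volume
theory and are handled explicitly:

1. **Frozen-bin sampling.** Positions are constant within `Δt`, so data
   binned at `T = Δt` have no intra-bin diffusion and the continuous binning
   function `B₂` does not apply at the native bin. The `binning="discrete"`
   mode computes the exact correction for counts re-binned from a
   `Δt`-sampled trace (the double average of `κ₁₁` over the sub-bin lag
   grid); it equals 1 at `T = Δt` and converges to the continuous closed
   form as `T/Δt → ∞`.
2. **Closed box (canonical ensemble).** The total molecule number is fixed,
   so the occupancy of the observation volume is binomial, not Poisson, and
   cumulants of order ≥2 are depressed by terms of relative size
   `~(V_AB/V_box)/γ₂` (≈1.8% for the two-species benchmark — several σ at
   60 s). The fit models accept the known constant `p = V_AB/V_box` and
   subtract the leading correction, `(p/2) N_i` times the convolution square
   of the single-molecule factorial moments.
3. **Periodic images.** A molecule that wraps around the box re-enters from
   the other side, adding image terms
   `Π_dim (1 + 2 exp(−c_mn (L/r)² / (1 + c_mn τ/τ_d)))` to the diffusion
   factor; these matter only for fast species at the longest lags and are
   applied with the known `(L/r)²` of the generator.

None of these corrections applies to real (open-volume, continuous-time)
data, where the defaults — continuous binning, `p = 0`, no images — recover
the ideal theory. Passing the validation protocols therefore demonstrates
the estimation machinery end to end under known ground truth, but says
nothing about detector artefacts (dead-time, afterpulsing), photophysics
(triplets, blinking, saturation) or non-Gaussian PSFs, none of which the
simulator emulates (hooks exist for the corrections but no formulas are
shipped).

## Problem sizes and numerical choices

The validation protocols are sized for a single CPU: the single-species
benchmark simulates 60 s at `T = Δt = 10 µs` (beam waist set to
r = 0.45 µm; the point-measurement analysis never uses `r`, only `τ_d` and
`s`, so `r` is purely a simulation-scale choice fixing the molecule count at
370); the two-species benchmark 60 s with r = 0.6 µm (1561 molecules); the
image benchmark 10 frames of 256×256 pixels (9733 molecules). The
single-species fit uses the multi-tau scheme (`T` doubling every 4 lags from
10 µs to 640 µs): the bin-size dependence through the binning functions is
what pins `τ_d` against the `τ_d`–`s` ridge of the lag dependence alone.

Other numerical choices: series truncation at term size < 1e−14 with a hard
cap of 200 terms (error suggests the FFT route); FFT grids padded to twice
the requested size (power of two) with tail mass checked post hoc (<1e−9)
and negative ringing clipped (failure above 1e−6); `B₂` evaluated by a
fourth-order series for `α < 10⁻³` where the closed form cancels; `β = 1/s²`
clamped to `[10⁻⁶, 1−10⁻⁹]` at the `atanh` branch limit; `V_AB/V = 1`
convention throughout; `τ_d = r²/4D` per channel, tracked separately for
unequal channels.

## Known limitations

- The energy `E_K` weights cumulant entries as if independent (as the method
  prescribes); entries at different lags share data and are strongly
  correlated, so fitted uncertainties are approximate and two-species
  decompositions remain ill-conditioned at desk-scale durations.
- The delta-method/batch variances are first-order; batch means slightly
  underestimate long-run variances for the heavy-tailed (`u^{-3/2}`)
  correlation decay of 3D diffusion.
- Dead-time, afterpulsing, triplet corrections and analog detectors are out
  of scope; arrival-time parsing covers plain tick lists, not vendor TTTR
  formats.
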