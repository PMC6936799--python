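# cpch — correlated photon-counting histograms

`cpch` resolves mixtures of fluorescent species **jointly by molecular
brightness and diffusion** from fluorescence-fluctuation data. It implements
the correlated photon-counting histogram: the joint distribution
`p_N(n_x, n_y | τ)` of the photon counts in two counting bins of length `T`
separated by a lag `τ`. Classical techniques are special cases of one object
computed from one dataset:

- **FCS** — `G(τ) = 1 + (K)₁₁(τ) / ((K)₁₀ (K)₀₁)` from the first joint
  factorial cumulant,
- **PCH** — the marginal over either axis (independent of `τ`),
- **FCA** — the 1D factorial cumulants `(K)_n = N εⁿ γ_n`,
- **dual-colour PCH** — the joint distribution at `τ = 0`,
- **RICS-style imaging** — pixel offsets of a raster scan mapped to lags,
  with the scan displacement entering as a flow term.

For a 3D Gaussian observation volume the factorial cumulants of a species
mixture are closed-form,

    (K)_{m,n}(τ, T) = γ_{m,n} Σ_i N_i (ε_i T)^{m+n} κ_{m,n}(τ, D_i) B_{m,n}(T, τ_{d,i}),

with shape factors `γ_{m,n}` (`(m+n)^{-3/2}` for identical channels),
diffusion factors `κ_{m,n}(τ)` with `τ_d = r²/4D`, and binning functions
`B_{m,n}` correcting for motion during long bins. Fitting the empirical
factorial cumulants (orders `m+n ≤ 4`, multi-tau lag/bin grid, delta-method
error bars) with a nested-sampling Monte-Carlo optimizer recovers
occupancies, brightnesses and diffusion times per species. The package also
computes the full joint distributions by three cross-checking routes
(factorial-moment series, generating-function FFT, exact recursion), the
analytic two-species inversion of the 1D cumulants, and ships
Brownian-dynamics simulators (point traces and raster-scanned image stacks)
for validation against known ground truth. Audience: people building or
validating FFS analysis pipelines — no external data is required.

## Worked example

Simulate a single species (N = 1 molecule in the observation volume,
brightness 0.24448 counts per 10 µs bin, τ_d = 175.7 µs, s = 1.928) for
60 s, build factorial cumulants on a multi-tau grid, and fit:

```python
from cpch.protocols import run_table1_single_species

res = run_table1_single_species(seed=1, duration=60.0)
print(res.fit.summary())
```

```
cPCH nested-sampling fit
  energy kind: EK   best energy: 0.3958   energy at mean: 0.5318
  live points: 100   replacements: 1500   energy evaluations: 189047

   parameter       estimate      std err
          N1       0.992931      0.00868
        eps1          24571          205
      tau_d1    0.000169913     1.41e-05
           s        2.26262        0.547
      gamma3       0.197157      0.00424
      gamma4       0.138527        0.013
  eps1_per_bin        0.24571    (derived)
   tau_d1_us        169.913    (derived)
```

The fitted occupancy (`N1 ≈ 0.99`), brightness (`0.246` counts/bin against
the true `0.244`) and diffusion time (`170 µs` against `175.7 µs`) recover
the simulation's ground truth to a few percent from one minute of data; the
shape factors come out near their ideal Gaussian-volume values
(`γ₃ = 0.192`, `γ₄ = 0.125`). `res.E_K_truth` evaluates the fit energy at
the true parameters — 0.791 for this run, consistent with a correct model
(≈ 1 expected when model and error bars agree).

Lower-level building blocks are plain functions/classes: `OpticalConfig`,
`SpeciesParams`, `CpchModel`, `factorial_cumulant`, `pN_fft` /
`pN_recursion`, `cumulant_table_from_counts`, `CumulantFitModel`,
`invert_two_species`, `simulate_trace`, `simulate_image_stack`. A thin
`cpch` command-line tool wraps the common pipelines
(`cpch simulate / hist / cumulants / fcs / pch / invert / fit / spatial`).

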