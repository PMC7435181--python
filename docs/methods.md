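# Methods

This note documents the models implemented in `angulai`, the choices made
where the design was genuinely open, and what the synthetic data can and
cannot show.

## Evaluation protocol

The 221 samples are split once into 176 calibration and 45 validation
samples, uniformly at random, with a fivefold assignment of the
calibration set. The same partition and folds are reused at every view
zenith angle (VZA): the physical samples are common to all angles, so
re-splitting per angle would confound sampling noise with angular effects.
(The alternative — an independent split per angle — is available by
constructing a fresh `Partition` per dataset.)

Metrics are the coefficient of determination R² = 1 − SSE/SST and
RMSE = √(Σ(Pᵢ − Oᵢ)²/n). Validation-set R² can be negative and is reported
raw, never clamped, so method comparisons stay honest. Angular decline is
reported as 100·(R²(0°) − R²(θ))/R²(0°) — decline relative to nadir — and
method-vs-method differences as 100·(R²_a − R²_b)/R²_b; both are undefined
(NaN) when the reference R² is not positive.

## Vegetation index catalog

The catalog carries 21 published narrowband indices (8 two-band, 8
three-band, 5 four-band) computed by nearest-band lookup on the canonical
400–900 nm, 1-nm grid (501 bands). Conventions that the index literature
leaves symbolic are fixed and exposed as module constants: the NIR,
red-edge and red bands of CIred-edge and MTCI are 790/720/670 nm; MSAVI2's
broad "NIR" and "red" bands are region means over 760–900 and 630–690 nm.
The red-edge position index anchors at the constant 700 nm (the
linear-interpolation method's lower wavelength), not the reflectance at
700 nm. Zero denominators and negative square-root arguments (possible in
MCARI2/MTVI2/MSAVI2 on unusual spectra) yield NaN markers, never
exceptions; regressions drop flagged samples and record the count.

## Two-band optimization

For each ordered pair (λ₁, λ₂) on the search grid, the ND/SR/DVI index is
computed per sample and regressed linearly on LAI over the calibration
set; the R² fills a surface whose argmax (ties broken toward the smallest
λ₁, then λ₂) is the optimal pair. The surface is vectorized through the
identity R² = corr(x, y)² for single-predictor least squares, and is
verified cell-by-cell against a naive double-loop oracle in the tests.
Cells with a constant index (both diagonals) or fewer than 3 valid samples
are undefined; a constant-LAI input defines R² as 0 with a warning. The
default search step is 1 nm; experiment-scale runs use 2 nm, which leaves
the location of the red-edge optimum unchanged while quartering the cell
count. ND and DVI surfaces are exactly symmetric under band swap; SR
surfaces are not (the reciprocal is a nonlinear transform). Note that ND
and SR fits can legitimately exceed the two-predictor OLS fit on the raw
bands — they are nonlinear functions of the pair — while DVI, linear in
the bands, cannot.

## PLSR

PLS1 via NIPALS: X and y are mean-centered (unit-variance scaling of X is
available but off by default — reflectance bands share units); each
component takes the weight vector w ∝ Xᵀy, scores t = Xw, loadings
p = Xᵀt/tᵀt and q = yᵀt/tᵀt, then deflates X and y. The regression vector
is W(PᵀW)⁻¹q; predictions through it agree with explicit sequential score
projection to 1e-10 (two independent code paths, both tested). Successive
scores are mutually orthogonal (tested at 1e-8). With A = rank the
predictions equal multivariate OLS; with a single predictor and A = 1 they
equal simple OLS — both limits are tested, as is agreement with an
established reference implementation.

The component count A is chosen by fivefold cross-validated RMSE over
A = 1..A_max (default 15, above the expected optimum range), ties toward
the smaller A. One NIPALS fit per fold serves all candidate A values,
since NIPALS models are nested.

## BPNN

A single-hidden-layer feedforward regressor: standardized inputs, ReLU
activation, linear output, trained by full-batch Adam (step 1e-3-style
conventional moments 0.9/0.999; step fixed at 1e-2 here since full-batch
gradients are low-variance) on mean squared error, with the target
standardized for conditioning. Each training run holds out a seeded 15%
monitor split and keeps the best snapshot by monitor loss, stopping after
a 50-epoch plateau — an interpolating network otherwise overfits its
calibration fold. The hidden size is selected from a grid (default
{5, 10, 20, 50, 100, 200}, spanning 5–200) by fivefold CV RMSE; then
`repeats` random initializations are compared by the same CV criterion and
the winner is retrained on the full calibration set. The default of 20
repeats keeps desk-scale runtime; experiment-scale runs use 5 repeats and
the reduced grid {10, 50} with 300 epochs — at canopy-spectra problem
sizes the selection is insensitive to the larger grid, and the runtime
budget goes to seeds instead. Everything is deterministic given the seed;
non-finite losses trigger a seeded restart.

## The synthetic canopy generator

The generator stands in for an undisclosed multi-angular field campaign on
winter wheat; it is a statistical emulator, not a radiative transfer
model.

**Canopy state.** LAI ~ truncated normal, mean 4.90, SD 1.63, range
[1.25, 8.76] (the campaign's reported moments), n = 221. Chlorophyll
content cab = 15 + 5·LAI + N(0, 4) µg cm⁻² couples pigment to structure,
so red-edge position carries LAI information. A per-sample soil brightness
factor ~ N(1, 0.08) varies the background.

**Leaf spectrum.** A sigmoid red edge joins a visible baseline (0.08) to a
NIR plateau (0.50); Gaussian absorption troughs at 450 and 670 nm deepen
with cab, saturating as 1 − exp(−cab/8) — nearly saturated over the
realistic cab range, so the visible carries limited pigment information,
as in dense green canopies; a green reflectance peak sits at 550 nm. The
red-edge inflection shifts by 0.5 nm per µg cm⁻² of cab, putting the
strongest, least-saturating LAI signal in 700–760 nm.

**Angular mixing.** The sensor-facing mixture is
R(λ) = a(θ)·(1−g)·leaf(λ) + g·soil(λ), with gap fraction
g = exp(−k·Ω·LAI/cosθ) (k = 0.5, clumping Ω = 0.9) and a linear
brightness asymmetry a(θ) = 1 + asym_h·θ/60 (asym_h = −0.05: backscatter
slightly brighter). The 1/cosθ path length makes oblique views saturate in
LAI earlier, which removes signal at large |θ| at the high-LAI end.

**Noise.** Three components, each with SD growing by (1 + 2·|θ|/60):
a spectrally smooth multiplicative field (SD 0.045 at nadir, Gaussian
correlation ≈ 35 nm) emulating BRDF and illumination drift — nearby bands
share it, so close band pairs cancel it while distant pairs cannot; an
independent per-band multiplicative term (SD 0.01); and an additive floor
(SD 0.004 reflectance) that dominates in dark absorption bands, as in real
spectroradiometers. The smooth component is what degrades full-spectrum
methods (PLSR, BPNN) away from nadir — independent noise alone would be
averaged out over 501 bands — and the additive floor is what keeps dark
visible bands from looking noiselessly informative.

These defaults were calibrated once, against the qualitative ordering the
analysis is meant to exhibit (red-edge optima at nadir; accuracy declining
with |VZA| for every method), never against any particular R² value, and
ship frozen in `default_config.yaml`.

**What the generator does not contain:** hotspot geometry, row structure
and leaf angle distributions, SWIR water features, atmospheric effects,
sensor spectral response functions, and any genuine radiative transfer.
Passing tests therefore show that the pipeline recovers the structure this
model encodes — they are evidence about the methods' relative behavior
under controlled conditions, not about absolute accuracy on field data.

## Determinism and problem sizes

Every stochastic stage receives a seed derived from one master seed via
child `SeedSequence`s (simulate / partition / fit), so the full experiment
is one-number reproducible and reruns are byte-identical. Experiment-scale
runs in the test suite and the acceptance script use: 221 samples, the 13
standard angles for generation with method evaluation concentrated at
−60°/0°/+60° (the angles the angular contrast is defined on), 2-nm band
search, PLSR A_max 12–15, BPNN grid {10, 50} with 5 repeats and 300
epochs, and 20 generator seeds for the across-seed assertions — sizes
chosen so a full run completes in minutes on one CPU while leaving every
qualitative conclusion unchanged at larger settings.

## Known limitations

- The BPNN is a deliberately small reference implementation (one hidden
  layer, full-batch Adam); it is not a tuned deep-learning baseline.
- The R² surface at 1-nm step over 501 bands holds ~251k cells per angle
  and index type in memory as a dense matrix (~2 MB); fine at this scale,
  wasteful for much finer grids.
- `resample_to_grid` is piecewise-linear; instruments with strongly
  non-triangular bandpass functions would need a convolution resampler.
- The ±90° view geometry limit is a hard error; the Beer–Lambert gap model
  is meaningless at grazing angles anyway.
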