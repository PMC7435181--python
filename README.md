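# angulai

Multi-angular hyperspectral estimation of leaf area index (LAI) in crop
canopies: a tested pipeline comparing four retrieval methods across view
zenith angles (VZAs), driven by a synthetic multi-angular canopy
reflectance generator.

## The problem

LAI (one-sided leaf area per unit ground area, m² m⁻²) is the central
structural descriptor of a crop stand. It can be estimated from canopy
reflectance spectra because leaf optics and canopy gap fraction shape the
spectrum — most strongly in the *red edge*, the steep reflectance rise
between ~690 and ~740 nm. But canopy reflectance is directional: a sensor
at an oblique view zenith angle sees a different mixture of leaf, soil and
shadow than one at nadir, so the accuracy of any LAI retrieval method
depends on the viewing angle. This package implements and compares, per
signed VZA (negative = backscattering), the four standard families of
retrieval methods:

1. **Published vegetation indices** — 21 two-, three- and four-band
   narrowband indices (NDVI, OSAVI, VOG, CIred-edge, mND705, MTCI, DDn,
   TCARI/OSAVI, red-edge position, …) each used as the predictor of a
   linear LAI model.
2. **Optimal two-band indices** — exhaustive search over all wavelength
   pairs (λ₁, λ₂) in 400–900 nm for the normalized-difference
   ND = (R_λ₁ − R_λ₂)/(R_λ₁ + R_λ₂), simple-ratio SR = R_λ₁/R_λ₂ and
   difference DVI = R_λ₁ − R_λ₂ forms, maximizing the R² of the linear
   LAI fit (an R² surface over the band-pair grid).
3. **Back-propagation neural network (BPNN)** — one hidden ReLU layer on
   the full 501-band spectrum, trained with full-batch Adam; the hidden
   size is chosen from a grid by fivefold cross-validated RMSE and the
   best of several random initializations is kept.
4. **Partial least squares regression (PLSR)** — from-scratch NIPALS
   (PLS1) on the mean-centered 501-band spectrum; the number of latent
   variables is chosen by fivefold cross-validated RMSE.

All methods share one random 176/45 calibration/validation split of the
221 samples (and one fold assignment), reused at every angle, and are
scored with R² = 1 − SSE/SST and RMSE = √(Σ(Pᵢ−Oᵢ)²/n).

No public multi-angular field dataset accompanies this problem, so the
package ships a first-class synthetic generator (`synthetic_canopy`) that
emulates the statistical structure of such a campaign: 221 samples with
LAI ~ truncated normal (mean 4.90, SD 1.63, range 1.25–8.76), 13 VZAs from
−60° to +60° in 10° steps, Beer–Lambert gap-fraction mixing of a
parametric leaf spectrum with a soil line, chlorophyll coupled to LAI, a
red edge whose inflection shifts with chlorophyll, and observation noise
(spectrally smooth + independent + additive floor) growing with |VZA|.

## Worked example

```python
import angulai as ag

# synthetic campaign: 221 samples at -60, 0, +60 degrees
cfg = ag.default_config().replace(seed=1)
datasets = ag.generate_dataset(cfg, vzas=[-60, 0, 60])
part = ag.make_partition(datasets[0], n_train=176, k=5, seed=1)
cal = datasets[0].subset(part.train_ids)
val = datasets[0].subset(part.test_ids)

# optimal two-band DVI at nadir (2-nm search step)
surface = ag.r2_surface(cal, "DVI", step=2)
best = ag.select_optimum(surface, cal)
print(f"DVI optimum ({best.lambda1:.0f}, {best.lambda2:.0f}) nm, "
      f"calibration R2 = {best.r2:.2f}")

# PLSR with cross-validated latent-variable count
sel = ag.select_components(cal.spectra.reflectance, cal.lai, A_max=15)
model = ag.fit_plsr(cal.spectra.reflectance, cal.lai, sel.chosen)
pred = model.predict(val.spectra.reflectance)
print(f"PLSR: A = {sel.chosen}, validation R2 = "
      f"{ag.r_squared(val.lai, pred):.2f}, RMSE = {ag.rmse(val.lai, pred):.2f}")
```

Output (seed 1):

```
DVI optimum (722, 762) nm, calibration R2 = 0.81
PLSR: A = 7, validation R2 = 0.90, RMSE = 0.48
```

The DVI optimum falls on two red-edge bands — the red edge carries most of
the LAI signal — and PLSR's validation R² at nadir exceeds what the same
model achieves at ±60° (run the same code on `datasets[60]` to see the
decline).

The same pipeline is scriptable from the shell:

```bash
angulai simulate --out-dir data --seed 1
angulai optimize --spectra data/spectra_vza+0.csv --lai data/lai.csv \
    --type DVI --step 2 --n-train 176 --seed 1
angulai report --out report_dir --seed 1     # full 13-angle experiment
```

## Layout

| module | contents |
|---|---|
| `angulai.spectra_io` | data model, CSV dialect, grid resampling, shared partition |
| `angulai.synthetic_canopy` | the multi-angular canopy generator and its config |
| `angulai.vi_catalog` | the 21 published vegetation indices |
| `angulai.band_optimizer` | exhaustive two-band R² surfaces and optima |
| `angulai.estimators` | NIPALS PLSR, component selection, BPNN |
| `angulai.angular_eval` | metrics, per-angle profiles, experiment driver |

See `docs/methods.md` for the model assumptions, parameter choices and
limitations.
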