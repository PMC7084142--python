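# cryoalgae

Glacier algae bloom on the bare ablation zone of ice sheets each summer,
screening their chloroplasts behind a dense vacuolar phenolic pigment.
That pigment makes the cells extraordinary light absorbers: it protects
the photosystems, dumps the intercepted energy as heat into the
surrounding ice, darkens the surface, and thereby amplifies melt.
`cryoalgae` implements the full computational chain that links single-cell
photophysiology and pigmentation to ice-surface radiative forcing, melt,
bloom development and albedo — for researchers in supraglacial microbial
ecology and ice-sheet surface energy balance.

The core quantities:

- **Photophysiology** — PSII quantum yields from PAM fluorometry
  (F_v/F_m = (F_m−F_o)/F_m, Y(PSII) = (F_m′−F)/F_m′,
  NPQ = (F_m−F_m′)/F_m), relative electron transport
  rETR = Y(PSII)·E·0.5, and rapid-light-curve fits of the
  photoinhibition-capable P–E model
  rETR(E) = P_s(1−e^{−αE/P_s})e^{−βE/P_s}, reporting α, rETR_max,
  E_k = rETR_max/α. A shading correction rescales incident excitation by
  the phenolic absorption share at the fluorometer wavelength
  (E′ = E(1−p), p ≈ 0.94 at 660 nm) to expose the chloroplast-level
  response.
- **Bio-optics** — extract extinction e(λ) = A/(l·c) by per-wavelength
  regression over a calibration series, conversion to mass-specific
  absorption (m²·mg⁻¹), and the additive single-cell absorption
  cross-section a(λ) = Σᵢ aᵢ(λ)·Cᵢ (m²·cell⁻¹).
- **Energy budget → melt** — per-cell absorbed photon flux a(λ)·E(λ)
  against the geometric ceiling (irradiance × half the lateral area of a
  cylindrical cell), an empirical packaging clip, population radiative
  forcing IRF(λ) = P_cell(λ)·N·A_factor·3600, and melt
  = ∫IRF dλ/(10⁴·334 J·cm⁻³) in cm water equivalent.
- **Bloom model** — daily biomass B′ = B + f·µB(1−B/K) − d·B where f is
  the fraction of hours with snow height < 2 cm, shortwave > 10 W·m⁻²
  and air temperature > 0.5 °C, with d = 10 %/day loss; the emergent
  plateau is B* = K(1−d/(f·µ)).
- **Albedo** — a 5-layer delta-Eddington two-stream ice column
  (underlying albedo 0.25) with algal absorption loaded into the top
  millimetre; visible broadband albedo over 350–700 nm.
- **Synthetic data** — seeded generators for every input (RLCs,
  calibration series, clear-sky diel spectra, seasonal forcing,
  abundance categories), so the whole chain runs offline.

## Worked example

```python
from cryoalgae import photophysiology as pp, synthetic as syn

curve = syn.gen_rlc(alpha=0.45, retrmax=0.45 * 938, noise_cv=0.0)
whole = pp.fit_rlc(curve)
chloro = pp.fit_rlc(pp.apply_shading_correction(curve, 0.94))
print(whole.Ek, chloro.Ek)
```

prints (`examples/rlc_fitting.py`):

```
whole cell:  alpha=0.450  rETRmax=422.1  Ek=938 umol photons m-2 s-1
chloroplast: alpha=0.450  rETRmax=25.3  Ek=56.3 umol photons m-2 s-1
```

The whole cell appears adapted to extreme irradiance (saturation onset
E_k ≈ 938 µmol photons·m⁻²·s⁻¹), but once the 94 % phenolic screen is
removed the chloroplasts saturate near 56 — low-light organelles behind
a sunshade. The `examples/` directory has one narrative script per
capability (RLC fitting, pigment calibration and cross-sections, energy
budget and melt, bloom season, ice albedo, full pipeline), each printing
its numbers with a line on what they mean.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the complete synthetic-season pipeline from scratch — RLC fitting
with shading correction, pigment calibration and cross-section
reconstruction, diel radiative forcing and melt per abundance category,
the threshold-gated bloom season, and the albedo sweep along the bloom
trajectory — writing per-stage CSVs and a content-hash manifest next to
the JSON result. Everything is recomputed at run time from the given
seed.
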