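# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `cryoalgae`, in the package's own terms.

## Photophysiology

**Model.** Rapid light curves are fitted with the saturating P–E form
with photoinhibition, rETR(E) = P_s(1−e^{−αE/P_s})e^{−βE/P_s}, the
β ≡ 0 exponential form available as `webb_exponential`. For β > 0 the
reported rETR_max is the analytic maximum
P_s·[α/(α+β)]·[β/(α+β)]^{β/α}, not the scale parameter P_s — the two
differ whenever photoinhibition is present. E_k = rETR_max/α is enforced
at construction of every fit object.

**Fitting.** Log-parameterized (P_s, α) and squared-parameterized β keep
the optimizer in the physical region without bounds; Levenberg–Marquardt
with ftol = xtol = gtol = 1e-15 is restarted from 5 seeded perturbations
of a slope/plateau initial guess (α₀ from the first nonzero-E steps, P_s₀
from the observed maximum, β₀ = 0). On noiseless forward-generated
curves parameters are recovered to ~1e-14 relative. The dark step (E = 0)
is excluded from the objective: its rETR is identically zero and carries
no information about the slope. Non-convergence returns the best
candidate flagged `converged=False`; it never fabricates values.

**Conventions.** The PSII/PSI excitation split is fixed at 0.5
(`PSII_FRACTION`), assuming equal allocation. NPQ defaults to
(F_m−F_m′)/F_m; the conventional Stern–Volmer form (F_m−F_m′)/F_m′ is
available via `convention="stern_volmer"`. Apparent negative quenching
(F_m′ > F_m, a transient artifact in noisy field data) is clamped to 0
with a logged warning.

**Shading correction.** The phenolic vacuole intercepts a fraction p of
the fluorometer's excitation before it reaches the chloroplast, so the
chloroplast-level curve is the measured curve with E′ = E(1−p), yields
unchanged. Because rETR = Y·E·0.5 also shrinks by (1−p), both axes scale
together: α is invariant and rETR_max, E_k scale by (1−p) exactly — a
property the tests verify to 1e-6. p is supplied per analysis (typically
the phenolic class fraction of the cross-section at 660 nm, ≈ 0.94);
whether such a fraction should be uniform across treatments or
re-derived per sample is a user decision, not assumed here. p = 1 is
rejected as a degenerate (all-dark) curve.

## Bio-optics

Extinction e(λ) is the per-wavelength ordinary-least-squares slope of
absorbance against concentration × path length, through the origin
because spectra are blank-corrected; `fit_intercept=True` reports a free
intercept to flag blank drift. Negative slopes are clamped to zero with
a warning (absorption is non-negative). The conversion to m²·mg⁻¹ is
1e-4 ×, with an optional ln(10) factor for users who want a natural-log
absorption coefficient rather than a decadic one; the decadic form is
the default and outputs state no more than the conversion applied.
Concentrations are assumed expressed on the same volume basis as the
absorbance measurement.

Cross-sections are strictly additive, a(λ) = Σ aᵢ(λ)·Cᵢ, with no
packaging physics at this stage. Spectra on different grids are linearly
resampled onto the intersection at the finer spacing; extrapolation is
an error. The canonical extract grid is 250–750 nm at 1 nm; joint
computations with irradiance (280–750 nm) use the intersection.

Literature in-vivo spectra for chlorophylls and carotenoids are *not*
transcribed; `synthetic.default_pigment_spectra` ships clearly labelled
synthetic Gaussian stand-ins at canonical band positions, and no test or
result depends on their exact values. All carotenoids are treated as
photoprotective by default (the photosynthetic-carotenoid class is
supported but zero-content).

## Energy budget, IRF and melt

Photon/energy conversion uses CODATA h, c, N_A (scipy.constants) and is
exactly invertible. The light available to a benthic cell is incident
irradiance × half the lateral surface of a cylinder, π·w·l/2 (the
upward-facing half of a prostrate filament; default cell 29.60 × 12.04
µm → 5.598e-10 m²; a rectangular alternative can be constructed by
supplying a custom geometry). The packaging correction clips absorbed to
available flux wavelength-by-wavelength, rescaling all pigment classes
by the common factor available/absorbed (proportional allocation); a
`phenolics_last` allocation — photosynthetic classes keep their share
and phenolics take the residual — is available by argument. The
comparison is done per wavelength, where photon and energy units give
identical clip factors.

Population forcing excludes the chlorophyll classes (light routed to
photochemistry is not immediately dissipated as surface heat); the
budget report still shows chlorophyll capture as a fraction. The
volume-to-area factor converting cells·mL⁻¹ of melted sample to
cells·m⁻² of ice surface is **required** — `volume_to_area_factor()`
documents the default construction (2 cm sampling depth × 1e4 cm²·m⁻²
× 0.9 ice/water density ratio = 1.8e4 mL·m⁻²) but no silent default is
applied inside `irf_per_m2`. Melt uses the latent heat of fusion
334 J·cm⁻³ and integrates 280–750 nm; one hour of 927.78 W·m⁻²
absorbed forcing is exactly 1 cm w.e., an identity the tests assert to
1e-6. Melt is exactly linear in abundance, so category statistics
(mean, SD, SE over all measured abundances) come from a single
unit-abundance diel computation.

## Bloom model

Forward-Euler daily step B′ = B + f·µB(1−B/K) − d·B. Choices:

- **Strict thresholds.** Hours with SH exactly 2 cm, SWD exactly
  10 W·m⁻² or TT exactly 0.5 °C are non-productive (strict
  inequalities), tested exhaustively at the boundaries.
- **Simultaneous growth and loss** within one day-step, not sequential;
  order matters at O(µd) and the simultaneous form is the documented
  choice. The loss applies every day, snow or sun.
- **Net growth as signed arithmetic**: decline happens whenever
  f·g < d·B; an optional `hard_gate` zeroes net-negative days instead.
- Growth is floored at 0 for B > K (no negative "growth"; decline above
  K comes from the loss term), and biomass at a configurable refuge
  floor `b_min` (default 0).
- µ, K and B₀ are configuration, not constants: the productivity data
  behind them are not reproducible here. Pipeline defaults µ = 0.3 d⁻¹,
  K = 17,000 ng DW·mL⁻¹, B₀ = 100 ng DW·mL⁻¹ are field-realistic
  choices (K at the top of observed biomass, µ of slow-growing
  psychrophiles, inoculum well below the bloom scale);
  `fit_logistic_productivity` recovers (µ, K) from a user-supplied
  (biomass, net-productivity) table by linear least squares on
  [B, B²], exact on noiseless logistic data.
- The equilibrium B* = K(1−d/(f·µ)) makes the field-observed "carrying
  capacity" an emergent, forcing-dependent quantity; simulations match
  it to 1e-6 after 500 constant-forcing days.

Trajectories are deterministic functions of forcing and parameters.

## Two-stream albedo

Hemispheric-mean two-stream (γ₁ = 2−ω(1+g), γ₂ = ω(1−g)) after
delta-Eddington scaling, diffuse-only incidence, solved as one banded
linear system over all layers (modes anchored at layer bottoms so all
exponentials are ≤ 1; no overflow for optically thick layers).
Conservative scattering is regularized by clipping ω to 1−1e-9.
Verified limits: transparent column → underlying albedo (0.25 default)
to machine precision; conservative semi-infinite layer → ≥ 0.999; black
base under transparent layers → 0; and agreement with an independent
adding–doubling combination of the same layer reflectances to 1e-6.

Algal cells add absorption only (their cross-sections were derived as
absorption); a load of L ng DW·mL⁻¹ maps to a mass mixing ratio
χ = L×1e-9 kg algae per kg ice via the identity 1 mL melted ice ≡ 1 g
ice mass — a documented, density-independent choice, adjustable through
`mass_ratio_scale`. ω and k_ext of the top layer are updated
consistently (ω′ = scat/(scat+abs′)). Ice-grain single-scattering
properties from geometric optics are out of scope; `default_column`
ships the 5-layer configuration (0.001 + 4×0.01 m; 400/400/500/800/800
kg·m⁻³; 1,000–8,000 µm grains) with a clearly synthetic smooth
parameterization (k_ext ≈ 3/(ρ_ice·r_eff), red-increasing absorption,
g = 0.89) whose purpose is testability, not radiative realism in the
near-IR.

## Synthetic data: what it does and does not emulate

Generators reproduce the *statistical structure* the analysis assumes:
nine-step RLCs to 4,000 µmol photons·m⁻²·s⁻¹ with multiplicative yield
noise; a phenolic extract spectrum with its UV-B maximum at 300 nm,
335-nm shoulder and red-decreasing visible tail, inverse-designed so
phenolics carry 94 % of cellular absorption at 660 nm at the measured
quota of 0.041 ng phenol·cell⁻¹ (≈ 11× the chlorophyll-a content);
53-sample log-uniform calibrations spanning 187–2.1e4 cells·mL⁻¹;
clear-sky diel spectra from solar-elevation geometry × a smooth
~5,800 K solar template normalized to a configurable noon PAR (default
1,700 µmol photons·m⁻²·s⁻¹); an ablation-season forcing with linear
snow retreat (held ≥ 2 cm until the stated clearance date), diurnal
shortwave and a seasonal+diurnal temperature cycle; and zero-truncated
lognormal abundances moment-matched to the field categories
(low 186±276 n=27, medium 3,711±2,333 n=34, high 8,989±4,773 n=103
cells·mL⁻¹ — skewed laws are required since the SDs approach or exceed
the means).

They do **not** emulate atmospheric radiative transfer, regional
climate physics, inter-annual variability, spatial heterogeneity, or
measured absolute pigment spectra. A green test therefore establishes
correctness of the computational chain — recovery of known parameters,
conservation, scaling laws, closed-form dynamics, solver agreement with
an independent oracle — not agreement with any field-measured absolute
value (absolute melt rates, site carrying capacities and MODIS albedo
comparisons depend on unpublished inputs and are explicitly out of
scope). All randomness flows through explicitly seeded
`numpy.random.Generator` instances; identical arguments give
bitwise-identical outputs.

## Known limitations

- The P–E fit assumes multiplicative/additive noise symmetry; heavily
  censored or non-monotone field curves may converge to local minima
  despite the multistart (flagged via `converged` and `rss`).
- The packaging clip is empirical, not a radiative-transfer treatment
  of intracellular self-shading.
- The albedo solver is diffuse-only; direct-beam geometry, algal
  scattering, and near-IR grain realism are not modeled.
- Dry-weight bookkeeping (biovolume → ng DW, cell mass for mixing
  ratios) uses a 0.2 pg·µm⁻³ density typical of microalgae; users with
  measured conversions should supply them.
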