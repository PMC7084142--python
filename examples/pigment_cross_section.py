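"""Calibrate phenolic extinction and reconstruct a cell's absorption.

Builds a 53-sample Beer–Lambert calibration series, recovers the
extinction spectrum e(λ) = A/(l·c) by per-wavelength regression,
converts it to a mass-specific absorption coefficient, and assembles
the single-cell absorption cross-section a(λ) = Σ aᵢ(λ)·Cᵢ.
"""

import numpy as np

from cryoalgae import biooptics as bo
from cryoalgae import synthetic as syn

spectra, profile = syn.default_cell_model()
e_true = spectra["phenolic"].mass_absorption / 1e-4  # L g-1 cm-1

calib = syn.gen_calibration(e_true, n_samples=53, noise_cv=0.02, seed=1)
fit = bo.fit_extinction(calib)
err = np.abs(fit["e_L_g_cm"] - e_true) / e_true.max()
print(f"calibration: n={calib.concentrations.size} samples spanning "
      f"{calib.cell_abundance.min():.0f}-{calib.cell_abundance.max():.0f} cells/mL")
print(f"extinction spectrum recovered; worst relative error "
      f"{err.max() * 100:.2f}% at 2% measurement noise")

cs = bo.reconstruct_cross_section(profile, list(spectra.values()))
total = bo.spectral_integral(cs, 250, 750)
no_phen = bo.spectral_integral(cs.without("phenolic"), 250, 750)
frac660 = bo.class_fraction_at(cs, "phenolic", 660.0)

print(f"integrated cross-section 250-750 nm: {total * 1e10:.0f} x1e-10 m2/cell "
      f"(without phenolics: {no_phen * 1e10:.1f})")
print(f"phenolic share of absorption at 660 nm: {frac660 * 100:.1f}%")
print()
print("Phenolic pigment dominates the cell's light capture by more than an")
print("order of magnitude; the 660-nm share is what the shading correction")
print("feeds back into the fluorometry.")
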