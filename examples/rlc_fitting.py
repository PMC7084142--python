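"""Fit a rapid light curve and apply the phenolic-shading correction.

Generates a synthetic whole-cell RLC (nine steps, 0–4,000 µmol
photons·m⁻²·s⁻¹), fits the photoinhibition-capable P–E model, then
reduces the incident excitation by the 94 % phenolic absorption share
at the 660-nm fluorometer wavelength and refits to obtain the
chloroplast-level response.
"""

from cryoalgae import photophysiology as pp
from cryoalgae import synthetic as syn

curve = syn.gen_rlc(alpha=0.45, retrmax=0.45 * 938, noise_cv=0.0)

whole = pp.fit_rlc(curve)
chloro = pp.fit_rlc(pp.apply_shading_correction(curve, 0.94))

print(f"whole cell:  alpha={whole.alpha:.3f}  rETRmax={whole.rETRmax:.1f}  "
      f"Ek={whole.Ek:.0f} umol photons m-2 s-1")
print(f"chloroplast: alpha={chloro.alpha:.3f}  rETRmax={chloro.rETRmax:.1f}  "
      f"Ek={chloro.Ek:.1f} umol photons m-2 s-1")
print()
print("Ek is the irradiance where photosynthesis saturates. The whole cell")
print("looks extremely high-light adapted (Ek ~938), but once the phenolic")
print("screen is accounted for, the chloroplasts saturate near ~56 -- they")
print("are low-light adapted organelles hiding behind a sunshade.")
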