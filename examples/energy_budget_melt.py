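"""Per-cell energy budget, population radiative forcing and melt.

Computes the diel cycle of absorbed light for a representative cell
under clear-sky spectral irradiance, clips absorption to the light
geometrically available (packaging correction), scales by measured
abundance categories and converts the absorbed power to hourly and
daily meltwater in cm water equivalent.
"""

from cryoalgae import energy_budget as eb
from cryoalgae import synthetic as syn

cs = syn.default_cross_section()
day = syn.gen_irradiance_day(latitude=67.0, date="2016-07-26")
v2a = eb.volume_to_area_factor(depth_cm=2.0, density_ratio=0.9)

noon = eb.build_budget(cs, eb.DEFAULT_CELL, day[12])
fr = noon.fractions()
print("solar-noon budget (fraction of light available to the cell):")
for k, v in sorted(fr.items(), key=lambda kv: -kv[1]):
    print(f"  {k:<11s} {v * 100:6.2f}%")

print(f"\nvolume-to-area factor: {v2a:.0f} mL/m2 (2 cm sampling depth)")
print("category   daily melt (cm w.e./d)  mean +/- SE")
for cat in ("low", "medium", "high"):
    sample = syn.gen_abundances(cat, seed=0)
    res = eb.diel_melt(cs, eb.DEFAULT_CELL, day, sample, v2a)
    print(f"  {cat:<8s} {res.daily_melt_mean:8.3f} +/- {res.daily_melt_se:.3f} "
          f"(n={sample.n})")
print()
print("Melt scales linearly with cell abundance: heavily loaded ice patches")
print("generate substantially more algal melt than lightly colonized ones.")
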