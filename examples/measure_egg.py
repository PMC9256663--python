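"""Render a synthetic egg and measure its diameter and spherical volume.

Only the egg shell is measured: embryo body and yolk segmentations inside
eggs are unreliable and excluded from output by policy.
"""

from ichthyoflow import EggSpec, RunConfig, render_egg, run_pipeline

scene = render_egg(EggSpec(diameter_mm=1.36), seed=7)
results, _ = run_pipeline(
    [("egg-demo", scene.image, scene.regions)], RunConfig(mode="egg")
)
row = results.iloc[0]

print(f"major / minor axis : {row['egg_major_mm']:.3f} / {row['egg_minor_mm']:.3f} mm")
print(f"mean diameter D_E  : {row['egg_diameter_mm']:.3f} mm (truth 1.360 mm)")
print(f"sphere volume V_E  : {row['egg_volume_mm3']:.4f} mm^3")
print(f"circularity        : {row['circularity']:.3f} (1.0 = perfect circle)")
# Cod eggs are nearly spherical; a circularity well below 1 would flag a
# bad segmentation rather than a genuinely elliptical egg.
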