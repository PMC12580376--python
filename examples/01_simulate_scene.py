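"""Generate a labelled synthetic multi-sensor scene.

Builds the default scene (621 soybean / 588 maize / 215 rice sample points,
5-day optical and 12-day SAR revisit over DOY 121-281, 30% cloud gaps,
12-look speckle) and prints what it contains.
"""

import numpy as np

import earlycrop as ec

scene = ec.generate_scene(ec.SceneConfig(seed=1))

print("samples per class:")
print(scene.samples["crop_class"].value_counts().to_string())
print(f"\noptical observations per sample: {len(scene.optical_doys)} "
      f"(DOY {scene.optical_doys[0]}..{scene.optical_doys[-1]})")
print(f"SAR observations per sample:     {len(scene.sar_doys)}")
print(f"fraction of cloud-flagged optical observations: {scene.cloudy.mean():.3f}")

# the noise-free class signatures behind the samples
profiles = ec.default_profiles()
grid = np.arange(121, 282)
sel = (grid >= 200) & (grid <= 260)
for crop in ("soybean", "maize"):
    vh = ec.generate_crop_profile(profiles[crop], grid)["vh"]
    print(f"mean VH backscatter DOY 200-260, {crop:8s}: {vh[sel].mean():6.2f} dB")
print("-> soybean's denser canopy raises its cross-polarized backscatter above "
      "maize after DOY 200; that contrast is what makes it identifiable early.")
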