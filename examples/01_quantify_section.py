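"""Quantify one synthetic coronal section: IS normalization, on-tissue
calibration, regional concentrations.

Builds a noisy in vivo risperidone section plus a spotted control section,
fits the six-point calibration curve in tissue-equivalent units, and reads
out regional total concentrations.  Concentrations are ng drug per g
tissue; the LLOQ is the lowest spotted standard (~103 ng/g).
"""

import kpuumap as km

noise = km.NoiseModel(pixel_cv=0.15, gain_amplitude=0.2, is_spray_cv=0.05)
atlas = km.default_atlas()
profile = km.default_profiles()["risperidone"]
layout = km.default_layout("risperidone")

control = km.generate_section(profile, "control", atlas, noise, seed=1)
spotted = km.generate_calibration(control, profile, layout, noise, seed=1,
                                  atlas=atlas)
curve = km.calibration_from_section(spotted, layout, "risperidone")
print(f"calibration: slope={curve.slope:.3e} per (ng/g), "
      f"R²={curve.r_squared:.4f}, LOD={curve.lod:.0f} ng/g, "
      f"LLOQ={curve.lloq:.0f} ng/g, accepted={curve.accepted}")

section = km.generate_section(profile, "in_vivo", atlas, noise, seed=2,
                              subject_id="animal1")
results = km.quantify_section(section, "risperidone", atlas, curve)
print("\nregion        C_tot (ng/g)   truth (ng/g)")
for region, r in results.items():
    truth = (profile.true_concentration(region, "in_vivo")
             if region != "whole_section" else
             profile.whole_section_concentration(
                 atlas, section.tissue_mask, "in_vivo"))
    flag = "  <LLOQ" if r.below_lloq else ""
    print(f"{region:13s} {r.concentration:10.1f} {truth:14.1f}{flag}")
print("\nEstimates track the generator truths to a few percent; white-"
      "matter regions (cc, ec, aca) carry visibly less drug.")
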