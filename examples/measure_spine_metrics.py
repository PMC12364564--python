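"""Measure the tool properties of a hook-shaped spine.

Generates a hooked spine profile with known geometry, re-measures it with
the shape pipeline, and classifies its morphotype.  In a real analysis the
profile would come from `geometry.read_profile_csv` or a mesh slice
instead of the generator.
"""

from spinemech import geometry, synth

params = synth.SpineGenParams(
    length=3.22,          # longest axis, mm (print scale used for testing)
    tip_angle=45.0,       # wedge opening angle, degrees
    tip_roc=0.08,         # apex cap radius, mm
    structural_curvature=100.0,  # centerline arc angle, degrees (a hook)
    base_width=0.8,
)
profile, truth = synth.generate_spine_profile(params)
mesh = synth.generate_spine_mesh(profile, lateral_compression=1.0)

metrics, centerline = geometry.measure_profile(profile, mesh=mesh)
morphotype = geometry.classify_morphotype(metrics, centerline)

print(f"tip angle            {metrics.tip_angle_deg:7.2f} deg   (true {truth.tip_angle_deg})")
print(f"tip radius (norm.)   {metrics.tip_roc_norm:7.4f}       (true {truth.tip_roc_norm:.4f})")
print(f"structural curvature {metrics.structural_curvature_deg:7.2f} deg   (true {truth.structural_curvature_deg})")
print(f"aspect ratio         {metrics.aspect_ratio:7.3f}")
print(f"volume               {metrics.volume_mm3:7.3f} mm^3")
print(f"morphotype           elongate={morphotype.elongate} hooked={morphotype.hooked} "
      f"wavy={morphotype.wavy} conical={morphotype.conical}")
print()
print("Sharpness (tip angle, tip radius) drives how much force puncture needs;")
print("structural curvature above ~60 deg marks a hooked spine, which tends to")
print("puncture over a wider range of approach angles.")
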