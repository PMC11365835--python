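"""Generate a synthetic dysplastic hip and inspect its morphology.

The phantom prescribes acetabular coverage per clock position, so the
radiographic indices below are known by construction — a dysplastic hip has
a lateral centre-edge (CE) angle around 10 degrees, an upsloping roof
(positive obliquity) and an acetabular head index around 60%.
"""

from raoplan import PhantomParams, frontal_indices, make_hip_phantom

model = make_hip_phantom(PhantomParams(seed=1))
print(f"pelvis: {len(model.pelvis_mesh.vertices)} vertices, "
      f"head: {len(model.head_mesh.vertices)} vertices, side: {model.side}")

fi = frontal_indices(model)
for key, val in fi.items():
    print(f"  {key:16s} {val:7.2f}")

# lateral_ce_deg ~ 10 (deficient roof), aro_deg ~ 25 (upsloping sourcil),
# ahi_pct ~ 59 (40% of the head uncovered), koehler_mm = 45 (lateralized).
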