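"""Clock-face coverage profile before and after virtual surgery.

The acetabular sector angle (ASA) is measured in 13 radial planes from
9:00 (posterior) through 12:00 (cephalad) to 3:00 (anterior). The planned
reorientation should raise coverage across the superior arc.
"""

from raoplan import (asa_profile, build_planning_model, make_hip_phantom,
                     plan_case)

model = make_hip_phantom()
plan = plan_case(model)
planning = build_planning_model(model, plan)

pre = asa_profile(model, source="preoperative")
post = asa_profile(planning, head_center=plan.planned_head_center,
                   source="planning")

print("position   preop ASA   planned ASA   gain")
for pos, a, b in zip(pre.positions, pre.values_deg, post.values_deg):
    print(f"  {pos:6s}   {a:7.1f}     {b:7.1f}     {b - a:+6.1f}")

# The 12:00 gain (~35 deg) is the lateral-coverage correction; anterior
# positions land near 137.5 deg, i.e. an anterior CE angle of 47.5 deg.
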