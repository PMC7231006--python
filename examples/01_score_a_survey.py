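"""Score one subject's liking survey into food groups and a guideline index.

Builds a small hand-written liking profile (a health-conscious eater:
high vegetable/fruit liking, low liking for sweets and fried foods), averages
items into the conceptual food groups, computes the guideline-weighted
theoretical diet quality index, and counts cardiometabolic abnormalities
from a biomarker panel.
"""

import pandas as pd

from likingdqi import GroupSchema, LikingProfile, score_groups, theoretical_dqi
from likingdqi.survey import BiomarkerPanel, count_abnormalities

schema = GroupSchema.default()

# A plausible rating per item: loves produce, dislikes sweets/fried food.
likes = {"vegetable": 80, "fruit": 75, "healthy fat": 50,
         "complex carbohydrate": 30, "low-fat dairy": 10, "salty": -10,
         "spicy/flavorful": 20, "refined carbohydrate": 0, "alcohol": -20,
         "sweet": -60, "saturated fat": -50, "high-fat protein": -70}
ratings = {}
for group, items in schema.groups.items():
    if schema.roles[group] == "food":
        ratings.update({item: float(likes[group]) for item in items})
ratings.update({item: 85.0 for item in schema.groups["pleasant"]})
ratings.update({item: -75.0 for item in schema.groups["unpleasant"]})

vec = score_groups(LikingProfile("subject-001", ratings), schema)
print("Group mean likings (-100 dislike ... +100 like):")
for group, value in sorted(vec.values.items(), key=lambda kv: -kv[1]):
    print(f"  {group:22s} {value:6.1f}")
print(f"  pleasant anchor        {vec.pleasant:6.1f}")
print(f"  unpleasant anchor      {vec.unpleasant:6.1f}")

groups_frame = pd.DataFrame([vec.values], index=["subject-001"])
dqi = theoretical_dqi(groups_frame)
print(f"\nTheoretical DQI: {dqi.scores.iloc[0]:.1f} "
      "(range -240..+240; higher = healthier liking pattern)")

panel = BiomarkerPanel(subject_id="subject-001", insulin=9.0, glucose=88.0,
                       hdl=62.0, ldl=85.0, total_cholesterol=168.0,
                       triglycerides=95.0, bmi=22.5, whr=0.76, sbp=112.0,
                       dbp=71.0, sex="female")
report = count_abnormalities(panel)
print(f"Cardiometabolic abnormalities: {report.count}/10 factors flagged "
      f"(HOMA-IR = {report.homa_ir:.2f}, normal < 2.0)")
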