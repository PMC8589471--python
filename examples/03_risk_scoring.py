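"""Score molar pairs with the published impaction risk model.

The fixed model is  ln(p/(1-p)) = 0.889 L + 3.396 A - 0.071 theta_b
- 0.089 theta_o - 19.797  (L in mm, A in mm^2, angles in degrees).
Longer contact lines and larger facets raise the impaction probability;
wider buccal and occlusal embrasures lower it.
"""

import pandas as pd

from interprox.stats import published_risk_score

pairs = pd.DataFrame([
    # the reference low-risk morphology
    {"label": "reference", "adjacent_line_length_mm": 3.52,
     "adjacent_surface_area_mm2": 6.21, "buccal_angle_deg": 54.15,
     "occlusal_angle_deg": 89.26},
    # a typical impaction-group morphology: larger facet, closed occlusal
    # embrasure
    {"label": "impaction-like", "adjacent_line_length_mm": 4.27,
     "adjacent_surface_area_mm2": 8.28, "buccal_angle_deg": 51.5,
     "occlusal_angle_deg": 59.5},
    # wide open embrasures around a short contact
    {"label": "open embrasures", "adjacent_line_length_mm": 2.8,
     "adjacent_surface_area_mm2": 7.0, "buccal_angle_deg": 75.0,
     "occlusal_angle_deg": 110.0},
])
pairs["risk_probability"] = published_risk_score(pairs)
print(pairs.set_index("label").round(4).to_string())
print("\nhigher contact area and tighter embrasures -> higher impaction risk")
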