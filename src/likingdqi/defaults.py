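"""Default survey instrument, food-group targets and scoring standards.

The package ships with the 73-item food/experience liking instrument it was
developed around: twelve conceptual food and beverage groups, seven
pleasant-experience and five unpleasant-experience items (the non-food liking
standards), plus an auxiliary lean-protein group used only by the
guideline-weighted index.  Alongside the item lists live the published
group-level summary statistics (means, SDs, pairwise correlations), the
internal-consistency (Cronbach alpha) targets, the guideline weights, the
0-100 scoring standard of the hybrid index, and the clinical abnormality
cut-offs.  Everything here is plain data; the functions that consume it live
in the sibling modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Food groups and survey items
# --------------------------------------------------------------------------

#: Twelve conceptual food/beverage groups with their survey items, ordered by
#: internal consistency (most to least reliable).
FOOD_GROUP_ITEMS: dict[str, tuple[str, ...]] = {
    "high-fat protein": (
        "sausage", "hotdog", "beef steak", "fried chicken", "bologna", "bacon",
    ),
    "refined carbohydrate": ("rice", "bagels", "pasta", "cracker", "pizza"),
    "sweet": (
        "ice cream", "cookies/cakes/pastries", "cake icing", "cheesecake",
        "chocolate milk", "soda", "sweetened coffee drink",
    ),
    "healthy fat": (
        "canned tuna in water", "salmon", "baked fish",
        "shrimp/other shellfish", "olive oil",
    ),
    "fruit": ("blueberry", "melon", "strawberry", "mango", "pineapple"),
    "alcohol": ("wine", "scotch", "dark beer"),
    "vegetable": (
        "broccoli", "carrots", "greens", "sweet potato", "mushrooms",
        "tomatoes", "tomato juice",
    ),
    "spicy/flavorful": (
        "horseradish/wasabi", "burn of a spicy meal", "tabasco sauce",
        "soy sauce", "grapefruit juice", "black coffee", "dark chocolate",
    ),
    "saturated fat": (
        "mayonnaise", "whole milk", "full fat dressing", "cheddar cheese",
    ),
    "salty": (
        "soup", "lean ham", "baked chicken", "chips", "salty pretzels",
        "french fries",
    ),
    "complex carbohydrate": (
        "whole wheat bread", "oatmeal", "shredded wheat cereal",
    ),
    "low-fat dairy": ("low-fat cottage cheese", "skim milk", "plain yogurt"),
}

#: Non-food experience items; ratings of these serve as hedonic anchors and
#: enter the regression models as covariates, never as diet signal.
PLEASANT_ITEMS: tuple[str, ...] = (
    "hearing your favorite piece of music",
    "smell of freshly cut grass",
    "favorite food",
    "favorite physical activity",
    "seeing a loved one completing a challenging task",
    "cooling off on a hot day",
    "watching tv",
)
UNPLEASANT_ITEMS: tuple[str, ...] = (
    "being caught in a lie",
    "glare of headlights at night",
    "most disliked physical activity",
    "least favorite food",
    "fear of being bitten by a snake",
)

#: Lean-protein group used only by the guideline-weighted (theoretical) index.
#: Its membership is not fixed by the instrument; this default reuses the
#: named lean items and may overlap the food groups above (role "auxiliary").
LOW_FAT_PROTEIN_ITEMS: tuple[str, ...] = (
    "lean ham", "baked chicken", "canned tuna in water",
)

# --------------------------------------------------------------------------
# Published group-level calibration targets
# --------------------------------------------------------------------------

#: Group order used for the correlation matrix below.
GROUP_ORDER: tuple[str, ...] = (
    "fruit", "refined carbohydrate", "sweet", "salty", "healthy fat",
    "saturated fat", "vegetable", "high-fat protein", "complex carbohydrate",
    "spicy/flavorful", "alcohol", "low-fat dairy",
)

GROUP_MEANS: dict[str, float] = {
    "fruit": 46.29, "refined carbohydrate": 40.45, "sweet": 33.37,
    "salty": 26.01, "healthy fat": 11.01, "saturated fat": 10.02,
    "vegetable": 5.44, "high-fat protein": 5.08, "complex carbohydrate": 2.51,
    "spicy/flavorful": -5.59, "alcohol": -10.28, "low-fat dairy": -11.54,
}

GROUP_SDS: dict[str, float] = {
    "fruit": 33.13, "refined carbohydrate": 29.02, "sweet": 30.09,
    "salty": 28.31, "healthy fat": 40.89, "saturated fat": 39.58,
    "vegetable": 34.19, "high-fat protein": 41.36,
    "complex carbohydrate": 36.23, "spicy/flavorful": 34.75,
    "alcohol": 51.63, "low-fat dairy": 39.20,
}

# Upper triangle of the published pairwise group correlations.
_CORR_UPPER: dict[tuple[str, str], float] = {
    ("fruit", "refined carbohydrate"): 0.06,
    ("fruit", "sweet"): -0.06,
    ("fruit", "salty"): -0.01,
    ("fruit", "healthy fat"): 0.13,
    ("fruit", "saturated fat"): 0.03,
    ("fruit", "vegetable"): 0.43,
    ("fruit", "high-fat protein"): -0.13,
    ("fruit", "complex carbohydrate"): 0.34,
    ("fruit", "spicy/flavorful"): 0.21,
    ("fruit", "alcohol"): 0.18,
    ("fruit", "low-fat dairy"): 0.32,
    ("refined carbohydrate", "sweet"): 0.67,
    ("refined carbohydrate", "salty"): 0.55,
    ("refined carbohydrate", "healthy fat"): -0.002,
    ("refined carbohydrate", "saturated fat"): 0.55,
    ("refined carbohydrate", "vegetable"): 0.003,
    ("refined carbohydrate", "high-fat protein"): 0.28,
    ("refined carbohydrate", "complex carbohydrate"): 0.048,
    ("refined carbohydrate", "spicy/flavorful"): 0.036,
    ("refined carbohydrate", "alcohol"): 0.10,
    ("refined carbohydrate", "low-fat dairy"): -0.004,
    ("sweet", "salty"): 0.467,
    ("sweet", "healthy fat"): 0.041,
    ("sweet", "saturated fat"): 0.590,
    ("sweet", "vegetable"): -0.144,
    ("sweet", "high-fat protein"): 0.342,
    ("sweet", "complex carbohydrate"): -0.065,
    ("sweet", "spicy/flavorful"): 0.067,
    ("sweet", "alcohol"): 0.097,
    ("sweet", "low-fat dairy"): 0.006,
    ("salty", "healthy fat"): 0.245,
    ("salty", "saturated fat"): 0.369,
    ("salty", "vegetable"): -0.063,
    ("salty", "high-fat protein"): 0.664,
    ("salty", "complex carbohydrate"): -0.066,
    ("salty", "spicy/flavorful"): 0.133,
    ("salty", "alcohol"): 0.021,
    ("salty", "low-fat dairy"): 0.0015,
    ("healthy fat", "saturated fat"): 0.133,
    ("healthy fat", "vegetable"): 0.276,
    ("healthy fat", "high-fat protein"): 0.326,
    ("healthy fat", "complex carbohydrate"): 0.164,
    ("healthy fat", "spicy/flavorful"): 0.309,
    ("healthy fat", "alcohol"): 0.124,
    ("healthy fat", "low-fat dairy"): 0.213,
    ("saturated fat", "vegetable"): 0.041,
    ("saturated fat", "high-fat protein"): 0.375,
    ("saturated fat", "complex carbohydrate"): 0.0005,
    ("saturated fat", "spicy/flavorful"): 0.168,
    ("saturated fat", "alcohol"): 0.135,
    ("saturated fat", "low-fat dairy"): 0.185,
    ("vegetable", "high-fat protein"): -0.148,
    ("vegetable", "complex carbohydrate"): 0.447,
    ("vegetable", "spicy/flavorful"): 0.393,
    ("vegetable", "alcohol"): 0.125,
    ("vegetable", "low-fat dairy"): 0.335,
    ("high-fat protein", "complex carbohydrate"): -0.125,
    ("high-fat protein", "spicy/flavorful"): 0.161,
    ("high-fat protein", "alcohol"): 0.086,
    ("high-fat protein", "low-fat dairy"): -0.057,
    ("complex carbohydrate", "spicy/flavorful"): 0.26,
    ("complex carbohydrate", "alcohol"): 0.165,
    ("complex carbohydrate", "low-fat dairy"): 0.417,
    ("spicy/flavorful", "alcohol"): 0.305,
    ("spicy/flavorful", "low-fat dairy"): 0.392,
    ("alcohol", "low-fat dairy"): 0.223,
}


def group_correlations() -> pd.DataFrame:
    """Symmetrized 12x12 pairwise group correlation matrix (unit diagonal)."""
    names = list(GROUP_ORDER)
    mat = np.eye(len(names))
    idx = {g: i for i, g in enumerate(names)}
    for (a, b), r in _CORR_UPPER.items():
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = r
    return pd.DataFrame(mat, index=names, columns=names)


#: Internal-consistency targets per food group (Cronbach alpha).
GROUP_ALPHAS: dict[str, float] = {
    "high-fat protein": 0.79, "refined carbohydrate": 0.742, "sweet": 0.723,
    "healthy fat": 0.716, "fruit": 0.713, "alcohol": 0.689,
    "vegetable": 0.687, "spicy/flavorful": 0.663, "saturated fat": 0.654,
    "salty": 0.608, "complex carbohydrate": 0.509, "low-fat dairy": 0.435,
}

#: Simulation targets for the non-food experience scales (mean, SD, alpha).
#: Pleasant experiences are the most liked block of the instrument and
#: unpleasant experiences the least liked; values chosen to respect that
#: ordering relative to the food-group means above.
EXPERIENCE_TARGETS: dict[str, tuple[float, float, float]] = {
    "pleasant": (68.0, 18.0, 0.70),
    "unpleasant": (-55.0, 22.0, 0.65),
}

# --------------------------------------------------------------------------
# Index weights and scoring standards
# --------------------------------------------------------------------------

#: Guideline-based weights of the theoretical diet quality index
#: (positive = encouraged food group, negative = food group to limit).
THEORETICAL_WEIGHTS: dict[str, int] = {
    "sweet": -3,
    "fruit": 2,
    "vegetable": 3,
    "refined carbohydrate": -1,
    "healthy fat": 3,
    "spicy/flavorful": 2,
    "low-fat protein": 3,
    "high-fat protein": -3,
    "salty": -2,
    "complex carbohydrate": 2,
}

#: Published 0-100 scoring standard of the hybrid index: component ->
#: (maximum points, "adequacy" | "moderation").  Adequacy components award
#: maximum points at liking +100; moderation components at liking -100.
#: Maximum points sum to exactly 100.
SCORING_STANDARD: dict[str, tuple[int, str]] = {
    "vegetable": (18, "adequacy"),
    "alcohol": (3, "adequacy"),
    "fruit": (2, "adequacy"),
    "sweet+saturated fat+refined carbohydrate": (52, "moderation"),
    "complex carbohydrate": (15, "moderation"),
    "spicy/flavorful": (4, "moderation"),
    "low-fat dairy": (3, "moderation"),
    "salty+high-fat protein": (2, "moderation"),
    "healthy fat": (1, "moderation"),
}

# --------------------------------------------------------------------------
# Clinical abnormality cut-offs
# --------------------------------------------------------------------------

#: Normal ranges for the cardiometabolic factors.  A value outside its range
#: counts as one abnormality; HDL and waist-to-hip ratio use sex-specific
#:  cut-offs, and insulin resistance is judged on the computed HOMA-IR value.
ABNORMALITY_CUTOFFS = {
    "bmi": ("<", 30.0),                   # kg/m^2
    "sbp": ("<", 130.0),                  # mmHg (blood pressure factor)
    "dbp": ("<", 85.0),                   # mmHg (blood pressure factor)
    "glucose": ("<", 100.0),              # mg/dL fasting
    "insulin": ("<", 17.0),               # mIU/L fasting
    "total_cholesterol": ("<", 200.0),    # mg/dL
    "ldl": ("<", 100.0),                  # mg/dL
    "triglycerides": ("<", 150.0),        # mg/dL
    "hdl": {"male": (">", 40.0), "female": (">", 50.0)},   # mg/dL
    "whr": {"male": ("<", 1.0), "female": ("<", 0.85)},    # ratio
    "homa_ir": ("<", 2.0),
}
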