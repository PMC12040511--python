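"""Calf-muscle anatomy constants shared across the package.

Six muscles / muscle groups are delineated bilaterally on a single axial
calf slice: tibialis anterior (TA), peroneus longus (PL), lateral and
medial gastrocnemius (LG, MG), soleus (SOL), and the deep posterior
tibial group (PT).  Label codes 1-6 are the right side, 7-12 the left,
0 is background.
"""

from __future__ import annotations

MUSCLES = ("TA", "PL", "LG", "MG", "SOL", "PT")
SIDES = ("R", "L")

MUSCLE_FULL_NAMES = {
    "TA": "tibialis anterior",
    "PL": "peroneus longus",
    "LG": "lateral gastrocnemius",
    "MG": "medial gastrocnemius",
    "SOL": "soleus",
    "PT": "posterior tibial group",
}

#: label code -> (side, muscle); right leg 1-6, left leg 7-12
LABELS = {i + 1 + 6 * s: (SIDES[s], m)
          for s in range(2) for i, m in enumerate(MUSCLES)}
LABEL_OF = {v: k for k, v in LABELS.items()}

#: per-side fraction of total (both-leg) calf cross-sectional area;
#: soleus is by far the largest muscle on an axial calf slice.
CSA_FRACTION = {"TA": 0.08, "PL": 0.05, "LG": 0.04, "MG": 0.08,
                "SOL": 0.20, "PT": 0.05}
assert abs(sum(CSA_FRACTION.values()) - 0.5) < 1e-12

#: relative involvement on a log-odds fat-fraction scale. Peroneus longus
#: is the most affected calf muscle in CMT1A, followed by tibialis
#: anterior and medial gastrocnemius; soleus is the least affected.
INVOLVEMENT_SHIFT = {"TA": 0.30, "PL": 0.55, "LG": 0.00, "MG": 0.30,
                     "SOL": -0.70, "PT": -0.25}


def muscle_column(side: str, muscle: str, quantity: str) -> str:
    """Canonical wide-table column name, e.g. ``ff_R_TA``."""
    return f"{quantity}_{side}_{muscle}"


def all_muscle_columns(quantity: str) -> list[str]:
    return [muscle_column(s, m, quantity) for s in SIDES for m in MUSCLES]
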