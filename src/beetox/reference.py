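"""Published reference values for the three-species sulfoxaflor study.

These are the printed LD50 summaries (point estimates and 95% confidence
limits, per bee and per gram of body weight) of the acute oral study of
sulfoxaflor alone and combined with fluxapyroxad in the honey bee
(*Apis mellifera*), the buff-tailed bumblebee (*Bombus terrestris*) and the
red mason bee (*Osmia bicornis*), together with the synergism-ratio and
MDR/toxic-unit summaries derived from them.  They serve as fixed inputs
for the desk-scale arithmetic of the downstream synergism metrics (the raw
per-bee mortality data are not redistributed here) and as reference points
for cross-checking analyses of comparable assays.

Honey-bee LD50s at 48-96 h are absent because the probit dose-response at
the tested doses was not significant at those times.
"""

from __future__ import annotations

import pandas as pd

FLU_LD50_UG = 110.9  # acute oral LD50 of fluxapyroxad, honey bee, ug/bee
FLU_DOSE_UG = 1.2  # fungicide co-exposure dose, ug/bee

# species, treatment, time_h, per-bee (point, lo, hi), per-g (point, lo, hi)
_LD50_ROWS = [
    ("honeybee", "SUL", 3, 145.43, 109.07, 202.21, 1788.80, 1341.60, 2487.19),
    ("honeybee", "SUL_FLU", 3, 175.72, 130.87, 251.45, 2161.43, 1609.70, 3092.91),
    ("honeybee", "SUL", 24, 55.38, 26.34, 111.46, 681.23, 324.03, 1370.99),
    ("honeybee", "SUL_FLU", 24, 33.16, 15.18, 64.28, 407.82, 186.68, 790.67),
    ("bumblebee", "SUL", 3, 172.95, 131.10, 216.09, 657.10, 498.10, 821.00),
    ("bumblebee", "SUL_FLU", 3, 160.19, 125.95, 199.02, 608.61, 478.55, 756.16),
    ("bumblebee", "SUL", 24, 83.51, 68.69, 98.21, 317.28, 260.97, 373.15),
    ("bumblebee", "SUL_FLU", 24, 79.87, 63.88, 94.87, 303.44, 242.72, 360.45),
    ("bumblebee", "SUL", 48, 83.51, 68.69, 98.21, 317.28, 260.97, 373.15),
    ("bumblebee", "SUL_FLU", 48, 79.87, 63.88, 94.87, 303.44, 242.72, 360.45),
    ("bumblebee", "SUL", 72, 83.51, 68.69, 98.21, 317.28, 260.97, 373.15),
    ("bumblebee", "SUL_FLU", 72, 79.87, 63.88, 94.87, 303.44, 242.72, 360.45),
    ("bumblebee", "SUL", 96, 83.51, 68.69, 98.21, 317.28, 260.97, 373.15),
    ("bumblebee", "SUL_FLU", 96, 79.87, 63.88, 94.87, 303.44, 242.72, 360.45),
    ("osmia", "SUL", 3, 81.21, 66.80, 102.48, 885.65, 728.51, 1117.52),
    ("osmia", "SUL_FLU", 3, 59.65, 45.33, 75.15, 650.51, 494.28, 819.49),
    ("osmia", "SUL", 24, 13.51, 10.41, 16.69, 147.28, 113.55, 182.00),
    ("osmia", "SUL_FLU", 24, 9.60, 7.75, 11.54, 104.73, 84.46, 125.87),
    ("osmia", "SUL", 48, 9.06, 6.80, 11.19, 98.76, 74.20, 122.04),
    ("osmia", "SUL_FLU", 48, 8.08, 5.92, 10.08, 88.12, 64.59, 109.94),
    ("osmia", "SUL", 72, 7.19, 4.12, 9.73, 78.40, 44.90, 106.15),
    ("osmia", "SUL_FLU", 72, 6.75, 3.60, 9.43, 73.60, 39.23, 102.82),
    ("osmia", "SUL", 96, 5.90, 1.97, 9.28, 64.35, 21.49, 101.22),
    ("osmia", "SUL_FLU", 96, 5.85, 2.01, 9.10, 63.83, 21.97, 99.19),
]

#: Published synergism ratios (alone / mixture) per (species, time_h).
PUBLISHED_SR = {
    ("honeybee", 3): 0.83,
    ("honeybee", 24): 1.67,
    ("bumblebee", 3): 1.08,
    ("bumblebee", 24): 1.05,
    ("bumblebee", 48): 1.05,
    ("bumblebee", 72): 1.05,
    ("bumblebee", 96): 1.05,
    ("osmia", 3): 1.36,
    ("osmia", 24): 1.41,
    ("osmia", 48): 1.12,
    ("osmia", 72): 1.07,
    ("osmia", 96): 1.01,
}

#: Published (MDR, TU_SUL, TU_total) per (species, time_h), 2 d.p.
PUBLISHED_MDR = {
    ("honeybee", 3): (0.82, 1.21, 1.22),
    ("honeybee", 24): (1.64, 0.60, 0.61),
    ("bumblebee", 3): (1.07, 0.93, 0.94),
    ("bumblebee", 24): (1.03, 0.96, 0.97),
    ("bumblebee", 48): (1.03, 0.96, 0.97),
    ("bumblebee", 72): (1.03, 0.96, 0.97),
    ("bumblebee", 96): (1.03, 0.96, 0.97),
    ("osmia", 3): (1.34, 0.73, 0.75),
    ("osmia", 24): (1.39, 0.71, 0.72),
    ("osmia", 48): (1.11, 0.89, 0.90),
    ("osmia", 72): (1.05, 0.94, 0.95),
    ("osmia", 96): (1.00, 0.99, 1.00),
}


def published_ld50_frame() -> pd.DataFrame:
    """Published LD50 table in the same layout as :func:`beetox.ld50_frame`."""
    rows = [
        {
            "species": sp,
            "treatment": tr,
            "time_h": float(t),
            "determinable": True,
            "ld50_ng_per_bee": bee,
            "ci_low": lo,
            "ci_high": hi,
            "ld50_ng_per_g": g,
            "ci_low_g": glo,
            "ci_high_g": ghi,
        }
        for sp, tr, t, bee, lo, hi, g, glo, ghi in _LD50_ROWS
    ]
    return pd.DataFrame(rows)
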