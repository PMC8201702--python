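"""Reference trait table for the divergent RFI selection design.

The 24 production, carcass-composition and meat-quality traits of the
experiment, with their narrow-sense heritabilities and the realized
between-line genetic differences at generation 9 (in genetic standard
deviations of each trait).  The selected trait is residual feed intake
(RFI); the two lines select for high (HRFI) and low (LRFI) RFI.

Genetic correlations of each trait to RFI are not part of the design
table; the simulator defaults infer them from the correlated responses
(difference in sigma_g divided by the RFI response of 3.84 sigma_g),
which is the expectation under a single round-about selection model.
"""

from __future__ import annotations

import pandas as pd

SELECTED_TRAIT = "RFI"

# trait -> (h2, G9 between-line genetic difference in sigma_g)
_TRAIT_TABLE = {
    "DFI": (0.41, 2.11),
    "ADG": (0.50, 0.15),
    "FCR": (0.42, 2.46),
    "RFI": (0.13, 3.84),
    "carcBFT": (0.40, 0.037),
    "a_GM": (0.29, 0.38),
    "a_GS": (0.26, 0.12),
    "b_GM": (0.24, 0.09),
    "b_GS": (0.32, 1.14),
    "L_GM": (0.20, 0.38),
    "L_GS": (0.33, 2.12),
    "pH24h_AD": (0.41, 1.39),
    "pH24h_GS": (0.39, 1.98),
    "pH24h_LM": (0.32, 1.45),
    "pH24h_SM": (0.38, 1.74),
    "WHC": (0.04, 0.68),
    "MQI": (0.33, 1.92),
    "LMCcalc": (0.59, 1.31),
    "DP": (0.36, 0.93),
    "Belly_W": (0.28, 1.90),
    "BF_W": (0.43, 0.92),
    "Ham_W": (0.51, 0.97),
    "Loin_W": (0.54, 1.69),
    "Shoulder_W": (0.38, 1.11),
}

TRAIT_NAMES: tuple[str, ...] = tuple(_TRAIT_TABLE)

H2_BY_TRAIT: dict[str, float] = {t: v[0] for t, v in _TRAIT_TABLE.items()}

G9_DIFF_SIGMA_G: dict[str, float] = {t: v[1] for t, v in _TRAIT_TABLE.items()}

#: Default genetic correlation to the selected trait, inferred from the
#: correlated responses (r ~ response_i / response_RFI).
DEFAULT_CORR_TO_SELECTED: dict[str, float] = {
    t: round(v[1] / _TRAIT_TABLE[SELECTED_TRAIT][1], 3) for t, v in _TRAIT_TABLE.items()
}


def trait_table() -> pd.DataFrame:
    """Return the design trait table as a DataFrame."""
    return pd.DataFrame(
        {
            "trait": TRAIT_NAMES,
            "h2": [H2_BY_TRAIT[t] for t in TRAIT_NAMES],
            "g9_diff_sigma_g": [G9_DIFF_SIGMA_G[t] for t in TRAIT_NAMES],
            "corr_to_selected": [DEFAULT_CORR_TO_SELECTED[t] for t in TRAIT_NAMES],
        }
    )
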