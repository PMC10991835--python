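"""Published grapevine sieve-element geometry used as reference inputs.

Literature summary statistics (mean ± SD) for pedicel sieve elements of
four wine-grape cultivars, plus the classic *Vitis vinifera* stem
sieve-element characterization used as the long-distance-pathway
comparison.  Lengths and radii in µm; total resistances in Pa·s·m⁻³.
These numbers are measurement summaries, shipped so that resistance
partitioning and the stem-versus-pedicel length comparison can be
recomputed without access to raw micrographs.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["pedicel_sieve_table", "stem_sieve_row", "SAP_VISCOSITY_PA_S"]

SAP_VISCOSITY_PA_S = 2e-3

_PEDICEL_ROWS = [
    # cultivar, color, climate, r, r_sd, l, l_sd, rp, rp_sd, lp, lp_sd, n_pores, np_sd,
    # pct_lumen, pct_plate, r_se_total
    ("Syrah", "red", "hot", 2.87, 0.41, 54.2, 13.2, 0.22, 0.18, 0.37, 0.22, 23.6, 8.38,
     34.4, 65.6, 1.21e16),
    ("Barbera", "red", "warm", 3.72, 0.86, 60.6, 13.3, 0.25, 0.09, 0.36, 0.09, 22.2, 4.92,
     33.7, 66.3, 1.45e16),
    ("Fiano", "white", "hot", 3.08, 0.53, 44.6, 13.2, 0.22, 0.07, 0.25, 0.07, 24.4, 6.67,
     11.2, 88.8, 1.95e16),
    ("Verdelho", "white", "hot", 3.27, 0.85, 54.9, 13.3, 0.19, 0.19, 0.26, 0.04, 25.4, 9.63,
     13.0, 87.0, 2.86e16),
]

_COLUMNS = [
    "cultivar", "color", "climate", "r_um", "r_sd_um", "l_um", "l_sd_um",
    "rp_mean_um", "rp_sd_um", "lp_um", "lp_sd_um", "n_pores", "n_pores_sd",
    "pct_lumen", "pct_plate", "r_se_total",
]


def pedicel_sieve_table() -> pd.DataFrame:
    """Pedicel sieve-element geometry summaries for the four measured cultivars."""
    return pd.DataFrame(_PEDICEL_ROWS, columns=_COLUMNS)


def stem_sieve_row() -> pd.Series:
    """Stem sieve-element geometry of *V. vinifera* from the literature."""
    return pd.Series(
        {
            "r_um": 18.0, "r_sd_um": 4.0,
            "l_um": 500.0, "l_sd_um": 100.0,
            "rp_mean_um": 0.7, "rp_sd_um": 0.23,
            "lp_um": 3.5,
            "n_pores": 661.0, "n_pores_sd": 64.0,
            "pct_lumen": 49.5, "pct_plate": 50.5,
            "r_se_total": 4.8e13,
        }
    )
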