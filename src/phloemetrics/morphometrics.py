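"""Vascular morphometrics from traced tissue-area tables.

Input rows are cross-sections of pedicels, petioles or midveins with
traced phloem, xylem and whole-organ areas (µm²).  Tracing conventions
recorded in the data dictionary: vascular rays more than 4 cell layers
thick are excluded from the tissue areas, and sieve-element areas
include the cell wall.  Area tables are taken as ground truth; no image
processing happens here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ORGANS = ("pedicel", "petiole", "midvein")

__all__ = [
    "ORGANS",
    "phloem_fraction",
    "xylem_phloem_ratio",
    "cultivar_organ_means",
    "group_contrast",
    "validate_sections",
]


class MorphometryError(ValueError):
    pass


def validate_sections(sections: pd.DataFrame) -> pd.DataFrame:
    """Validate an anatomy table (cultivar, vine, organ, areas in µm²)."""
    required = {"cultivar", "vine", "organ", "phloem_area_um2", "xylem_area_um2",
                "total_area_um2"}
    missing = required - set(sections.columns)
    if missing:
        raise MorphometryError(f"anatomy table missing columns: {sorted(missing)}")
    bad_organ = set(sections["organ"]) - set(ORGANS)
    if bad_organ:
        raise MorphometryError(f"unknown organ labels: {sorted(bad_organ)}")
    areas = sections[["phloem_area_um2", "xylem_area_um2", "total_area_um2"]]
    if (areas < 0).any().any():
        raise MorphometryError("negative tissue areas")
    vascular = sections["phloem_area_um2"] + sections["xylem_area_um2"]
    if (vascular > sections["total_area_um2"] * (1 + 1e-9)).any():
        raise MorphometryError("phloem + xylem area exceeds total organ area")
    return sections


def phloem_fraction(phloem_area, total_area):
    """Phloem share of the whole-organ cross-section, in [0, 1]."""
    phloem = np.asarray(phloem_area, dtype=float)
    total = np.asarray(total_area, dtype=float)
    if np.any(total <= 0):
        raise MorphometryError("total organ area must be > 0")
    return phloem / total if phloem.ndim else float(phloem / total)


def xylem_phloem_ratio(xylem_area, phloem_area):
    """Xylem-to-phloem area ratio; > 1 means a xylem-dominated section."""
    xylem = np.asarray(xylem_area, dtype=float)
    phloem = np.asarray(phloem_area, dtype=float)
    if np.any(phloem <= 0):
        raise MorphometryError("phloem area must be > 0 for the ratio")
    return xylem / phloem if xylem.ndim else float(xylem / phloem)


def cultivar_organ_means(sections: pd.DataFrame, min_n: int = 2) -> pd.DataFrame:
    """Mean areas per (cultivar, organ) stratum with replicate counts.

    Strata with fewer than ``min_n`` sections are flagged (``low_n``),
    not dropped.
    """
    sections = validate_sections(sections)
    if sections.empty:
        raise MorphometryError("empty anatomy table")
    grouped = (
        sections.groupby(["cultivar", "organ"], sort=True)
        .agg(
            phloem_area_um2=("phloem_area_um2", "mean"),
            xylem_area_um2=("xylem_area_um2", "mean"),
            total_area_um2=("total_area_um2", "mean"),
            n=("phloem_area_um2", "size"),
        )
        .reset_index()
    )
    grouped["low_n"] = grouped["n"] < min_n
    return grouped


def group_contrast(
    table: pd.DataFrame,
    value_col: str,
    group_col: str,
    numerator: str,
    denominator: str,
) -> float:
    """Percent difference between two group means: 100·(mean_A − mean_B)/mean_B.

    ``numerator`` is group A, ``denominator`` group B (the baseline — for
    climate contrasts the hotter group).
    """
    for label in (numerator, denominator):
        if label not in set(table[group_col]):
            raise MorphometryError(f"group {label!r} absent from {group_col!r}")
    mean_a = table.loc[table[group_col] == numerator, value_col].mean()
    mean_b = table.loc[table[group_col] == denominator, value_col].mean()
    if mean_b == 0:
        raise MorphometryError("baseline group mean is zero")
    return 100.0 * (mean_a - mean_b) / mean_b
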