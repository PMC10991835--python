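"""Sieve-element hydraulic resistance and sieve-plate porosity.

A sieve element is modeled as a cylindrical lumen in series with its
sieve plate, a perforated end wall whose pores act as short channels in
parallel.  Volumetric-flow resistances (Pa·s·m⁻³):

* lumen (Hagen–Poiseuille):      R_lumen = 8·η·l / (π·r⁴)
* one plate pore (Sampson end correction + Poiseuille channel):
                                 R_pore  = 3·η/r_p³ + 8·η·l_p/(π·r_p⁴)
* plate, per-pore mode:          parallel network, R_plate = [Σ 1/R_pore,i]⁻¹
* plate, moment mode (only mean ± SD of pore radii known):
      R_plate = (1/N_p)·( 3η/(r̄_p³·A) + 8η·l_p/(π·r̄_p⁴·B) )
  with A = E[r_p³]/r̄_p³ and B = E[r_p⁴]/r̄_p⁴ absorbing the pore-size
  variation; for normally distributed radii
      E[r³] = µ³ + 3µσ²,   E[r⁴] = µ⁴ + 6µ²σ² + 3σ⁴.
  A = B = 1 when σ = 0, where the two modes coincide exactly.  The
  moment treatment is exact separately in the Sampson-only and
  Poiseuille-only limits; for mixed terms it is an approximation.

All public inputs are in µm (the scale of anatomical measurements);
conversion to meters happens internally.  Default sap viscosity is
2 mPa·s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_ETA_PA_S",
    "SieveElementGeometry",
    "SieveResistance",
    "PlateGeometry",
    "lumen_resistance",
    "pore_resistance",
    "plate_resistance",
    "total_se_resistance",
    "porosity",
    "length_ratio",
    "normal_moment_factors",
]

DEFAULT_ETA_PA_S = 2e-3
_UM = 1e-6


class GeometryError(ValueError):
    pass


@dataclass
class SieveElementGeometry:
    """Sieve-element geometry; lengths in µm, viscosity in Pa·s.

    Pore radii may be given per pore (``pore_radii_um``) or as a summary
    (``rp_mean_um``, ``rp_sd_um``, ``n_pores``).
    """

    r_um: float
    l_um: float
    lp_um: float
    n_pores: int | None = None
    rp_mean_um: float | None = None
    rp_sd_um: float | None = None
    pore_radii_um: np.ndarray | None = None
    eta: float = DEFAULT_ETA_PA_S
    cultivar: str = ""

    def __post_init__(self) -> None:
        for name in ("r_um", "l_um", "lp_um"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        if self.eta <= 0:
            raise GeometryError("viscosity must be > 0")
        if self.pore_radii_um is not None:
            self.pore_radii_um = np.asarray(self.pore_radii_um, dtype=float)
            if self.pore_radii_um.size == 0:
                raise GeometryError("empty pore radius list")
            if np.any(self.pore_radii_um <= 0):
                raise GeometryError("pore radii must be > 0")
            if self.n_pores is None:
                self.n_pores = int(self.pore_radii_um.size)
        else:
            if self.rp_mean_um is None or self.n_pores is None:
                raise GeometryError("need per-pore radii or (rp_mean_um, rp_sd_um, n_pores)")
            if self.rp_mean_um <= 0:
                raise GeometryError("rp_mean_um must be > 0")
            if self.rp_sd_um is not None and self.rp_sd_um < 0:
                raise GeometryError("rp_sd_um must be >= 0")
        if self.n_pores is not None and self.n_pores < 1:
            raise GeometryError("n_pores must be >= 1")


@dataclass(frozen=True)
class SieveResistance:
    """Resistance decomposition of one sieve element (Pa·s·m⁻³)."""

    r_lumen: float
    r_plate: float
    r_total: float
    pct_lumen: float
    pct_plate: float
    a_factor: float
    b_factor: float
    mode: str


@dataclass
class PlateGeometry:
    """A sieve plate face: total area and individual pore areas, in µm²."""

    plate_area_um2: float
    pore_areas_um2: np.ndarray

    def __post_init__(self) -> None:
        self.pore_areas_um2 = np.asarray(self.pore_areas_um2, dtype=float)


def lumen_resistance(r_um: float, l_um: float, eta: float = DEFAULT_ETA_PA_S) -> float:
    """Hagen–Poiseuille lumen resistance 8ηl/(πr⁴), Pa·s·m⁻³."""
    if r_um <= 0 or l_um <= 0 or eta <= 0:
        raise GeometryError("r, l and eta must all be > 0")
    r = r_um * _UM
    l = l_um * _UM
    return 8.0 * eta * l / (np.pi * r**4)


def pore_resistance(rp_um: float, lp_um: float, eta: float = DEFAULT_ETA_PA_S) -> float:
    """Resistance of one plate pore: Sampson orifice term plus channel term."""
    if rp_um <= 0 or lp_um < 0 or eta <= 0:
        raise GeometryError("rp must be > 0, lp >= 0, eta > 0")
    rp = rp_um * _UM
    lp = lp_um * _UM
    return 3.0 * eta / rp**3 + 8.0 * eta * lp / (np.pi * rp**4)


def normal_moment_factors(mean: float, sd: float) -> tuple[float, float]:
    """Pore-size variation factors (A, B) from normal raw moments.

    A = E[r³]/µ³ and B = E[r⁴]/µ⁴ for r ~ Normal(µ, σ); both reduce to 1
    at σ = 0.
    """
    if mean <= 0:
        raise GeometryError("mean pore radius must be > 0")
    if sd < 0:
        raise GeometryError("pore radius SD must be >= 0")
    a = 1.0 + 3.0 * (sd / mean) ** 2
    b = 1.0 + 6.0 * (sd / mean) ** 2 + 3.0 * (sd / mean) ** 4
    return a, b


def plate_resistance(
    geom: SieveElementGeometry, mode: str = "per_pore"
) -> tuple[float, float, float]:
    """Sieve-plate resistance; returns (R_plate, A, B).

    per_pore — exact parallel network over the listed pore radii
    (A and B are reported as the sample moment ratios for reference);
    moment — the mean/SD approximation described in the module docstring.
    """
    eta = geom.eta
    lp = geom.lp_um
    if mode == "per_pore":
        if geom.pore_radii_um is None:
            raise GeometryError("per_pore mode requires pore_radii_um")
        radii = geom.pore_radii_um
        conductance = np.sum(1.0 / np.array([pore_resistance(r, lp, eta) for r in radii]))
        mu = float(radii.mean())
        a = float(np.mean(radii**3)) / mu**3
        b = float(np.mean(radii**4)) / mu**4
        return 1.0 / conductance, a, b
    if mode == "moment":
        if geom.rp_mean_um is None or geom.n_pores is None:
            raise GeometryError("moment mode requires rp_mean_um and n_pores")
        sd = geom.rp_sd_um or 0.0
        a, b = normal_moment_factors(geom.rp_mean_um, sd)
        rp = geom.rp_mean_um * _UM
        lp_m = lp * _UM
        per_plate = (
            3.0 * eta / (rp**3 * a) + 8.0 * eta * lp_m / (np.pi * rp**4 * b)
        ) / geom.n_pores
        return per_plate, a, b
    raise GeometryError(f"unknown plate mode {mode!r}")


def total_se_resistance(geom: SieveElementGeometry, mode: str = "per_pore") -> SieveResistance:
    """Lumen + plate resistance of one sieve element with % partitioning."""
    r_lum = lumen_resistance(geom.r_um, geom.l_um, geom.eta)
    r_plate, a, b = plate_resistance(geom, mode=mode)
    total = r_lum + r_plate
    return SieveResistance(
        r_lumen=r_lum,
        r_plate=r_plate,
        r_total=total,
        pct_lumen=100.0 * r_lum / total,
        pct_plate=100.0 * r_plate / total,
        a_factor=a,
        b_factor=b,
        mode=mode,
    )


def porosity(plate: PlateGeometry) -> float:
    """Open fraction of the sieve plate: Σ pore areas / plate area, in [0, 1]."""
    if plate.plate_area_um2 <= 0:
        raise GeometryError("plate area must be > 0")
    areas = plate.pore_areas_um2
    if areas.size and np.any(areas <= 0):
        raise GeometryError("pore areas must be > 0")
    total = float(np.sum(areas))
    if total > plate.plate_area_um2 * (1 + 1e-12):
        raise GeometryError("pore area exceeds plate area")
    return min(total / plate.plate_area_um2, 1.0)


def length_ratio(stem_l_um: float, pedicel_lengths_um) -> float:
    """Stem sieve-element length over the mean pedicel sieve-element length."""
    lengths = np.asarray(pedicel_lengths_um, dtype=float)
    if lengths.size == 0:
        raise GeometryError("empty pedicel length list")
    mean = float(lengths.mean())
    if mean == 0:
        raise GeometryError("zero mean pedicel length")
    return stem_l_um / mean
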