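"""Seeded synthetic data with the statistical structure of a hot-site
common-garden cultivar panel.

The generator emulates the five input tables the pipeline consumes:
daily weather, a cultivar panel with vascular anatomy and physiology,
Brix sampling trajectories, per-vine anatomy sections, and sieve-element
geometry with per-pore radii.  Defaults are the study conditions: a hot,
dry growing season (study-window daily means ~22.8–24.5 °C, daily maxima
~32.6–34.4 °C), an 18-cultivar panel mixing hot-, warm- and
temperate-climate cultivars 9:7:2, warm-vs-hot phloem-area multipliers
of 2.04 (pedicel), 2.93 (petiole) and 1.04 (midvein), xylem–phloem
correlations of 0.59/0.99/0.93 per organ, Brix noise of 0.5 °Brix, and
pedicel sieve geometry centered on measured grapevine values.

The logistic slope magnitude |b| of each cultivar is linearly coupled to
its pedicel phloem area, with coupling noise matched to the coupling
signal so the panel-level regression of maximum Brix rate on pedicel
phloem area has a population r² ≈ 0.5.  Photosynthesis and midday water
potential are drawn independently of the ripening parameters (a built-in
null effect).

Everything is deterministic given the config seed; each generator
derives its own stream from (seed, stage-id), so stages can be called in
any order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometrics import ORGANS
from .thermal_time import GddSeries

__all__ = [
    "SyntheticConfig",
    "generate_weather",
    "generate_panel",
    "generate_anatomy_sections",
    "generate_brix_observations",
    "generate_sieve_geometry",
    "allocate_groups",
]

_STAGE = {"weather": 1, "panel": 2, "brix": 3, "sieve": 4, "sections": 5}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic panel (see module docstring)."""

    seed: int = 0
    n_cultivars: int = 18
    climate_mix: dict = field(
        default_factory=lambda: {"hot": 9 / 18, "warm": 7 / 18, "temperate": 2 / 18}
    )
    red_fraction: float = 13 / 18
    n_vines: int = 2

    # weather: long-run daily mean + seasonal sinusoid + day-to-day noise
    season_start: str = "2020-07-01"
    season_days: int = 80
    mean_daily_c: float = 22.0
    seasonal_amp_c: float = 2.0
    peak_doy: int = 201  # late July
    diurnal_range_c: float = 19.6
    weather_noise_sd: float = 1.5

    # Brix sampling
    # Brix sampling cadence: field protocols sample at Brix-defined
    # (adaptive) intervals so the sigmoid rise is always tracked; a fixed
    # 4-day grid from 50% veraison to harvest emulates that coverage.
    gdd_start: str = "2020-07-22"
    sampling_dates: tuple = tuple(
        str(d.date()) for d in pd.date_range("2020-07-22", "2020-09-08", freq="4D")
    )
    brix_noise_sd: float = 0.5

    # anatomy (µm²): hot-climate organ means, shared CV, group multipliers
    phloem_hot_mean_um2: dict = field(
        default_factory=lambda: {"pedicel": 1.2e5, "petiole": 1.5e5, "midvein": 8.0e4}
    )
    warm_multiplier: dict = field(
        default_factory=lambda: {"pedicel": 2.04, "petiole": 2.93, "midvein": 1.04}
    )
    temperate_multiplier: dict = field(
        default_factory=lambda: {"pedicel": 1.4, "petiole": 1.8, "midvein": 1.0}
    )
    area_cv: float = 0.3
    xylem_phloem_mean_ratio: dict = field(
        default_factory=lambda: {"pedicel": 3.0, "petiole": 1.5, "midvein": 1.5}
    )
    xylem_phloem_r: dict = field(
        default_factory=lambda: {"pedicel": 0.59, "petiole": 0.99, "midvein": 0.93}
    )
    red_petiole_phloem_multiplier: float = 1.25
    total_organ_mean_um2: dict = field(
        default_factory=lambda: {"pedicel": 1.5e6, "petiole": 2.5e6, "midvein": 1.2e6}
    )
    total_organ_cv: float = 0.2
    section_cv: float = 0.1  # within-cultivar (vine section) noise

    # physiology, independent of ripening rate by construction
    photosynthesis_mean: float = 12.0  # µmol CO2 m⁻² s⁻¹
    photosynthesis_sd: float = 2.0
    water_potential_mean_mpa: float = -1.0
    water_potential_sd_mpa: float = 0.25

    # true ripening parameters; |b| = b_base + coupling*(pedicel area/1e5) + noise
    smin_mean: float = 4.5
    smin_sd: float = 0.8
    smax_mean: float = 24.0
    smax_sd: float = 1.2
    x0_mean_gdd: float = 250.0
    x0_sd_gdd: float = 60.0
    b_base: float = 0.008
    coupling_slope: float = 0.010  # per 1e5 µm² pedicel phloem area
    b_noise_sd: float = 0.008

    # sieve-element geometry (µm), centered on measured pedicel values
    n_elements_per_vine: int = 3
    se_r_mean: float = 3.0
    se_r_sd: float = 0.6
    se_l_mean: float = 54.0
    se_l_sd: float = 13.0
    se_lp_mean: float = 0.30
    se_lp_sd: float = 0.10
    se_np_mean: float = 24.0
    pore_r_mean: float = 0.22
    pore_r_sd: float = 0.10

    def __post_init__(self) -> None:
        total = sum(self.climate_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("climate_mix proportions must sum to 1")
        if self.brix_noise_sd < 0 or self.area_cv < 0:
            raise ValueError("noise levels must be >= 0")
        if any(m <= 0 for m in self.warm_multiplier.values()):
            raise ValueError("group multipliers must be > 0")
        for organ, rho in self.xylem_phloem_r.items():
            if not -1.0 < rho < 1.0:
                raise ValueError(f"infeasible xylem-phloem correlation for {organ}: {rho}")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STAGE[stage]])


def allocate_groups(n: int, mix: dict) -> list[str]:
    """Deterministic largest-remainder allocation of n items to groups.

    Keeps the panel composition fixed for a given n (e.g. 18 → 9 hot,
    7 warm, 2 temperate; 13 → 7/5/1), mirroring a designed panel rather
    than a random draw.
    """
    labels = list(mix)
    quotas = np.array([mix[g] * n for g in labels])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts))
    for i in range(remainder):
        counts[order[i % len(labels)]] += 1
    out = []
    for g, c in zip(labels, counts):
        out.extend([g] * c)
    return out


def _truncated_normal(rng, mean, sd, size, lower=0.0):
    """Normal draws truncated below ``lower`` by resampling."""
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = out <= lower
        if not bad.any():
            return out
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad] if np.ndim(mean) else mean,
                              sd, int(bad.sum()))
    return np.maximum(out, lower + 1e-12)


def generate_weather(config: SyntheticConfig) -> pd.DataFrame:
    """Daily weather table: seasonal sinusoid plus day-to-day noise.

    The long-run mean of the daily mean temperature is
    ``mean_daily_c``; the study window (near the seasonal peak) runs a
    degree or two warmer, landing inside the configured hot-site bands.
    """
    rng = config.rng("weather")
    dates = pd.date_range(config.season_start, periods=config.season_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    tmean = (
        config.mean_daily_c
        + config.seasonal_amp_c * np.cos(2 * np.pi * (doy - config.peak_doy) / 365.25)
        + rng.normal(0.0, config.weather_noise_sd, len(dates))
    )
    half_range = np.maximum(
        config.diurnal_range_c / 2.0 + rng.normal(0.0, config.weather_noise_sd / 2.0, len(dates)),
        1.0,
    )
    return pd.DataFrame(
        {"date": dates, "tmax_c": tmean + half_range, "tmin_c": tmean - half_range}
    )


def generate_panel(config: SyntheticConfig) -> pd.DataFrame:
    """Cultivar panel: climate/color groups, organ areas, physiology, and
    true logistic ripening parameters (one row per cultivar)."""
    rng = config.rng("panel")
    n = config.n_cultivars
    climates = allocate_groups(n, config.climate_mix)
    colors = np.where(rng.random(n) < config.red_fraction, "red", "white")
    panel = pd.DataFrame(
        {
            "cultivar": [f"CV{i + 1:03d}" for i in range(n)],
            "climate": climates,
            "color": colors,
        }
    )

    multiplier = {"hot": {o: 1.0 for o in ORGANS},
                  "warm": config.warm_multiplier,
                  "temperate": config.temperate_multiplier}
    for organ in ORGANS:
        mu_p = np.array(
            [config.phloem_hot_mean_um2[organ] * multiplier[c][organ] for c in climates]
        )
        if organ == "petiole":
            mu_p = mu_p * np.where(colors == "red", config.red_petiole_phloem_multiplier, 1.0)
        rho = config.xylem_phloem_r[organ]
        zp = rng.standard_normal(n)
        zx = rho * zp + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        phloem = np.maximum(mu_p * (1.0 + config.area_cv * zp), mu_p * 0.05)
        mu_x = mu_p * config.xylem_phloem_mean_ratio[organ]
        xylem = np.maximum(mu_x * (1.0 + config.area_cv * zx), mu_x * 0.05)
        total = _truncated_normal(
            rng,
            config.total_organ_mean_um2[organ],
            config.total_organ_cv * config.total_organ_mean_um2[organ],
            n,
        )
        total = np.maximum(total, (phloem + xylem) * 1.1)
        panel[f"phloem_{organ}_um2"] = phloem
        panel[f"xylem_{organ}_um2"] = xylem
        panel[f"total_{organ}_um2"] = total

    panel["photosynthesis"] = rng.normal(
        config.photosynthesis_mean, config.photosynthesis_sd, n
    )
    panel["water_potential_mpa"] = rng.normal(
        config.water_potential_mean_mpa, config.water_potential_sd_mpa, n
    )

    area_scaled = panel["phloem_pedicel_um2"].to_numpy() / 1e5
    b_mag = config.b_base + config.coupling_slope * area_scaled + rng.normal(
        0.0, config.b_noise_sd, n
    )
    panel["true_smin"] = _truncated_normal(rng, config.smin_mean, config.smin_sd, n)
    panel["true_smax"] = _truncated_normal(rng, config.smax_mean, config.smax_sd, n)
    panel["true_b"] = -b_mag
    panel["true_x0"] = _truncated_normal(rng, config.x0_mean_gdd, config.x0_sd_gdd, n)
    panel["seed"] = config.seed
    return panel


def generate_anatomy_sections(panel: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Per-vine traced sections around each cultivar's true organ areas."""
    rng = config.rng("sections")
    rows = []
    for _, cv in panel.iterrows():
        for vine in range(1, config.n_vines + 1):
            for organ in ORGANS:
                phloem = cv[f"phloem_{organ}_um2"] * max(
                    1.0 + rng.normal(0.0, config.section_cv), 0.05
                )
                xylem = cv[f"xylem_{organ}_um2"] * max(
                    1.0 + rng.normal(0.0, config.section_cv), 0.05
                )
                total = max(
                    cv[f"total_{organ}_um2"] * max(1.0 + rng.normal(0.0, config.section_cv), 0.05),
                    (phloem + xylem) * 1.05,
                )
                rows.append(
                    {
                        "cultivar": cv["cultivar"],
                        "vine": f"V{vine}",
                        "organ": organ,
                        "phloem_area_um2": phloem,
                        "xylem_area_um2": xylem,
                        "total_area_um2": total,
                    }
                )
    return pd.DataFrame(rows)


def generate_brix_observations(
    panel: pd.DataFrame, gdd_series: GddSeries, config: SyntheticConfig
) -> pd.DataFrame:
    """Brix samples per cultivar × vine × sampling date on the true curve
    plus Gaussian measurement noise."""
    from .ripening import LogisticFit, logistic_value

    rng = config.rng("brix")
    rows = []
    for _, cv in panel.iterrows():
        fit = LogisticFit(
            smin=cv["true_smin"], smax=cv["true_smax"], b=cv["true_b"], x0=cv["true_x0"],
            rss=0.0, n_obs=0, converged=True,
        )
        for date in config.sampling_dates:
            gdd = gdd_series.gdd_at(date)
            clean = logistic_value(fit, gdd)
            for vine in range(1, config.n_vines + 1):
                brix = clean + rng.normal(0.0, config.brix_noise_sd)
                rows.append(
                    {
                        "cultivar": cv["cultivar"],
                        "vine": f"V{vine}",
                        "date": pd.Timestamp(date),
                        "gdd": gdd,
                        "brix": float(np.clip(brix, 0.0, 40.0)),
                    }
                )
    return pd.DataFrame(rows)


def generate_sieve_geometry(panel: pd.DataFrame, config: SyntheticConfig):
    """Sieve-element geometry tables: per-element summaries and per-pore radii.

    Returns ``(elements, pores)``: element rows carry truncated-normal
    lumen radius, length and plate thickness with a Poisson-dispersed
    pore count; the pore table holds individual pore radii whose
    mean/SD/count summarize back into the element rows.
    """
    rng = config.rng("sieve")
    elem_rows, pore_rows = [], []
    for _, cv in panel.iterrows():
        for vine in range(1, config.n_vines + 1):
            for el in range(1, config.n_elements_per_vine + 1):
                r = float(_truncated_normal(rng, config.se_r_mean, config.se_r_sd, 1)[0])
                l = float(_truncated_normal(rng, config.se_l_mean, config.se_l_sd, 1)[0])
                lp = float(_truncated_normal(rng, config.se_lp_mean, config.se_lp_sd, 1)[0])
                n_p = max(int(rng.poisson(config.se_np_mean)), 1)
                radii = _truncated_normal(
                    rng, config.pore_r_mean, config.pore_r_sd, n_p, lower=0.01
                )
                elem_id = f"E{el}"
                elem_rows.append(
                    {
                        "cultivar": cv["cultivar"],
                        "vine": f"V{vine}",
                        "element_id": elem_id,
                        "r_um": r,
                        "l_um": l,
                        "lp_um": lp,
                        "n_pores": n_p,
                        "rp_mean_um": float(radii.mean()),
                        "rp_sd_um": float(radii.std(ddof=0)),
                    }
                )
                for k, rp in enumerate(radii, start=1):
                    pore_rows.append(
                        {
                            "cultivar": cv["cultivar"],
                            "vine": f"V{vine}",
                            "plate_id": elem_id,
                            "pore_id": k,
                            "rp_um": float(rp),
                        }
                    )
    return pd.DataFrame(elem_rows), pd.DataFrame(pore_rows)
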