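"""End-to-end run: simulate → thermal time → fits → hydraulics → statistics.

Every number in the report comes from the module operations; the
orchestrator only wires tables together and serializes results.  Given
the same config (including the seed) the report is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hydraulics, morphometrics, ripening, trait_stats
from .synthetic import (
    SyntheticConfig,
    generate_anatomy_sections,
    generate_brix_observations,
    generate_panel,
    generate_sieve_geometry,
    generate_weather,
)
from .thermal_time import cumulative_gdd

log = logging.getLogger("phloemetrics")

__all__ = ["load_config", "run_all", "DEFAULT_MODELS"]

# candidate model ledger: phloem anatomy vs physiology predictors for max rate
DEFAULT_MODELS = [
    ("anatomy+physiology", ["phloem_midvein_um2", "phloem_petiole_um2",
                            "phloem_pedicel_um2", "photosynthesis", "water_potential_mpa"]),
    ("phloem all organs", ["phloem_midvein_um2", "phloem_petiole_um2", "phloem_pedicel_um2"]),
    ("petiole+pedicel", ["phloem_petiole_um2", "phloem_pedicel_um2"]),
    ("pedicel", ["phloem_pedicel_um2"]),
    ("petiole", ["phloem_petiole_um2"]),
    ("midvein", ["phloem_midvein_um2"]),
    ("physiology", ["photosynthesis", "water_potential_mpa"]),
    ("photosynthesis", ["photosynthesis"]),
    ("water potential", ["water_potential_mpa"]),
]


def load_config(path=None, seed: int | None = None) -> SyntheticConfig:
    """Build a SyntheticConfig from a YAML/JSON file, overriding the seed."""
    kwargs = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        valid = {f.name for f in dataclasses.fields(SyntheticConfig)}
        unknown = set(loaded) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(loaded)
    if seed is not None:
        kwargs["seed"] = int(seed)
    return SyntheticConfig(**kwargs)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, pd.Timestamp):
        return obj.isoformat()
    return obj


def run_all(
    config: SyntheticConfig,
    out_dir=None,
    fit_options: ripening.FitOptions | None = None,
) -> dict:
    """Run the whole synthetic-panel analysis; optionally write artifacts.

    Returns the report dict; when ``out_dir`` is given, also writes the
    CSV inputs and a ``report.json``.
    """
    fit_options = fit_options or ripening.FitOptions(seed=config.seed)

    log.info("simulating weather and panel (seed=%d)", config.seed)
    weather = generate_weather(config)
    gdd = cumulative_gdd(weather, config.gdd_start)
    panel = generate_panel(config)
    sections = generate_anatomy_sections(panel, config)
    brix = generate_brix_observations(panel, gdd, config)
    elements, pores = generate_sieve_geometry(panel, config)

    log.info("fitting logistic ripening curves for %d cultivars", len(panel))
    fits = ripening.fit_cultivars(brix, fit_options)
    rejected = fits.loc[~fits["accepted"], ["cultivar", "rejection_reason"]]

    # hydraulics: moment-mode resistance on per-cultivar mean geometry
    resistance_rows = []
    for cultivar, grp in elements.groupby("cultivar", sort=True):
        geom = hydraulics.SieveElementGeometry(
            r_um=grp["r_um"].mean(),
            l_um=grp["l_um"].mean(),
            lp_um=grp["lp_um"].mean(),
            n_pores=max(int(round(grp["n_pores"].mean())), 1),
            rp_mean_um=grp["rp_mean_um"].mean(),
            rp_sd_um=grp["rp_sd_um"].mean(),
        )
        res = hydraulics.total_se_resistance(geom, mode="moment")
        resistance_rows.append(
            {
                "cultivar": cultivar,
                "r_lumen": res.r_lumen,
                "r_plate": res.r_plate,
                "r_total": res.r_total,
                "pct_lumen": res.pct_lumen,
                "pct_plate": res.pct_plate,
                "a_factor": res.a_factor,
                "b_factor": res.b_factor,
            }
        )
    resistance = pd.DataFrame(resistance_rows)

    # trait table: accepted fits joined to cultivar-level anatomy means
    organ_means = morphometrics.cultivar_organ_means(sections, min_n=config.n_vines)
    wide = organ_means.pivot(index="cultivar", columns="organ",
                             values=["phloem_area_um2", "xylem_area_um2"])
    wide.columns = [f"{tissue.split('_')[0]}_{organ}_um2" for tissue, organ in wide.columns]
    traits = (
        fits.loc[fits["accepted"], ["cultivar", "max_rate", "transition_width"]]
        .merge(wide.reset_index(), on="cultivar")
        .merge(
            panel[["cultivar", "climate", "color", "photosynthesis", "water_potential_mpa"]],
            on="cultivar",
        )
    )

    report: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "gdd_total": gdd.total,
        "fits": fits.to_dict(orient="records"),
        "rejected": rejected.to_dict(orient="records"),
        "resistance": resistance.to_dict(orient="records"),
        "warnings": [],
    }
    if len(rejected):
        report["warnings"].append(
            f"{len(rejected)} cultivar(s) rejected: "
            + ", ".join(f"{r.cultivar} ({r.rejection_reason})" for r in rejected.itertuples())
        )

    # model ledger (needs enough accepted cultivars for the largest model)
    max_k = max(len(p) for _, p in DEFAULT_MODELS)
    if len(traits) >= max_k + 4:
        ledger = trait_stats.rank_models(DEFAULT_MODELS, traits, "max_rate")
        report["model_ledger"] = ledger.to_dict(orient="records")
    else:
        report["model_ledger"] = []
        report["warnings"].append(
            f"only {len(traits)} accepted cultivars; model ledger skipped"
        )

    # climate/color ANOVAs on section-level areas, temperate excluded
    anova_sections = sections.merge(panel[["cultivar", "climate", "color"]], on="cultivar")
    anova_sections = anova_sections[anova_sections["climate"] != "temperate"]
    anovas = {}
    for organ in morphometrics.ORGANS:
        sub = anova_sections[anova_sections["organ"] == organ]
        entry = {}
        for tissue in ("phloem_area_um2", "xylem_area_um2"):
            try:
                res = trait_stats.two_way_anova(sub, tissue, "climate", "color")
                entry[tissue] = {
                    term: {"F": float(res.table.loc[term, "F"]),
                           "p": float(res.table.loc[term, "PR(>F)"])}
                    for term in (set(res.table.index) - {"Residual"})
                }
                tuk = trait_stats.tukey_hsd(sub[tissue], sub["climate"])
                entry[tissue]["tukey_climate"] = tuk.to_dict(orient="records")
                entry[tissue]["letters"] = tuk.attrs["letters"]
            except trait_stats.StatsError as exc:
                entry[tissue] = {"error": str(exc)}
                report["warnings"].append(f"ANOVA skipped for {organ}/{tissue}: {exc}")
        anovas[organ] = entry
    report["anova"] = anovas

    # group contrasts (warm vs hot) on cultivar-level phloem means
    contrasts = {}
    means_with_climate = organ_means.merge(panel[["cultivar", "climate"]], on="cultivar")
    for organ in morphometrics.ORGANS:
        sub = means_with_climate[means_with_climate["organ"] == organ]
        contrasts[organ] = morphometrics.group_contrast(
            sub, "phloem_area_um2", "climate", "warm", "hot"
        )
    report["warm_vs_hot_phloem_contrast_pct"] = contrasts

    report = _jsonable(report)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        weather.to_csv(out / "weather.csv", index=False)
        panel.to_csv(out / "panel.csv", index=False)
        sections.to_csv(out / "anatomy.csv", index=False)
        brix.to_csv(out / "brix.csv", index=False)
        elements.to_csv(out / "sieve_elements.csv", index=False)
        pores.to_csv(out / "sieve_pores.csv", index=False)
        fits.to_csv(out / "fits.csv", index=False)
        resistance.to_csv(out / "resistance.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        log.info("wrote report to %s", out / "report.json")
    return report
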