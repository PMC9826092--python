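"""End-to-end pipeline driver.

Runs simulate -> occurrence filtering -> ensemble niche models -> exposure /
vulnerability / hazard -> risk ledger -> richness maps on a synthetic world,
writing every stage's tables (CSV) plus a manifest (config hash, seed,
version) under an output directory.  Reruns with the same configuration are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grids import RasterGrid
from .occurrences import (OccurrenceSet, build_calibration_area,
                          prepare_occurrences)
from .risk_engine import (assemble_risk, group_percentages, top_decile,
                          total_loss_species)
from .richness import (overlay_lucc_on_richness, rich_area_reduction,
                       richness_threshold, stack_richness)
from .suitability import (DEFAULT_LEARNER_FAMILIES, EnvelopeLearner,
                          LogisticQuadraticLearner, TreeLearner, model_species)
from .synthetic_world import ScenarioSpec, WorldConfig, make_world
from .vulnerability import npa_change, sensitivity_scores
from .exposure import exposure_record
from .hazard import hazard_record

LEARNER_REGISTRY = {
    "logistic": LogisticQuadraticLearner,
    "tree": TreeLearner,
    "envelope": EnvelopeLearner,
}


@dataclass
class RunConfig:
    """All pipeline tunables with their protocol defaults."""

    world: WorldConfig = field(default_factory=WorldConfig)
    thin_km: float = 10.0
    n_pseudo_absences: int = 1000
    n_replicates: int = 10
    learner_families: tuple[str, ...] = ("logistic", "tree", "envelope")
    r_max: float = 0.8
    include_p_change: bool = True
    richness_absolute: int = 75
    write_rasters: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["world"]["scenarios"] = [dataclasses.asdict(s)
                                   for s in self.world.scenarios]
        d["learner_families"] = list(self.learner_families)
        d["world"]["extent"] = list(self.world.extent)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        w = dict(d.pop("world", {}))
        if "scenarios" in w:
            w["scenarios"] = tuple(ScenarioSpec(**s) for s in w["scenarios"])
        if "extent" in w:
            w["extent"] = tuple(w["extent"])
        d["learner_families"] = tuple(d.get("learner_families",
                                            cls.learner_families))
        return cls(world=WorldConfig(**w), **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    config: RunConfig
    world: object
    filtered_occurrences: dict[str, np.ndarray]
    excluded_species: list[str]
    suitability: dict[str, dict[str, object]]   # species -> scenario key -> map
    exposure: pd.DataFrame
    npa: pd.DataFrame
    hazard: pd.DataFrame
    sensitivity: pd.Series
    ledgers: dict[str, pd.DataFrame]            # principle -> ledger
    total_loss: list[str]
    group_summaries: pd.DataFrame
    richness_summary: pd.DataFrame


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None
                 ) -> PipelineResult:
    world = make_world(config.world)
    grid = world.grid
    current = config.world.current_scenario
    futures = config.world.future_scenarios
    families = tuple(LEARNER_REGISTRY[n] for n in config.learner_families) \
        or DEFAULT_LEARNER_FAMILIES

    # --- occurrence filtering ------------------------------------------------
    filtered: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for sp in world.species:
        occ = prepare_occurrences(
            OccurrenceSet(sp.species_id, sp.occurrences),
            min_km=config.thin_km)
        if occ is None:
            excluded.append(sp.species_id)
        else:
            filtered[sp.species_id] = occ.points

    # --- niche models per species -------------------------------------------
    seed_root = np.random.SeedSequence([config.world.seed, 32452843])
    seeds = dict(zip(sorted(filtered), seed_root.spawn(len(filtered))))
    suitability: dict[str, dict[str, object]] = {}
    metrics_rows = []
    for sid in sorted(filtered):
        pts = filtered[sid]
        try:
            cal = build_calibration_area(sid, pts, world.landscape.ecoregions)
            maps = model_species(
                sid, pts, cal, world.landscape.climate,
                list(config.world.scenarios), current,
                n_pseudo_absences=config.n_pseudo_absences,
                n_replicates=config.n_replicates,
                learner_families=families, r_max=config.r_max,
                rng=np.random.default_rng(seeds[sid]))
        except ValueError as exc:
            raise ValueError(f"suitability stage failed for {sid}: {exc}") \
                from exc
        suitability[sid] = maps
        for rec in maps[current.key].metrics:
            metrics_rows.append({"species_id": sid, **rec})

    # --- exposure, NPA, hazard -----------------------------------------------
    exp_rows, npa_rows, haz_rows = [], [], []
    cur_t = world.landscape.climate[current.key].layer("bio1")
    cur_p = world.landscape.climate[current.key].layer("bio3")
    for sid, maps in suitability.items():
        cur_bin = maps[current.key].binary
        for scen in futures:
            fut_bin = maps[scen.key].binary
            lucc = world.lucc[scen.period]
            for mode in ("limited_full", "none"):
                exp_rows.append(dataclasses.asdict(exposure_record(
                    sid, scen.key, cur_bin, fut_bin, lucc, dispersal=mode)))
            rec = exp_rows[-2]  # limited_full record for this scenario
            if not rec["total_loss"]:
                npa_rows.append(dataclasses.asdict(npa_change(
                    sid, scen.key, cur_bin, fut_bin, world.landscape.pa_mask)))
                fut_t = world.landscape.climate[scen.key].layer("bio1")
                fut_p = world.landscape.climate[scen.key].layer("bio3")
                haz_rows.append(dataclasses.asdict(hazard_record(
                    sid, scen.key, cur_t, fut_t, cur_p, fut_p, world.fires,
                    world.hurricane_category, world.hurricane_frequency,
                    fut_bin)))
    exposure = pd.DataFrame(exp_rows)
    npa = pd.DataFrame(npa_rows)
    hazard = pd.DataFrame(haz_rows)

    # --- vulnerability and risk ----------------------------------------------
    traits = world.traits_table()
    traits = traits[traits["species_id"].isin(suitability)]
    sensitivity = sensitivity_scores(traits)
    ledgers = {}
    for principle in ("WP", "WoP"):
        led = assemble_risk(sensitivity, npa, exposure, hazard, principle,
                            include_p_change=config.include_p_change)
        ledgers[principle] = top_decile(led)
    loss = total_loss_species(exposure)
    ledger_all = pd.concat(ledgers.values(), ignore_index=True)
    group_frames = [group_percentages(ledger_all, traits, g)
                    for g in ("order", "trophic", "body_size", "locomotion")]
    group_summaries = pd.concat(group_frames, ignore_index=True)

    # --- richness -------------------------------------------------------------
    n_modelled = len(suitability)
    rich_rows = []
    cur_counts = stack_richness([suitability[s][current.key].binary
                                 for s in sorted(suitability)])
    thr = richness_threshold(n_modelled, config.richness_absolute,
                             max_count=int(cur_counts.values.max()))
    cur_lucc = world.lucc["current"]
    cur_masks = {"climate": cur_counts.values > thr}
    for pr in ("WP", "WoP"):
        cur_masks[pr] = overlay_lucc_on_richness(
            cur_counts, cur_lucc, pr).values > thr
    for scen in futures:
        counts = stack_richness([suitability[s][scen.key].binary
                                 for s in sorted(suitability)])
        lucc = world.lucc[scen.period]
        variants = {"climate": counts.values > thr}
        for pr in ("WP", "WoP"):
            variants[pr] = overlay_lucc_on_richness(counts, lucc, pr).values > thr
        for variant, mask in variants.items():
            if cur_masks[variant].sum() == 0:
                continue
            rich_rows.append({
                "scenario": scen.key, "variant": variant,
                "threshold": thr,
                "rich_cells_current": int(cur_masks[variant].sum()),
                "rich_cells_future": int(mask.sum()),
                "reduction_pct": rich_area_reduction(cur_masks[variant], mask),
            })
    richness_summary = pd.DataFrame(rich_rows)

    result = PipelineResult(
        config=config, world=world, filtered_occurrences=filtered,
        excluded_species=excluded, suitability=suitability,
        exposure=exposure, npa=npa, hazard=hazard, sensitivity=sensitivity,
        ledgers=ledgers, total_loss=loss, group_summaries=group_summaries,
        richness_summary=richness_summary)

    if out_dir is not None:
        _write_outputs(result, pd.DataFrame(metrics_rows), Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, metrics: pd.DataFrame,
                   out: Path) -> None:
    from .io import write_ascii_grid, write_geojson, write_occurrences_csv

    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    write_occurrences_csv(out / "occurrences_filtered.csv",
                          result.filtered_occurrences)
    result.world.traits_table().to_csv(out / "traits.csv", index=False)
    metrics.to_csv(out / "model_metrics.csv", index=False)
    result.exposure.to_csv(out / "exposure.csv", index=False)
    result.npa.to_csv(out / "npa.csv", index=False)
    result.hazard.to_csv(out / "hazard.csv", index=False)
    for principle, led in result.ledgers.items():
        led.to_csv(out / f"risk_ledger_{principle}.csv", index=False)
    pd.DataFrame({"species_id": result.total_loss}).to_csv(
        out / "total_loss_species.csv", index=False)
    result.group_summaries.to_csv(out / "group_summaries.csv", index=False)
    result.richness_summary.to_csv(out / "richness_summary.csv", index=False)
    write_geojson(out / "ecoregions.geojson",
                  [(poly, {"ecoregion_id": eid})
                   for eid, poly in result.world.landscape.ecoregions])
    if cfg.write_rasters:
        rdir = out / "rasters"
        rdir.mkdir(exist_ok=True)
        write_ascii_grid(rdir / "pa_mask.asc",
                         RasterGrid(result.world.grid,
                                    result.world.landscape.pa_mask.values
                                    .astype(float)))
        write_ascii_grid(rdir / "fires.asc",
                         RasterGrid(result.world.grid,
                                    result.world.fires.values.astype(float)))
        for period, lucc in result.world.lucc.items():
            write_ascii_grid(rdir / f"lucc_{period}.asc",
                             RasterGrid(result.world.grid,
                                        lucc.values.astype(float)))
        for sid, maps in result.suitability.items():
            for key, smap in maps.items():
                write_ascii_grid(rdir / f"{sid}_{key}_binary.asc", smap.binary)

    manifest = {
        "version": __version__,
        "seed": cfg.world.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest(),
        "n_species_simulated": cfg.world.n_species,
        "n_species_modelled": len(result.suitability),
        "n_species_excluded": len(result.excluded_species),
        "n_total_loss": len(result.total_loss),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
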