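"""Generate the synthetic study system and write its inputs to disk.

Produces the landscape a real study would assemble from external sources:
climate stacks for the current period and two contrasting futures, land-use
maps with expanding agriculture, fire and hurricane layers, ecoregion
polygons, a protected-area mask, species occurrence records and the trait
table.  Everything downstream is reproducible from these files plus the
seed recorded in the config.

Usage: python analysis/01_simulate_world.py [--seed 0] [--out results/world]
"""

import argparse
from pathlib import Path

from riskdex.grids import RasterGrid
from riskdex.io import write_ascii_grid, write_geojson, write_occurrences_csv
from riskdex.pipeline import RunConfig
from riskdex.synthetic_world import WorldConfig, make_world


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/world"))
    args = parser.parse_args()

    cfg = RunConfig(world=WorldConfig(seed=args.seed))
    world = make_world(cfg.world)
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    write_occurrences_csv(out / "occurrences.csv",
                          {sp.species_id: sp.occurrences
                           for sp in world.species})
    world.traits_table().to_csv(out / "traits.csv", index=False)
    write_geojson(out / "ecoregions.geojson",
                  [(poly, {"ecoregion_id": eid})
                   for eid, poly in world.landscape.ecoregions])
    for key, stack in world.landscape.climate.items():
        for var in ("bio1", "bio3"):
            write_ascii_grid(out / f"climate_{key}_{var}.asc",
                             stack.layer(var))
    for period, lucc in world.lucc.items():
        write_ascii_grid(out / f"lucc_{period}.asc",
                         RasterGrid(world.grid, lucc.values.astype(float)))
    write_ascii_grid(out / "pa_mask.asc",
                     RasterGrid(world.grid,
                                world.landscape.pa_mask.values.astype(float)))
    cfg.to_yaml(out / "run_config.yaml")

    n_occ = sum(len(sp.occurrences) for sp in world.species)
    mix = {}
    for sp in world.species:
        mix[sp.traits["archetype"]] = mix.get(sp.traits["archetype"], 0) + 1
    print(f"world seed {args.seed}: grid {world.grid.shape}, "
          f"{cfg.world.n_species} species ({mix}), {n_occ} raw records, "
          f"{len(world.landscape.climate)} climate scenarios -> {out}")


if __name__ == "__main__":
    main()
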