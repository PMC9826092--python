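"""Synthetic study system with known ground truth.

Builds everything the risk pipeline consumes for one landscape: smooth,
spatially autocorrelated climate surfaces for a current and several future
scenarios; categorical land-use/cover (LUCC) maps whose agricultural classes
expand over time; fire and hurricane hazard layers; ecoregion polygons and a
protected-area mask; and a set of virtual species with Gaussian climate
niches, clustered occurrence records and a trait table.

Each species carries a niche *archetype* that fixes how its climatically
suitable area responds to the imposed warming:

``stable``
    broad thermal tolerance centred mid-landscape; suitable area barely moves.
``shrinking``
    optimum in the cool part of the landscape; warming erodes the band.
``expanding``
    optimum at the warm margin; warming brings new cells into tolerance.
``doomed``
    thermal band narrower than the weakest scenario's minimum warming, so
    every future scenario leaves zero suitable cells — by construction.

Because niches, archetypes and land-class histories are known exactly, every
downstream stage (thinning, niche modelling, exposure, hazard, risk ranking)
can be checked against recoverable truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import box

from .grids import ClimateStack, GridSpec, RasterGrid

# LUCC legend shared by the whole pipeline
LUCC_NATURAL = 1
LUCC_RAINFED_AGRICULTURE = 2
LUCC_CATTLE_GRASSLAND = 3
LUCC_URBAN = 4

ARCHETYPES = ("doomed", "stable", "shrinking", "expanding")

# Gaussian suitability >= 0.5  <=>  squared Mahalanobis distance <= 2 ln 2
TRUE_SUITABILITY_THRESHOLD = 0.5
_CHI_HALF = math.sqrt(2.0 * math.log(2.0))

ORDER_LABELS = (
    "Rodentia", "Chiroptera", "Carnivora", "Eulipotyphla", "Artiodactyla",
    "Lagomorpha", "Didelphimorphia", "Primates", "Cingulata",
)
TROPHIC_LABELS = (
    "frugivore-granivore", "insectivore", "herbivore-browser",
    "carnivore", "omnivore", "piscivore", "myrmecophage",
)
BODY_SIZE_LABELS = ("small", "medium", "medium-large", "large")
LOCOMOTION_LABELS = ("terrestrial", "arboreal", "semi-aquatic", "fossorial", "volant")

IUCN_CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "DD")
POPULATION_TRENDS = ("increasing", "stable", "decreasing", "unknown")


@dataclass(frozen=True)
class ScenarioSpec:
    """One (GCM, SSP, period) combination of the scenario design.

    ``dt_mean`` / ``dp_mean`` are the landscape-mean temperature (degC) and
    precipitation (mm) anomalies the scenario imposes on the current climate.
    """

    gcm_label: str
    ssp_label: str
    period: str  # {"current", "2030", "2050", "2070"}
    dt_mean: float = 0.0
    dp_mean: float = 0.0

    @property
    def key(self) -> str:
        return f"{self.gcm_label}_{self.ssp_label}_{self.period}"

    @property
    def is_current(self) -> bool:
        return self.period == "current"


def default_scenarios() -> list[ScenarioSpec]:
    """Current climate plus two contrasting 2070 futures.

    One GCM-like future is warmer and wetter, the other warms less and
    dries, mirroring the contrast between CanESM5-style and BCC-CSM2-style
    projections over Mexico (warming 1.2-5.2 degC; precipitation anomalies
    of either sign within roughly -87 to +16 mm).
    """
    return [
        ScenarioSpec("hist", "hist", "current"),
        ScenarioSpec("warmwet", "ssp585", "2070", dt_mean=3.5, dp_mean=12.0),
        ScenarioSpec("cooldry", "ssp245", "2070", dt_mean=2.0, dp_mean=-45.0),
    ]


def full_scenario_design() -> list[ScenarioSpec]:
    """The 2 GCM x 2 SSP x 3 period = 12-combination design."""
    periods = {"2030": 0.45, "2050": 0.75, "2070": 1.0}
    ssps = {"ssp245": (2.2, 1.0), "ssp585": (4.2, 1.6)}
    gcms = {"warmwet": +14.0, "cooldry": -55.0}
    out = [ScenarioSpec("hist", "hist", "current")]
    for gcm, dp in gcms.items():
        for ssp, (dt, pscale) in ssps.items():
            for period, frac in periods.items():
                out.append(ScenarioSpec(gcm, ssp, period,
                                        dt_mean=dt * frac,
                                        dp_mean=dp * pscale * frac))
    return out


@dataclass(frozen=True)
class WorldConfig:
    seed: int = 0
    extent: tuple[float, float, float, float] = (-106.0, -98.0, 16.0, 24.0)
    resolution: float = 1.0 / 15.0  # ~7.4 km cells at this latitude
    n_species: int = 20
    n_climate_vars: int = 6
    scenarios: tuple[ScenarioSpec, ...] = tuple(default_scenarios())
    archetype_mix: dict = field(
        default_factory=lambda: {"doomed": 0.1, "stable": 0.4,
                                 "shrinking": 0.3, "expanding": 0.2})
    pa_fraction: float = 0.12
    n_ecoregion_blocks: int = 3
    occ_min: int = 80
    occ_max: int = 4000
    occupancy_floor: float = TRUE_SUITABILITY_THRESHOLD  # records occur only in suitable cells
    lucc_initial_fractions: dict = field(
        default_factory=lambda: {"agriculture": 0.15, "grassland": 0.10,
                                 "urban": 0.02})
    lucc_growth_rate: float = 0.35  # fractional growth of ag+grass per period step
    fire_intensity: float = 1.0
    hurricane_intensity: float = 1.0
    hurricane_band_fraction: float = 0.25  # eastern fraction of columns hit

    def __post_init__(self) -> None:
        lon_min, lon_max, lat_min, lat_max = self.extent
        if not (lon_max > lon_min and lat_max > lat_min):
            raise ValueError("degenerate extent")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        total = sum(self.archetype_mix.get(a, 0.0) for a in ARCHETYPES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("archetype proportions must sum to 1")
        keys = set(self.scenarios)
        if len(keys) != len(self.scenarios):
            raise ValueError("duplicate (gcm, ssp, period) in scenario design")

    @property
    def grid(self) -> GridSpec:
        lon_min, lon_max, lat_min, lat_max = self.extent
        return GridSpec.from_extent(lon_min, lon_max, lat_min, lat_max,
                                    self.resolution)

    @property
    def future_scenarios(self) -> list[ScenarioSpec]:
        return [s for s in self.scenarios if not s.is_current]

    @property
    def current_scenario(self) -> ScenarioSpec:
        for s in self.scenarios:
            if s.is_current:
                return s
        raise ValueError("scenario design lacks a current period")


@dataclass
class TrueNiche:
    """Ground-truth Gaussian niche in climate space."""

    optimum: np.ndarray          # over niche variables (temperature, precipitation)
    breadth: np.ndarray          # strictly positive, same length
    archetype: str
    niche_vars: tuple[str, ...] = ("bio1", "bio3")

    def __post_init__(self) -> None:
        self.optimum = np.asarray(self.optimum, dtype=float)
        self.breadth = np.asarray(self.breadth, dtype=float)
        if np.any(self.breadth <= 0):
            raise ValueError("niche breadth must be strictly positive")
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")

    def suitability(self, stack: ClimateStack) -> RasterGrid:
        z2 = np.zeros(stack.spec.shape)
        for i, name in enumerate(self.niche_vars):
            z2 += ((stack.variables[name] - self.optimum[i]) / self.breadth[i]) ** 2
        return RasterGrid(stack.spec, np.exp(-0.5 * z2))

    def suitable_mask(self, stack: ClimateStack,
                      threshold: float = TRUE_SUITABILITY_THRESHOLD) -> RasterGrid:
        return RasterGrid(stack.spec,
                          self.suitability(stack).values >= threshold)


@dataclass
class SpeciesTruth:
    species_id: str
    occurrences: np.ndarray       # (n, 2) lon/lat
    niche: TrueNiche
    traits: dict


@dataclass
class Landscape:
    config: WorldConfig
    climate: dict[str, ClimateStack]              # scenario key -> stack
    ecoregions: list[tuple[int, object]]          # (id, shapely polygon)
    ecoregion_raster: RasterGrid                  # int ids
    pa_mask: RasterGrid                           # bool

    @property
    def grid(self) -> GridSpec:
        return self.config.grid

    def stack_for(self, scenario: ScenarioSpec) -> ClimateStack:
        return self.climate[scenario.key]


@dataclass
class SyntheticWorld:
    config: WorldConfig
    landscape: Landscape
    lucc: dict[str, RasterGrid]                   # period -> categorical map
    fires: RasterGrid
    hurricane_category: RasterGrid
    hurricane_frequency: RasterGrid
    species: list[SpeciesTruth]

    @property
    def grid(self) -> GridSpec:
        return self.config.grid

    def traits_table(self):
        import pandas as pd
        return pd.DataFrame([{"species_id": sp.species_id, **sp.traits}
                             for sp in self.species])


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float = 6.0) -> np.ndarray:
    """Unit-variance spatially autocorrelated Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _sinusoid(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    rows = np.linspace(0.0, 1.0, shape[0])[:, None]
    cols = np.linspace(0.0, 1.0, shape[1])[None, :]
    out = np.zeros(shape)
    for _ in range(3):
        fr, fc = rng.uniform(0.5, 2.0, size=2)
        pr, pc = rng.uniform(0.0, 2.0 * np.pi, size=2)
        out += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * fr * rows + pr) \
            * np.cos(2 * np.pi * fc * cols + pc)
    return out / max(out.std(), 1e-12)


def make_landscape(config: WorldConfig) -> Landscape:
    """Climate stacks per scenario, ecoregion polygons, protected-area mask.

    Current climate: bio1 is temperature-like (degC, with a latitudinal
    gradient), bio3 precipitation-like (mm).  bio2 and bio4 are engineered
    collinear partners of bio1 and bio3 (|r| > 0.9) to exercise correlation
    pre-selection; remaining variables are independent smooth fields.
    Futures add smooth anomaly fields with landscape means ``dt_mean`` (> 0
    everywhere for temperature) and ``dp_mean`` (either sign).
    """
    grid = config.grid
    shape = grid.shape
    root = np.random.SeedSequence(config.seed)
    r_clim, r_eco, r_pa, r_anom = [np.random.default_rng(s)
                                   for s in root.spawn(4)]

    _, lat = grid.cell_centers()
    lat01 = (lat - lat.min()) / max(lat.max() - lat.min(), 1e-12)

    # independent base surfaces
    temp = 24.0 - 8.0 * lat01 + 2.5 * _smooth_field(r_clim, shape) \
        + 1.0 * _sinusoid(shape, r_clim)
    precip = np.clip(900.0 + 450.0 * _smooth_field(r_clim, shape)
                     + 180.0 * _sinusoid(shape, r_clim), 0.0, None)
    aux = {f"bio{i}": _smooth_field(r_clim, shape) * 10.0
           for i in range(5, config.n_climate_vars + 1)}

    def derived(parent: np.ndarray, scale: float, noise: np.ndarray) -> np.ndarray:
        return scale * parent + noise

    noise2 = 0.15 * parent_sd(temp) * _smooth_field(r_clim, shape)
    noise4 = 0.15 * parent_sd(precip) * _smooth_field(r_clim, shape)

    def build_stack(t: np.ndarray, p: np.ndarray,
                    extra: dict[str, np.ndarray]) -> ClimateStack:
        variables = {
            "bio1": t,
            "bio2": derived(t, 1.4, noise2),
            "bio3": p,
            "bio4": derived(p, 0.6, noise4),
        }
        variables.update(extra)
        keep = [f"bio{i}" for i in range(1, config.n_climate_vars + 1)]
        return ClimateStack(grid, {k: variables[k] for k in keep
                                   if k in variables})

    climate = {config.current_scenario.key: build_stack(temp, precip, aux)}

    for scen in config.future_scenarios:
        rs = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7919, _stable_hash(scen.key)]))
        # warming anomaly: strictly positive when dt_mean > 0, with at least
        # half the scenario-mean warming everywhere (no cell escapes warming)
        dt = scen.dt_mean * (1.0 + 0.35 * _smooth_field(rs, shape))
        if scen.dt_mean > 0:
            dt = np.clip(dt, 0.5 * scen.dt_mean, None)
        dp = scen.dp_mean + abs(scen.dp_mean) * 0.4 * _smooth_field(rs, shape)
        amp = (abs(scen.dt_mean) + abs(scen.dp_mean)) / 10.0
        extra = {k: v + amp * _smooth_field(rs, shape)
                 for k, v in aux.items()}
        climate[scen.key] = build_stack(temp + dt, precip + dp, extra)

    # ecoregions: a block partition of the extent
    lon_min, lon_max, lat_min, lat_max = config.extent
    k = config.n_ecoregion_blocks
    dlon = (lon_max - lon_min) / k
    dlat = (lat_max - lat_min) / k
    ecoregions = []
    eco_raster = np.zeros(shape, dtype=int)
    lon_c, lat_c = grid.cell_centers()
    eid = 0
    for i in range(k):
        for j in range(k):
            eid += 1
            poly = box(lon_min + j * dlon, lat_max - (i + 1) * dlat,
                       lon_min + (j + 1) * dlon, lat_max - i * dlat)
            ecoregions.append((eid, poly))
            inside = ((lon_c >= lon_min + j * dlon)
                      & (lon_c < lon_min + (j + 1) * dlon + 1e-12)
                      & (lat_c <= lat_max - i * dlat)
                      & (lat_c > lat_max - (i + 1) * dlat - 1e-12))
            eco_raster[inside] = eid

    pa_field = _smooth_field(r_pa, shape)
    if config.pa_fraction <= 0:
        pa = np.zeros(shape, dtype=bool)
    else:
        pa = pa_field >= np.quantile(pa_field, 1.0 - config.pa_fraction)

    return Landscape(config=config, climate=climate, ecoregions=ecoregions,
                     ecoregion_raster=RasterGrid(grid, eco_raster),
                     pa_mask=RasterGrid(grid, pa))


def parent_sd(arr: np.ndarray) -> float:
    return float(np.std(arr))


def _stable_hash(text: str) -> int:
    h = 2166136261
    for ch in text.encode():
        h = ((h ^ ch) * 16777619) % (2 ** 31)
    return h


def make_lucc(config: WorldConfig, landscape: Landscape) -> dict[str, RasterGrid]:
    """Categorical land-use maps per period, agriculture expanding over time.

    Urban cells are fixed across periods (observed, not projected); rainfed
    agriculture and cattle grassland expand monotonically into natural
    vegetation by lowering the threshold on a fixed propensity field, so the
    agricultural footprint of a later period is a superset of an earlier one.
    """
    grid = landscape.grid
    shape = grid.shape
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    ag_field = _smooth_field(rng, shape)
    gr_field = _smooth_field(rng, shape)
    urb_field = _smooth_field(rng, shape, sigma=3.0)

    fr = config.lucc_initial_fractions
    urban = (urb_field >= np.quantile(urb_field, 1.0 - fr["urban"])) \
        if fr["urban"] > 0 else np.zeros(shape, dtype=bool)

    periods = ["current"] + sorted({s.period for s in config.future_scenarios})
    out: dict[str, RasterGrid] = {}
    for step, period in enumerate(periods):
        growth = (1.0 + config.lucc_growth_rate) ** step
        ag_frac = min(fr["agriculture"] * growth, 0.9)
        gr_frac = min(fr["grassland"] * growth, 0.9)
        ag = (ag_field >= np.quantile(ag_field, 1.0 - ag_frac)) \
            if ag_frac > 0 else np.zeros(shape, dtype=bool)
        gr = (gr_field >= np.quantile(gr_field, 1.0 - gr_frac)) \
            if gr_frac > 0 else np.zeros(shape, dtype=bool)
        lucc = np.full(shape, LUCC_NATURAL, dtype=int)
        lucc[gr] = LUCC_CATTLE_GRASSLAND
        lucc[ag & ~gr] = LUCC_RAINFED_AGRICULTURE
        lucc[urban] = LUCC_URBAN
        out[period] = RasterGrid(grid, lucc)
    return out


def make_hazards(config: WorldConfig, landscape: Landscape
                 ) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Fire counts plus hurricane (mean category, frequency) layers.

    Fires follow a Poisson draw on a smooth south-western rate gradient;
    hurricanes are confined to an eastern coastal band with category and
    frequency decaying inland, echoing observed Gulf-side storm exposure.
    """
    grid = landscape.grid
    shape = grid.shape
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1299709]))

    if config.fire_intensity <= 0:
        fires = np.zeros(shape, dtype=int)
    else:
        cols = np.linspace(1.0, 0.0, shape[1])[None, :]
        rows = np.linspace(0.0, 1.0, shape[0])[:, None]
        rate = config.fire_intensity * (0.1 + 1.5 * cols * rows
                                        + 0.4 * np.abs(_smooth_field(rng, shape)))
        fires = rng.poisson(rate)

    category = np.zeros(shape)
    frequency = np.zeros(shape)
    if config.hurricane_intensity > 0 and config.hurricane_band_fraction > 0:
        band_cols = max(1, int(round(shape[1] * config.hurricane_band_fraction)))
        decay = np.zeros(shape[1])
        decay[-band_cols:] = np.linspace(0.15, 1.0, band_cols)
        decay2d = np.broadcast_to(decay[None, :], shape)
        category = np.clip(5.0 * config.hurricane_intensity * decay2d, 0.0, 5.0)
        frequency = np.round(
            config.hurricane_intensity * decay2d
            * (2.0 + np.abs(_smooth_field(rng, shape))), 2)
        frequency[decay2d == 0] = 0.0
    return (RasterGrid(grid, fires), RasterGrid(grid, category),
            RasterGrid(grid, frequency))


def _archetype_counts(config: WorldConfig) -> list[str]:
    n = config.n_species
    counts = {a: int(math.floor(config.archetype_mix.get(a, 0.0) * n))
              for a in ARCHETYPES}
    remainders = sorted(
        ARCHETYPES,
        key=lambda a: -(config.archetype_mix.get(a, 0.0) * n
                        - counts[a]))
    i = 0
    while sum(counts.values()) < n:
        counts[remainders[i % len(remainders)]] += 1
        i += 1
    labels = []
    for a in ARCHETYPES:
        labels.extend([a] * counts[a])
    return labels[:n]


def _build_niche(archetype: str, temp: np.ndarray, precip: np.ndarray,
                 min_future_warming: float, rng: np.random.Generator) -> TrueNiche:
    t_sd = float(temp.std())
    p_med, p_sd = float(np.median(precip)), float(precip.std())
    if archetype == "doomed":
        # cold-margin thermal band [Tmin + 0.05 dTmin, Tmin + 0.95 dTmin]:
        # the coldest cells stay suitable today, but every cell warms by at
        # least dTmin, pushing the whole landscape past the band's upper
        # edge in every future scenario — extinction by construction
        half_width = 0.45 * min_future_warming
        opt_t = float(temp.min()) + 0.5 * min_future_warming
        breadth_t = max(half_width / _CHI_HALF, 1e-6)
        return TrueNiche(optimum=[opt_t, p_med],
                         breadth=[breadth_t, 50.0 * max(p_sd, 1.0)],
                         archetype=archetype)
    if archetype == "stable":
        # precipitation-limited: the occupied area is a rainfall band
        # (learnable against background), thermally tolerant enough that
        # warming barely moves it, and the small precipitation anomalies
        # shift it only marginally
        # optima cluster near the landscape median so ranges overlap and
        # stacked richness forms hotspot cells, as real assemblages do
        opt_t = float(np.median(temp)) + rng.normal(0.0, 0.2 * t_sd)
        return TrueNiche(optimum=[opt_t, p_med + rng.normal(0.0, 0.15 * p_sd)],
                         breadth=[5.0 * t_sd, rng.uniform(0.35, 0.5) * p_sd],
                         archetype=archetype)
    if archetype == "shrinking":
        opt_t = float(np.quantile(temp, rng.uniform(0.15, 0.35)))
        return TrueNiche(optimum=[opt_t, p_med + rng.normal(0.0, 0.15 * p_sd)],
                         breadth=[rng.uniform(0.45, 0.75) * t_sd, 2.0 * p_sd],
                         archetype=archetype)
    # expanding: optimum at the warm margin, band wide enough to keep a
    # foothold now and admit newly warmed cells later; rainfall optimum
    # anchored to the warm region so the niche is never empty today
    opt_t = float(temp.max()) + 0.3 * min_future_warming
    p_warm = float(np.median(precip[temp >= np.quantile(temp, 0.9)]))
    return TrueNiche(optimum=[opt_t, p_warm],
                     breadth=[rng.uniform(1.2, 1.6) * t_sd, 2.0 * p_sd],
                     archetype=archetype)


def make_species(config: WorldConfig, landscape: Landscape,
                 lucc: dict[str, RasterGrid] | None = None
                 ) -> list[SpeciesTruth]:
    """Virtual species: occurrences, ground-truth niches, trait table rows."""
    if config.n_species < 2:
        raise ValueError("need at least 2 species to rank")
    grid = landscape.grid
    current = landscape.stack_for(config.current_scenario)
    temp = current.variables["bio1"]
    precip = current.variables["bio3"]

    warmings = []
    for scen in config.future_scenarios:
        fut = landscape.stack_for(scen)
        warmings.append(float((fut.variables["bio1"] - temp).min()))
    min_future_warming = min(warmings) if warmings else 1.0
    if min_future_warming <= 0 and any(
            a == "doomed" for a in _archetype_counts(config)):
        raise ValueError(
            "doomed archetypes require strictly positive warming in every "
            "future scenario")

    lon_c, lat_c = grid.cell_centers()
    archetypes = _archetype_counts(config)
    species: list[SpeciesTruth] = []
    root = np.random.SeedSequence([config.seed, 15485863])
    seeds = root.spawn(config.n_species)
    for i, archetype in enumerate(archetypes):
        rng = np.random.default_rng(seeds[i])
        niche = _build_niche(archetype, temp, precip, min_future_warming, rng)
        suit = niche.suitability(current).values
        weights = np.where(suit >= config.occupancy_floor, suit, 0.0).ravel()
        total = weights.sum()
        if total <= 0:
            raise RuntimeError("species has no positive suitability anywhere")
        n_occ = int(round(np.exp(rng.uniform(np.log(config.occ_min),
                                             np.log(config.occ_max)))))
        if archetype == "doomed":
            # range-restricted species are densely recorded within their
            # small range, so the record floor tests the model, not sampling
            n_occ = max(n_occ, 400)
        idx = rng.choice(weights.size, size=n_occ, replace=True,
                         p=weights / total)
        jitter = rng.uniform(-0.5, 0.5, size=(n_occ, 2)) * grid.resolution
        lon = lon_c.ravel()[idx] + jitter[:, 0]
        lat = lat_c.ravel()[idx] + jitter[:, 1]
        lon = np.clip(lon, grid.lon_min + 1e-9, grid.lon_max - 1e-9)
        lat = np.clip(lat, grid.lat_min + 1e-9, grid.lat_max - 1e-9)
        occ = np.column_stack([lon, lat])

        row, col = grid.index_of(lon, lat)
        eco_ids = np.unique(landscape.ecoregion_raster.values[row, col])
        traits = {
            "n_ecoregions": int(max(1, len(eco_ids[eco_ids > 0]))),
            "iucn_category": rng.choice(IUCN_CATEGORIES,
                                        p=[0.45, 0.12, 0.15, 0.12, 0.06, 0.10]),
            "population_trend": rng.choice(POPULATION_TRENDS,
                                           p=[0.10, 0.35, 0.40, 0.15]),
            "endemic": bool(rng.random() < 0.3),
            "feeding": rng.choice(["generalist", "specialist"], p=[0.55, 0.45]),
            "cue_dependency": bool(rng.random() < 0.35),
            "dispersal_ability": rng.choice(["high", "medium", "low"],
                                            p=[0.3, 0.4, 0.3]),
            "island_restricted": bool(rng.random() < 0.08),
            "order_label": rng.choice(ORDER_LABELS),
            "trophic_group": rng.choice(TROPHIC_LABELS),
            "body_size_class": rng.choice(BODY_SIZE_LABELS),
            "locomotion_group": rng.choice(LOCOMOTION_LABELS),
            "archetype": archetype,
        }
        species.append(SpeciesTruth(species_id=f"sp{i:03d}",
                                    occurrences=occ, niche=niche,
                                    traits=traits))
    return species


def make_world(config: WorldConfig) -> SyntheticWorld:
    """Full synthetic study system for one configuration."""
    landscape = make_landscape(config)
    lucc = make_lucc(config, landscape)
    fires, hcat, hfreq = make_hazards(config, landscape)
    species = make_species(config, landscape, lucc)
    return SyntheticWorld(config=config, landscape=landscape, lucc=lucc,
                          fires=fires, hurricane_category=hcat,
                          hurricane_frequency=hfreq, species=species)
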