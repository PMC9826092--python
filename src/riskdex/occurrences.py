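"""Occurrence-record filtering and calibration areas.

Records pass through a fixed sequence before modelling: exact-coordinate
deduplication, spatial thinning to a minimum great-circle separation
(default 10 km; 5 km for range-restricted endemics), an inclusion floor of
25 unique records, and — for record-rich species — distance-based
subsampling down to a target that saturates at 300 as sample size grows.
The calibration/transference area is the 2-degree buffer around the
intersection of (i) the union of ecoregions holding at least one record and
(ii) a 3-degree buffer around the records themselves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from shapely.geometry import MultiPoint, Point
from shapely.ops import unary_union

from .grids import haversine_km, pairwise_haversine_km

MIN_RECORDS = 25
MAX_RECORDS = 300
DEFAULT_THIN_KM = 10.0
ENDEMIC_THIN_KM = 5.0

# decay constant anchoring the subsampling curve at m(25)=25, m(inf)=300
_TAU = (MAX_RECORDS - MIN_RECORDS) / math.log(MAX_RECORDS / (MAX_RECORDS - MIN_RECORDS))


class Stage(str, Enum):
    RAW = "raw"
    DEDUPLICATED = "deduplicated"
    THINNED = "thinned"
    SUBSAMPLED = "subsampled"


@dataclass
class OccurrenceSet:
    """One species' georeferenced points with filtering provenance."""

    species_id: str
    points: np.ndarray  # (n, 2) lon/lat decimal degrees
    stage: Stage = Stage.RAW
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size and self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2) lon/lat")

    def __len__(self) -> int:
        return 0 if self.points.size == 0 else self.points.shape[0]

    def evolve(self, points: np.ndarray, stage: Stage, note: str) -> "OccurrenceSet":
        return OccurrenceSet(self.species_id, points, stage,
                             self.history + [note])


def deduplicate(occ: OccurrenceSet, decimals: int = 6) -> OccurrenceSet:
    """Drop exact coordinate duplicates after rounding, keeping first seen."""
    pts = np.round(occ.points, decimals)
    _, first = np.unique(pts, axis=0, return_index=True)
    keep = np.sort(first)
    return occ.evolve(occ.points[keep], Stage.DEDUPLICATED,
                      f"dedup: {len(occ)} -> {len(keep)}")


def thin(occ: OccurrenceSet, min_km: float = DEFAULT_THIN_KM) -> OccurrenceSet:
    """Greedy spatial thinning in input order.

    A point is retained iff it lies at least ``min_km`` (haversine) from
    every previously retained point; deterministic without a seed.
    """
    if len(occ) == 0:
        raise ValueError("cannot thin an empty occurrence set")
    if min_km <= 0:
        raise ValueError("min_km must be > 0")
    pts = occ.points
    kept: list[int] = []
    for i in range(len(pts)):
        if not kept:
            kept.append(i)
            continue
        d = haversine_km(pts[i, 0], pts[i, 1],
                         pts[kept, 0], pts[kept, 1])
        if np.all(d >= min_km):
            kept.append(i)
    return occ.evolve(pts[kept], Stage.THINNED,
                      f"thin {min_km} km: {len(occ)} -> {len(kept)}")


def include_species(n_unique: int) -> bool:
    """Inclusion floor: species enter the pipeline with >= 25 unique records."""
    if n_unique < 0:
        raise ValueError("record count cannot be negative")
    return n_unique >= MIN_RECORDS


def target_sample_size(n_unique: int) -> int:
    """Subsampling target for record-rich species.

    m(n) = round(300 - 275 * exp(-(n - 25) / tau)) with tau chosen so that
    m(25) = 25 and m(n) saturates at 300 for large samples; the curve is
    non-decreasing and never exceeds min(n, 300).
    """
    if n_unique < MIN_RECORDS:
        raise ValueError(
            f"species with fewer than {MIN_RECORDS} unique records are "
            "excluded upstream")
    m = round(MAX_RECORDS
              - (MAX_RECORDS - MIN_RECORDS)
              * math.exp(-(n_unique - MIN_RECORDS) / _TAU))
    return int(min(m, n_unique, MAX_RECORDS))


def subsample_to_target(occ: OccurrenceSet, target: int) -> OccurrenceSet:
    """Distance-based subsampling: discard from the closest pair until target.

    At each step the currently closest pair is found and the member whose
    second-nearest-neighbour distance is smaller is removed (ties broken
    toward the lower input index), which preferentially keeps spread-out
    records.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    n = len(occ)
    if target > n:
        raise ValueError(f"target {target} exceeds record count {n}")
    if target == n:
        return occ.evolve(occ.points, Stage.SUBSAMPLED, "subsample: identity")

    dmat = pairwise_haversine_km(occ.points)
    np.fill_diagonal(dmat, np.inf)
    alive = np.ones(n, dtype=bool)
    # nearest-neighbour distance and index per point, updated incrementally
    nn_idx = np.argmin(dmat, axis=1)
    nn_dist = dmat[np.arange(n), nn_idx]

    def second_nearest(i: int) -> float:
        row = dmat[i][alive]
        if row.size < 2:
            return np.inf
        return float(np.partition(row, 1)[1])

    n_alive = n
    while n_alive > target:
        masked = np.where(alive, nn_dist, np.inf)
        a = int(np.argmin(masked))
        b = int(nn_idx[a])
        sa, sb = second_nearest(a), second_nearest(b)
        if sa < sb or (sa == sb and a < b):
            drop = a
        else:
            drop = b
        alive[drop] = False
        dmat[drop, :] = np.inf
        dmat[:, drop] = np.inf
        stale = alive & (nn_idx == drop)
        stale[drop] = False
        for i in np.nonzero(stale)[0]:
            nn_idx[i] = int(np.argmin(dmat[i]))
            nn_dist[i] = dmat[i, nn_idx[i]]
        n_alive -= 1

    keep = np.nonzero(alive)[0]
    return occ.evolve(occ.points[keep], Stage.SUBSAMPLED,
                      f"subsample: {n} -> {len(keep)}")


def prepare_occurrences(occ: OccurrenceSet,
                        min_km: float = DEFAULT_THIN_KM) -> OccurrenceSet | None:
    """Full filtering chain; None when the species misses the 25-record floor."""
    deduped = deduplicate(occ)
    thinned = thin(deduped, min_km=min_km)
    if not include_species(len(thinned)) and min_km > ENDEMIC_THIN_KM:
        # endemic relaxation: thin the deduplicated records at 5 km instead
        thinned = thin(deduped, min_km=ENDEMIC_THIN_KM)
    if not include_species(len(thinned)):
        return None
    target = target_sample_size(len(thinned))
    if target < len(thinned):
        return subsample_to_target(thinned, target)
    return thinned


@dataclass
class CalibrationArea:
    """Model calibration/transference region for one species."""

    species_id: str
    polygon: object  # shapely geometry, WGS84 degrees
    component_ecoregion_ids: list[int]


def build_calibration_area(species_id: str, points: np.ndarray,
                           ecoregions: list[tuple[int, object]],
                           buffer_localities_deg: float = 3.0,
                           buffer_final_deg: float = 2.0) -> CalibrationArea:
    """buffer_2deg( (union of occupied ecoregions) intersect buffer_3deg(points) ).

    Buffers are taken in decimal degrees.  Points falling outside every
    ecoregion contribute through the locality buffer alone (with a warning).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("no points")
    locality_buffer = MultiPoint([Point(x, y) for x, y in pts]).buffer(
        buffer_localities_deg)
    occupied = []
    covered = np.zeros(len(pts), dtype=bool)
    for eid, poly in ecoregions:
        hits = np.fromiter((poly.intersects(Point(x, y)) for x, y in pts),
                           dtype=bool, count=len(pts))
        if hits.any():
            occupied.append((eid, poly))
            covered |= hits
    if not covered.all():
        warnings.warn(
            f"{species_id}: {int((~covered).sum())} point(s) outside all "
            "ecoregions; covered by the locality buffer only")
    if occupied:
        core = unary_union([p for _, p in occupied]).intersection(locality_buffer)
        if not covered.all():
            stray = MultiPoint([Point(x, y) for x, y in pts[~covered]])
            core = unary_union([core, stray.buffer(buffer_localities_deg)])
    else:
        core = locality_buffer
    area = core.buffer(buffer_final_deg)
    return CalibrationArea(species_id=species_id, polygon=area,
                           component_ecoregion_ids=[e for e, _ in occupied])


def min_pairwise_distance_km(points: np.ndarray) -> float:
    """Smallest great-circle distance among a set of points (inf for n<2)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        return float("inf")
    d = pairwise_haversine_km(pts)
    np.fill_diagonal(d, np.inf)
    return float(d.min())
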