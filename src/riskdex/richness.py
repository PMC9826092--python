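"""Stacked species richness, species-rich areas, and turnover maps.

Per-species binary suitability maps are summed cellwise into richness
counts; cells above a richness threshold form the "species-rich area" whose
contraction across time is reported as a percentage.  Overlaying a LUCC map
zeroes richness on land classes unsuitable under the chosen precautionary
principle.  Cross-time differences split into gain and loss masks that
localize expected species turnover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exposure import PRINCIPLE_CLASSES
from .grids import GridMismatchError, RasterGrid, check_same_grid

DEFAULT_ABSOLUTE_THRESHOLD = 75


def richness_threshold(n_species: int,
                       absolute: int = DEFAULT_ABSOLUTE_THRESHOLD,
                       max_count: int | None = None) -> float:
    """Species-rich cut delimiting the richest cells.

    Large assemblages (>= 100 species) use the absolute cut (default 75
    species).  Small desk-scale assemblages use 75% of the observed maximum
    richness when ``max_count`` is supplied — three-quarters of an entire
    assemblage never co-occurs in one cell, so a fraction of the richness
    peak is the reading that still delimits non-empty rich areas — and fall
    back to 75% of ``n_species`` otherwise.
    """
    if n_species >= 100:
        return float(absolute)
    if max_count is not None:
        return 0.75 * max_count
    return 0.75 * n_species


@dataclass
class RichnessMap:
    scenario: str
    principle: str | None        # None = climate-only stacking
    counts: RasterGrid
    threshold: float

    @property
    def rich_mask(self) -> np.ndarray:
        return self.counts.values > self.threshold


def stack_richness(binary_maps: list[RasterGrid]) -> RasterGrid:
    """Cellwise sum of binary maps; cells outside every area count 0."""
    if not binary_maps:
        raise ValueError("no maps to stack")
    spec = check_same_grid(*[m.spec for m in binary_maps])
    counts = np.zeros(spec.shape)
    for m in binary_maps:
        counts += np.nan_to_num(m.values.astype(float), nan=0.0)
    return RasterGrid(spec, counts.astype(int))


def overlay_lucc_on_richness(counts: RasterGrid, lucc_map: RasterGrid,
                             principle: str,
                             class_sets: dict | None = None) -> RasterGrid:
    """Zero richness on land classes unsuitable under the principle."""
    if counts.spec != lucc_map.spec:
        raise GridMismatchError("richness/LUCC grids differ")
    classes = (class_sets or PRINCIPLE_CLASSES)[principle]
    out = counts.values.copy()
    out[np.isin(lucc_map.values, list(classes))] = 0
    return RasterGrid(counts.spec, out)


def richness_change(counts_current: RasterGrid, counts_future: RasterGrid
                    ) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """(signed difference, gain mask, loss mask) between two richness maps."""
    if counts_current.spec != counts_future.spec:
        raise GridMismatchError("richness grids differ")
    diff = counts_future.values.astype(int) - counts_current.values.astype(int)
    return (RasterGrid(counts_current.spec, diff),
            RasterGrid(counts_current.spec, diff > 0),
            RasterGrid(counts_current.spec, diff < 0))


def rich_area_reduction(mask_current: np.ndarray,
                        mask_future: np.ndarray) -> float:
    """Percent contraction of the species-rich area (pixel counts)."""
    cur = int(np.asarray(mask_current, dtype=bool).sum())
    if cur == 0:
        raise ValueError("current species-rich area is empty")
    fut = int(np.asarray(mask_future, dtype=bool).sum())
    return 100.0 * (cur - fut) / cur
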