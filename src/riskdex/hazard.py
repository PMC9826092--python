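"""Hazard variables over a species' future potential distribution area.

Four physical-event variables are measured on the future PDA (under the
active dispersal assumption): mean absolute temperature change (degC), mean
absolute precipitation change (mm), fire density (observed fire counts per
PDA pixel), and hurricane intensity (PDA-weighted mean of per-cell mean
category x frequency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridMismatchError, RasterGrid


@dataclass
class HazardRecord:
    species_id: str
    scenario: str
    t_change: float
    p_change: float
    fire_density: float
    hurricane_intensity: float


def _pda_indices(pda_binary: RasterGrid) -> np.ndarray:
    vals = pda_binary.values
    mask = np.nan_to_num(vals, nan=0.0) >= 1.0 if vals.dtype.kind == "f" \
        else vals.astype(bool)
    if not mask.any():
        raise ValueError("empty PDA (total-loss species)")
    return mask


def delta_climate(current_t: RasterGrid, future_t: RasterGrid,
                  current_p: RasterGrid, future_p: RasterGrid,
                  pda_binary: RasterGrid) -> tuple[float, float]:
    """PDA means of |future - current| for temperature and precipitation."""
    for layer in (current_t, future_t, current_p, future_p):
        if layer.spec != pda_binary.spec:
            raise GridMismatchError("climate/PDA grids differ")
    mask = _pda_indices(pda_binary)
    dt = float(np.abs(future_t.values - current_t.values)[mask].mean())
    dp = float(np.abs(future_p.values - current_p.values)[mask].mean())
    return dt, dp


def fire_density(fire_counts: RasterGrid, pda_binary: RasterGrid) -> float:
    """Total observed fires on the PDA divided by the PDA pixel count."""
    if fire_counts.spec != pda_binary.spec:
        raise GridMismatchError("fire/PDA grids differ")
    mask = _pda_indices(pda_binary)
    return float(fire_counts.values[mask].sum() / mask.sum())


def hurricane_intensity(category: RasterGrid, frequency: RasterGrid,
                        pda_binary: RasterGrid) -> float:
    """PDA mean of per-cell intensity = mean category x frequency.

    Equivalent to summing each distinct intensity level weighted by the
    fraction of the PDA at that level.
    """
    if category.spec != pda_binary.spec or frequency.spec != pda_binary.spec:
        raise GridMismatchError("hurricane/PDA grids differ")
    mask = _pda_indices(pda_binary)
    intensity = category.values * frequency.values
    return float(intensity[mask].mean())


def hazard_record(species_id: str, scenario: str,
                  current_t: RasterGrid, future_t: RasterGrid,
                  current_p: RasterGrid, future_p: RasterGrid,
                  fires: RasterGrid, hurr_category: RasterGrid,
                  hurr_frequency: RasterGrid,
                  pda_binary: RasterGrid) -> HazardRecord:
    dt, dp = delta_climate(current_t, future_t, current_p, future_p, pda_binary)
    return HazardRecord(
        species_id=species_id, scenario=scenario, t_change=dt, p_change=dp,
        fire_density=fire_density(fires, pda_binary),
        hurricane_intensity=hurricane_intensity(hurr_category, hurr_frequency,
                                                pda_binary))
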