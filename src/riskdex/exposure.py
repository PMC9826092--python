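"""Per-species exposure: suitable-area change and LUCC overlap.

Exposure couples two signals: the change in potential distribution area
(PDA, a pixel count of climatically suitable cells) between the current and
a future scenario, and the fraction of the remaining future PDA that falls
on land classes treated as unsuitable.  The land-class reading follows the
precautionary principle: under WP rainfed agriculture and cattle grassland
(plus urban) are unsuitable; under WoP only urban is.  Dispersal enters as a
masking assumption: limited full dispersal allows any suitable cell within
the calibration/transference area, non-dispersal keeps only cells suitable
both now and in the future.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridMismatchError, RasterGrid
from .synthetic_world import (LUCC_CATTLE_GRASSLAND, LUCC_RAINFED_AGRICULTURE,
                              LUCC_URBAN)

WP_UNSUITABLE_CLASSES = frozenset(
    {LUCC_RAINFED_AGRICULTURE, LUCC_CATTLE_GRASSLAND, LUCC_URBAN})
WOP_UNSUITABLE_CLASSES = frozenset({LUCC_URBAN})

PRINCIPLE_CLASSES = {"WP": WP_UNSUITABLE_CLASSES, "WoP": WOP_UNSUITABLE_CLASSES}

DISPERSAL_MODES = ("limited_full", "none")


@dataclass
class ExposureRecord:
    species_id: str
    scenario: str
    dispersal: str
    pda_current: int
    pda_future: int
    pda_change_pct: float | None
    lucc_wp_fraction: float | None
    lucc_wop_fraction: float | None
    total_loss: bool


def _binary_mask(layer: RasterGrid) -> np.ndarray:
    vals = layer.values
    return np.nan_to_num(vals, nan=0.0) >= 1.0 if vals.dtype.kind == "f" \
        else vals.astype(bool)


def apply_dispersal(current_binary: RasterGrid, future_binary: RasterGrid,
                    mode: str) -> RasterGrid:
    """Mask a future binary map under a dispersal assumption."""
    if current_binary.spec != future_binary.spec:
        raise GridMismatchError("current/future grids differ")
    if mode not in DISPERSAL_MODES:
        raise ValueError(f"unknown dispersal mode {mode!r}")
    if mode == "limited_full":
        return future_binary
    cur = _binary_mask(current_binary)
    fut = future_binary.values.copy()
    if fut.dtype.kind == "f":
        fut[~cur & ~np.isnan(fut)] = 0.0
    else:
        fut = (fut.astype(bool) & cur)
    return RasterGrid(future_binary.spec, fut)


def pda_pixels(binary: RasterGrid) -> int:
    return int(_binary_mask(binary).sum())


def pda_change(current_binary: RasterGrid, future_binary: RasterGrid) -> float:
    """Signed percent change of suitable pixel count; -100 means total loss."""
    if current_binary.spec != future_binary.spec:
        raise GridMismatchError("current/future grids differ")
    cur = pda_pixels(current_binary)
    if cur == 0:
        raise ValueError("current PDA is empty; species not modellable")
    fut = pda_pixels(future_binary)
    return 100.0 * (fut - cur) / cur


def lucc_unsuitable_fraction(future_binary: RasterGrid, lucc_map: RasterGrid,
                             principle: str,
                             class_sets: dict | None = None) -> float:
    """Fraction of suitable cells lying on land classes unsuitable under
    the given principle."""
    if future_binary.spec != lucc_map.spec:
        raise GridMismatchError("suitability/LUCC grids differ")
    classes = (class_sets or PRINCIPLE_CLASSES)[principle]
    pda = _binary_mask(future_binary)
    n = int(pda.sum())
    if n == 0:
        raise ValueError("future PDA is empty (total-loss species)")
    unsuitable = np.isin(lucc_map.values, list(classes))
    return float((pda & unsuitable).sum() / n)


def exposure_record(species_id: str, scenario_key: str,
                    current_binary: RasterGrid, future_binary: RasterGrid,
                    lucc_map: RasterGrid, dispersal: str = "limited_full",
                    class_sets: dict | None = None) -> ExposureRecord:
    """All exposure quantities for one species x scenario x dispersal mode."""
    fut = apply_dispersal(current_binary, future_binary, dispersal)
    cur_n = pda_pixels(current_binary)
    fut_n = pda_pixels(fut)
    if fut_n == 0:
        return ExposureRecord(species_id, scenario_key, dispersal,
                              cur_n, 0, -100.0 if cur_n else None,
                              None, None, total_loss=True)
    return ExposureRecord(
        species_id, scenario_key, dispersal, cur_n, fut_n,
        pda_change(current_binary, fut),
        lucc_unsuitable_fraction(fut, lucc_map, "WP", class_sets),
        lucc_unsuitable_fraction(fut, lucc_map, "WoP", class_sets),
        total_loss=False)
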