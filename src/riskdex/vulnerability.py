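"""Vulnerability: trait-based sensitivity and protected-area adaptive capacity.

Sensitivity scores eight biological characteristics per species (ecoregion
occupancy, IUCN category, population trend, endemism, feeding specialism,
environmental-cue dependency, dispersal ability, island restriction).  Each
characteristic maps to a numeric risk value, species are ranked per
characteristic with ties averaged (higher rank = more at risk), the eight
ranks are summed, and the sums are ranked again to give the sensitivity
score.  Adaptive capacity is the change in the share of a species' suitable
cells that lie inside protected areas (NPA): a falling in-PA share signals
eroding capacity to cope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grids import GridMismatchError, RasterGrid

SENSITIVITY_TRAITS = (
    "n_ecoregions", "iucn_category", "population_trend", "endemic",
    "feeding", "cue_dependency", "dispersal_ability", "island_restricted",
)

# categorical trait value -> risk contribution (+1 riskier, -1 safer, 0 neutral)
DEFAULT_TRAIT_RISK = {
    "iucn_category": {"LC": -1, "NT": 0, "VU": 1, "EN": 1, "CR": 1, "DD": 0},
    "population_trend": {"increasing": -1, "stable": 0, "decreasing": 1,
                         "unknown": 0},
    "endemic": {True: 1, False: -1},
    "feeding": {"generalist": -1, "specialist": 1},
    "cue_dependency": {True: 1, False: -1},
    "dispersal_ability": {"high": -1, "medium": 0, "low": 1},
    "island_restricted": {True: 1, False: -1},
}


def score_trait(trait: str, value, mapping: dict | None = None) -> float:
    """Numeric risk value for one trait observation.

    Categorical traits map through the configured {-1, 0, +1} table;
    ``n_ecoregions`` enters as a negated count (occupying fewer ecoregions
    is riskier).
    """
    if trait == "n_ecoregions":
        n = int(value)
        if n < 1:
            raise ValueError("n_ecoregions must be >= 1")
        return -float(n)
    table = (mapping or DEFAULT_TRAIT_RISK).get(trait)
    if table is None:
        raise KeyError(f"unknown trait {trait!r}")
    if isinstance(value, (bool, np.bool_)):
        value = bool(value)
    if value not in table:
        raise ValueError(f"unknown value {value!r} for trait {trait!r}")
    return float(table[value])


def rank_risk(values: np.ndarray) -> np.ndarray:
    """Ascending tie-averaged ranks; the riskiest value gets rank n."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite trait risk value")
    return rankdata(values, method="average")


def sensitivity_scores(traits: pd.DataFrame,
                       mapping: dict | None = None) -> pd.Series:
    """Per-species sensitivity score: rank of the summed per-trait ranks.

    ``traits`` holds one row per species with the eight sensitivity
    characteristics as columns and ``species_id`` as a column or index.
    """
    if len(traits) < 2:
        raise ValueError("sensitivity ranking needs at least 2 species")
    df = traits.set_index("species_id") if "species_id" in traits.columns \
        else traits
    rank_sum = np.zeros(len(df))
    for trait in SENSITIVITY_TRAITS:
        vals = np.array([score_trait(trait, v, mapping) for v in df[trait]])
        rank_sum += rank_risk(vals)
    return pd.Series(rank_risk(rank_sum), index=df.index,
                     name="sensitivity_score")


@dataclass
class NpaRecord:
    species_id: str
    scenario: str
    npa_current_pct: float
    npa_future_pct: float
    npa_change: float
    degenerate: bool = False  # set when the PA baseline is empty


def _in_pa_share(binary: RasterGrid, pa_mask: RasterGrid) -> float:
    vals = binary.values
    suit = np.nan_to_num(vals, nan=0.0) >= 1.0 if vals.dtype.kind == "f" \
        else vals.astype(bool)
    n = int(suit.sum())
    if n == 0:
        raise ValueError("empty PDA")
    return 100.0 * float((suit & pa_mask.values.astype(bool)).sum()) / n


def npa_change(species_id: str, scenario: str,
               current_binary: RasterGrid, future_binary: RasterGrid,
               pa_mask: RasterGrid) -> NpaRecord:
    """Percent change of the in-protected-area share of suitable cells.

    Zero-baseline conventions: current share 0 and future share > 0 maps to
    +100; both zero maps to 0.  An all-empty protected-area mask yields 0
    with the degenerate flag set.
    """
    if not (current_binary.spec == future_binary.spec == pa_mask.spec):
        raise GridMismatchError("NPA inputs on different grids")
    if not pa_mask.values.any():
        return NpaRecord(species_id, scenario, 0.0, 0.0, 0.0, degenerate=True)
    cur = _in_pa_share(current_binary, pa_mask)
    fut = _in_pa_share(future_binary, pa_mask)
    if cur == 0.0:
        change = 100.0 if fut > 0 else 0.0
    else:
        change = 100.0 * (fut - cur) / cur
    return NpaRecord(species_id, scenario, cur, fut, change)
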