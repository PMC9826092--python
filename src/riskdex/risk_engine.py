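"""Composite risk index: tie-averaged ranks, normalization, group summaries.

Every component variable is converted to a tie-averaged rank over the scored
assemblage (larger rank = more at risk; variables with a protective
direction are negated first).  Ranks are summed within each of the three
components — vulnerability (sensitivity + NPA), exposure (PDA change + LUCC
overlap under a precautionary principle), hazard (temperature, precipitation,
fires, hurricanes) — and the component sums are added into a raw risk value,
normalized by the assemblage maximum so the riskiest species scores exactly 1.
Species that lose their entire suitable area in a scenario cannot be ranked
and are reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

RISK_INCREASING = "risk_increasing"
RISK_DECREASING = "risk_decreasing"

# direction of each raw variable's relationship with risk: variables where a
# larger value is safer (more remaining area, growing in-PA share) are
# negated before ranking
DEFAULT_DIRECTIONS = {
    "npa_change": RISK_DECREASING,
    "pda_change_pct": RISK_DECREASING,
    "lucc_fraction": RISK_INCREASING,
    "t_change": RISK_INCREASING,
    "p_change": RISK_INCREASING,
    "fire_density": RISK_INCREASING,
    "hurricane_intensity": RISK_INCREASING,
}

GROUP_COLUMNS = {
    "order": "order_label",
    "trophic": "trophic_group",
    "body_size": "body_size_class",
    "locomotion": "locomotion_group",
}


def rank_with_ties(values, direction: str = RISK_INCREASING) -> np.ndarray:
    """Ascending tie-averaged ranks, oriented so larger rank = more at risk."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite value in ranking input")
    if direction == RISK_DECREASING:
        values = -values
    elif direction != RISK_INCREASING:
        raise ValueError(f"unknown direction {direction!r}")
    return rankdata(values, method="average")


def assemble_risk(sensitivity: pd.Series, npa: pd.DataFrame,
                  exposure: pd.DataFrame, hazard: pd.DataFrame,
                  principle: str, include_p_change: bool = True,
                  directions: dict | None = None,
                  dispersal: str = "limited_full") -> pd.DataFrame:
    """Risk ledger: one row per scored species x future scenario.

    ``sensitivity`` is indexed by species_id; ``npa``/``exposure``/``hazard``
    carry one row per species x scenario.  Total-loss species (empty future
    PDA) are excluded from ranking; ranks are computed within each scenario
    over the scored assemblage.
    """
    if principle not in ("WP", "WoP"):
        raise ValueError("principle must be 'WP' or 'WoP'")
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    lucc_col = "lucc_wp_fraction" if principle == "WP" else "lucc_wop_fraction"

    exp_rows = exposure[exposure["dispersal"] == dispersal]
    ledgers = []
    for scenario, exp_s in exp_rows.groupby("scenario", sort=True):
        scored = exp_s[~exp_s["total_loss"]].set_index("species_id")
        if scored.empty:
            raise ValueError(f"no scorable species in scenario {scenario}")
        ids = scored.index
        npa_s = npa[npa["scenario"] == scenario].set_index("species_id").loc[ids]
        haz_s = hazard[hazard["scenario"] == scenario].set_index(
            "species_id").loc[ids]

        led = pd.DataFrame(index=ids)
        led["scenario"] = scenario
        led["principle"] = principle
        led["sensitivity_score"] = sensitivity.loc[ids].to_numpy()
        led["npa_score"] = rank_with_ties(npa_s["npa_change"],
                                          directions["npa_change"])
        led["vulnerability_score"] = (led["sensitivity_score"]
                                      + led["npa_score"])
        led["pda_score"] = rank_with_ties(scored["pda_change_pct"],
                                          directions["pda_change_pct"])
        led["lucc_score"] = rank_with_ties(scored[lucc_col],
                                           directions["lucc_fraction"])
        led["exposition_score"] = led["pda_score"] + led["lucc_score"]
        led["t_score"] = rank_with_ties(haz_s["t_change"],
                                        directions["t_change"])
        led["p_score"] = rank_with_ties(haz_s["p_change"],
                                        directions["p_change"])
        led["fire_score"] = rank_with_ties(haz_s["fire_density"],
                                           directions["fire_density"])
        led["hurricane_score"] = rank_with_ties(haz_s["hurricane_intensity"],
                                                directions["hurricane_intensity"])
        led["hazard_score"] = (led["t_score"] + led["fire_score"]
                               + led["hurricane_score"])
        if include_p_change:
            led["hazard_score"] += led["p_score"]
        led["risk_raw"] = (led["vulnerability_score"]
                           + led["exposition_score"] + led["hazard_score"])
        led["risk_normalized"] = led["risk_raw"] / led["risk_raw"].max()
        ledgers.append(led.reset_index().rename(columns={"index": "species_id"}))
    return pd.concat(ledgers, ignore_index=True)


def total_loss_species(exposure: pd.DataFrame,
                       dispersal: str = "limited_full") -> list[str]:
    """Species losing their entire suitable area in at least one scenario."""
    rows = exposure[(exposure["dispersal"] == dispersal)
                    & exposure["total_loss"]]
    return sorted(rows["species_id"].unique().tolist())


def top_decile(ledger: pd.DataFrame) -> pd.DataFrame:
    """Flag the ~10% highest-risk species per scenario x principle.

    The cut keeps the ceil(n/10) largest raw risk values; species tied with
    the value at the cut are all included.
    """
    import warnings
    out = ledger.copy()
    out["top_decile_flag"] = False
    for (_, _), idx in out.groupby(["scenario", "principle"]).groups.items():
        sub = out.loc[idx]
        n = len(sub)
        k = max(1, math.ceil(n / 10))
        if n < 10:
            warnings.warn(f"fewer than 10 scored species (n={n}); "
                          f"flagging {k}")
        cut = sub["risk_raw"].nlargest(k).min()
        flagged = sub.index[sub["risk_raw"] >= cut]
        if len(flagged) > k:
            warnings.warn("tie at the top-decile cut; including all tied "
                          "species")
        out.loc[flagged, "top_decile_flag"] = True
    return out


def _round_half_up(x: float, decimals: int = 2) -> float:
    scale = 10 ** decimals
    return math.floor(x * scale + 0.5) / scale


@dataclass
class GroupSummary:
    group_type: str
    group_label: str
    n_species: int
    pct_min: float
    pct_max: float


def group_percentages(ledger: pd.DataFrame, traits: pd.DataFrame,
                      group_type: str) -> pd.DataFrame:
    """Per group x scenario x principle: % of the group's species flagged."""
    col = GROUP_COLUMNS[group_type]
    tr = traits.set_index("species_id") if "species_id" in traits.columns \
        else traits
    merged = ledger.merge(tr[[col]], left_on="species_id", right_index=True)
    rows = []
    for (label, scenario, principle), sub in merged.groupby(
            [col, "scenario", "principle"]):
        n = len(sub)
        if n == 0:
            continue
        pct = _round_half_up(100.0 * sub["top_decile_flag"].sum() / n)
        rows.append({"group_type": group_type, "group_label": label,
                     "scenario": scenario, "principle": principle,
                     "n_species": n, "pct_top_decile": pct})
    return pd.DataFrame(rows)


def group_summary(ledger: pd.DataFrame, traits: pd.DataFrame,
                  group_type: str) -> list[GroupSummary]:
    """Min-max range of the top-decile percentage across scenario combinations."""
    pct = group_percentages(ledger, traits, group_type)
    out = []
    for label, sub in pct.groupby("group_label"):
        out.append(GroupSummary(
            group_type=group_type, group_label=str(label),
            n_species=int(sub["n_species"].iloc[0]),
            pct_min=float(sub["pct_top_decile"].min()),
            pct_max=float(sub["pct_top_decile"].max())))
    return out


def compare_groups(risk_a: np.ndarray, risk_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum comparison of two groups.

    Small samples (min n <= 8) use the exact null distribution, or exhaustive
    permutation when ties make the classical exact distribution invalid;
    larger samples use the tie-corrected normal approximation.
    """
    a = np.asarray(risk_a, dtype=float)
    b = np.asarray(risk_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 members")
    small = min(len(a), len(b)) <= 8
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if small and not has_ties:
        method = "exact"
    elif small:
        method = stats.PermutationMethod(n_resamples=20000,
                                         rng=np.random.default_rng(0))
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
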