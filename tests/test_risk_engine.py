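import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from riskdex.risk_engine import (assemble_risk, compare_groups,
                                 group_percentages, group_summary,
                                 rank_with_ties, top_decile,
                                 total_loss_species)


def average_rank_oracle(values):
    """Independent tie-averaged ranking: mean of the 1-based sorted positions
    each value occupies."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def component_tables(n, rng, scenarios=("s1",), total_loss=()):
    """Random but consistent component tables for n species."""
    ids = [f"sp{i:03d}" for i in range(n)]
    sensitivity = pd.Series(rank_with_ties(rng.random(n)), index=ids)
    npa_rows, exp_rows, haz_rows = [], [], []
    for scen in scenarios:
        for sid in ids:
            lost = sid in total_loss
            npa_rows.append({"species_id": sid, "scenario": scen,
                             "npa_change": rng.uniform(-80, 80)})
            wop = rng.uniform(0, 0.5)
            exp_rows.append({
                "species_id": sid, "scenario": scen,
                "dispersal": "limited_full",
                "pda_change_pct": -100.0 if lost else rng.uniform(-90, 50),
                "lucc_wp_fraction": None if lost else wop + rng.uniform(0, 0.4),
                "lucc_wop_fraction": None if lost else wop,
                "total_loss": lost})
            haz_rows.append({"species_id": sid, "scenario": scen,
                             "t_change": rng.uniform(0, 5),
                             "p_change": rng.uniform(0, 90),
                             "fire_density": rng.uniform(0, 2),
                             "hurricane_intensity": rng.uniform(0, 10)})
    return (sensitivity, pd.DataFrame(npa_rows), pd.DataFrame(exp_rows),
            pd.DataFrame(haz_rows))


class TestRankWithTies:
    def test_tie_averaged_example(self):
        assert rank_with_ties([10, 20, 20, 30]).tolist() == [1, 2.5, 2.5, 4]

    def test_single_value(self):
        assert rank_with_ties([7.0]).tolist() == [1.0]

    def test_direction_flip(self):
        # for a protective variable the smallest value is riskiest
        assert rank_with_ties([10, 20, 30], "risk_decreasing").tolist() \
            == [3, 2, 1]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            rank_with_ties([1.0, np.nan])

    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=50))
    def test_matches_oracle_and_conserves_sum(self, values):
        ranks = rank_with_ties(values)
        assert ranks.tolist() == average_rank_oracle(values)
        n = len(values)
        assert ranks.sum() == pytest.approx(n * (n + 1) / 2)


class TestAssembleRisk:
    def test_single_scored_species_normalizes_to_one(self, rng):
        tabs = component_tables(1, rng)
        led = assemble_risk(*tabs, principle="WP")
        assert led["risk_normalized"].tolist() == [1.0]

    @pytest.mark.parametrize("n", [2, 7, 33])
    def test_max_normalized_risk_exactly_one(self, n, rng):
        led = assemble_risk(*component_tables(n, rng), principle="WP")
        assert led["risk_normalized"].max() == 1.0
        assert (led["risk_normalized"] > 0).all()

    def test_strictly_ordered_species_preserve_order(self, rng):
        ids = ["a", "b", "c"]
        sens = pd.Series([1.0, 2.0, 3.0], index=ids)
        npa = pd.DataFrame({"species_id": ids, "scenario": "s1",
                            "npa_change": [30.0, 0.0, -30.0]})
        exp = pd.DataFrame({"species_id": ids, "scenario": "s1",
                            "dispersal": "limited_full",
                            "pda_change_pct": [10.0, -20.0, -50.0],
                            "lucc_wp_fraction": [0.1, 0.2, 0.3],
                            "lucc_wop_fraction": [0.05, 0.1, 0.15],
                            "total_loss": False})
        haz = pd.DataFrame({"species_id": ids, "scenario": "s1",
                            "t_change": [1.0, 2.0, 3.0],
                            "p_change": [5.0, 10.0, 15.0],
                            "fire_density": [0.1, 0.2, 0.3],
                            "hurricane_intensity": [1.0, 2.0, 3.0]})
        led = assemble_risk(sens, npa, exp, haz, principle="WP"
                            ).set_index("species_id")
        # hand-computed rank sums: each of the 8 ranked variables
        # (sensitivity, NPA, PDA, LUCC, T, P, fires, hurricanes) ranks
        # a=1, b=2, c=3 -> raw risk 8, 16, 24
        assert led.loc["a", "risk_raw"] == pytest.approx(8.0)
        assert led.loc["c", "risk_raw"] == pytest.approx(24.0)
        assert led["risk_normalized"].tolist() == pytest.approx(
            [8 / 24, 16 / 24, 1.0])

    def test_total_loss_species_excluded_and_reported(self, rng):
        tabs = component_tables(6, rng, total_loss=("sp000",))
        led = assemble_risk(*tabs, principle="WoP")
        assert "sp000" not in set(led["species_id"])
        assert total_loss_species(tabs[2]) == ["sp000"]

    def test_three_variable_hazard_switch(self, rng):
        tabs = component_tables(8, rng)
        led4 = assemble_risk(*tabs, principle="WP", include_p_change=True)
        led3 = assemble_risk(*tabs, principle="WP", include_p_change=False)
        assert (led4["hazard_score"]
                == led3["hazard_score"] + led4["p_score"]).all()

    def test_worsening_one_variable_never_lowers_risk(self, rng):
        """End-to-end monotonicity of the composite index."""
        for trial in range(30):
            tabs = component_tables(12, np.random.default_rng(trial))
            led = assemble_risk(*tabs, principle="WP").set_index("species_id")
            sid = f"sp{trial % 12:03d}"
            sens, npa, exp, haz = tabs
            haz = haz.copy()
            haz.loc[haz.species_id == sid, "fire_density"] += 10.0
            led2 = assemble_risk(sens, npa, exp, haz, principle="WP"
                                 ).set_index("species_id")
            assert led2.loc[sid, "risk_normalized"] \
                >= led.loc[sid, "risk_normalized"] - 1e-12


class TestTopDecile:
    def _ledger(self, n, rng, risks=None):
        led = assemble_risk(*component_tables(n, rng), principle="WP")
        if risks is not None:
            led["risk_raw"] = risks
        return led

    def test_450_species_flags_45(self):
        rng = np.random.default_rng(5)
        led = self._ledger(450, rng)
        assert top_decile(led)["top_decile_flag"].sum() == 45

    def test_20_species_flags_2(self, rng):
        led = self._ledger(20, rng)
        assert top_decile(led)["top_decile_flag"].sum() == 2

    def test_matches_sort_oracle_on_distinct_risks(self, rng):
        led = self._ledger(37, rng, risks=rng.permutation(37).astype(float))
        flagged = top_decile(led)
        k = int(np.ceil(37 / 10))
        oracle = set(flagged.sort_values("risk_raw", ascending=False)
                     ["species_id"].head(k))
        assert set(flagged[flagged.top_decile_flag]["species_id"]) == oracle

    def test_tie_at_cut_includes_all(self, rng):
        led = self._ledger(20, rng, risks=[50.0] * 5 + list(range(15)))
        with pytest.warns(UserWarning, match="tie"):
            flagged = top_decile(led)
        assert flagged["top_decile_flag"].sum() == 5

    def test_small_assemblage_warns_and_flags_one(self, rng):
        led = self._ledger(5, rng)
        with pytest.warns(UserWarning, match="fewer than 10"):
            flagged = top_decile(led)
        assert flagged["top_decile_flag"].sum() == 1


class TestGroupSummaries:
    def _flagged_ledger(self, labels, flags):
        n = len(labels)
        led = pd.DataFrame({
            "species_id": [f"sp{i}" for i in range(n)],
            "scenario": "s1", "principle": "WP",
            "risk_raw": np.arange(n, dtype=float),
            "risk_normalized": np.linspace(0.1, 1.0, n),
            "top_decile_flag": flags})
        traits = pd.DataFrame({"species_id": [f"sp{i}" for i in range(n)],
                               "order_label": labels})
        return led, traits

    def test_one_of_three_is_33_33(self):
        led, traits = self._flagged_ledger(["Primates"] * 3,
                                           [True, False, False])
        pct = group_percentages(led, traits, "order")
        assert pct["pct_top_decile"].tolist() == [33.33]

    def test_single_species_group_reaches_100(self):
        led, traits = self._flagged_ledger(["Perissodactyla", "Rodentia"],
                                           [True, False])
        pct = group_percentages(led, traits, "order")
        row = pct[pct.group_label == "Perissodactyla"]
        assert row["pct_top_decile"].tolist() == [100.0]

    def test_unflagged_group_is_zero(self):
        led, traits = self._flagged_ledger(["Rodentia"] * 4, [False] * 4)
        pct = group_percentages(led, traits, "order")
        assert pct["pct_top_decile"].tolist() == [0.0]

    def test_summary_ranges(self):
        led, traits = self._flagged_ledger(["A", "A", "B"],
                                           [True, False, False])
        led2 = led.copy()
        led2["scenario"] = "s2"
        led2.loc[:, "top_decile_flag"] = [False, False, True]
        combined = pd.concat([led, led2], ignore_index=True)
        summaries = {s.group_label: s
                     for s in group_summary(combined, traits, "order")}
        assert summaries["A"].pct_min == 0.0
        assert summaries["A"].pct_max == 50.0
        assert summaries["B"].pct_max == 100.0


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        stat, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_groups_exact(self):
        # all 20 assignments of {1..6} into two triples: observed U = 0 is
        # one of the 2 most extreme -> two-sided exact p = 2/20 = 0.1
        stat, p = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert stat == 0.0
        assert p == pytest.approx(0.1)

    def test_invariant_to_monotone_transform(self, rng):
        a = rng.uniform(0, 1, 12)
        b = rng.uniform(0.2, 1.2, 15)
        _, p1 = compare_groups(a, b)
        _, p2 = compare_groups(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_groups([1.0], [2.0, 3.0])
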