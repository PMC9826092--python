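"""Summarize risk by taxonomic and functional groups.

Reads the ledgers written by 02_run_risk_pipeline.py, tabulates the share
of each order / trophic / body-size / locomotion group in the top risk
decile (the Table-4-style ranges across scenario combinations), and
compares the normalized risk of the two largest trophic groups with a
two-sided Wilcoxon rank-sum test.

Usage: python analysis/03_group_risk_analysis.py [--pipeline results/pipeline]
       [--out results/groups]
"""

import argparse
from pathlib import Path

import pandas as pd

from riskdex.risk_engine import compare_groups, group_summary


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--pipeline", type=Path,
                        default=Path("results/pipeline"))
    parser.add_argument("--out", type=Path, default=Path("results/groups"))
    args = parser.parse_args()

    traits = pd.read_csv(args.pipeline / "traits.csv")
    ledgers = [pd.read_csv(args.pipeline / f"risk_ledger_{p}.csv")
               for p in ("WP", "WoP")]
    ledger = pd.concat(ledgers, ignore_index=True)

    args.out.mkdir(parents=True, exist_ok=True)
    rows = []
    for group_type in ("order", "trophic", "body_size", "locomotion"):
        for s in group_summary(ledger, traits, group_type):
            rows.append({"group_type": s.group_type,
                         "group_label": s.group_label,
                         "n_species": s.n_species,
                         "pct_top_decile_min": s.pct_min,
                         "pct_top_decile_max": s.pct_max})
    table = pd.DataFrame(rows).sort_values(
        ["group_type", "pct_top_decile_max"], ascending=[True, False])
    table.to_csv(args.out / "group_ranges.csv", index=False)
    print("groups most represented in the top risk decile "
          "(min-max % across scenarios and principles):")
    print(table.head(10).to_string(index=False))

    # Wilcoxon comparison of the two largest trophic groups
    merged = ledger.merge(traits[["species_id", "trophic_group"]],
                          on="species_id")
    sizes = merged.groupby("trophic_group")["species_id"].nunique()
    if len(sizes) >= 2:
        g1, g2 = sizes.nlargest(2).index
        a = merged.loc[merged.trophic_group == g1, "risk_normalized"]
        b = merged.loc[merged.trophic_group == g2, "risk_normalized"]
        stat, p = compare_groups(a.to_numpy(), b.to_numpy())
        pd.DataFrame([{"group_a": g1, "group_b": g2, "n_a": len(a),
                       "n_b": len(b), "statistic": stat, "p_value": p}]) \
            .to_csv(args.out / "wilcoxon.csv", index=False)
        print(f"Wilcoxon rank-sum {g1} (n={len(a)}) vs {g2} (n={len(b)}): "
              f"U = {stat:.1f}, two-sided p = {p:.3f}")


if __name__ == "__main__":
    main()
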