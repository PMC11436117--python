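#!/usr/bin/env python
"""Run the 50-test group-comparison battery (Wilcoxon + Hedge's g,
Bonferroni over the full designed family) on the feature table.

Reads results/feature_table.csv, writes results/battery.csv and prints the
rows with the largest effect sizes.
"""

from pathlib import Path

from specmdd import stats as st
from specmdd.features import read_feature_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_feature_table(RESULTS / "feature_table.csv")
    results = st.run_battery(table)
    frame = st.battery_frame(results)
    frame.to_csv(RESULTS / "battery.csv", index=False)

    n_sig = int(frame["significant_at_0.05"].sum())
    print(f"battery: {len(frame)} tests, Bonferroni family {len(frame)}, "
          f"{n_sig} significant at adjusted alpha = 0.05")
    top = frame.reindex(
        frame.hedges_g.abs().sort_values(ascending=False).index).head(8)
    print("top rows by |Hedge's g| (positive = reduced in MDD):")
    for _, r in top.iterrows():
        print(f"  {r.feature:42s} g={r.hedges_g:+.2f} "
              f"p_adj={r.p_bonferroni:.2e}"
              f"{' *' if r['significant_at_0.05'] else ''}")


if __name__ == "__main__":
    main()
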