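#!/usr/bin/env python
"""Spearman correlations of the five selected electrode-level features with
the BDI total and its anhedonia and melancholia subscales.

Reads results/feature_table.csv, writes results/correlations.csv.
"""

from pathlib import Path

from specmdd import classify as clf
from specmdd import stats as st
from specmdd.features import read_feature_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_feature_table(RESULTS / "feature_table.csv")
    corr = st.correlation_table(table, list(clf.SELECTED_FEATURES.values()))
    corr.to_csv(RESULTS / "correlations.csv", index=False,
                float_format="%.6g")
    print("Spearman correlations with clinical scores "
          f"({len(corr)} feature x score pairs):")
    for _, r in corr.iterrows():
        print(f"  {r.feature:42s} vs {r.score:8s} rho={r.rho:+.2f} "
              f"p={r.p:.2e}")
    strongest = corr.reindex(corr.rho.abs().sort_values(ascending=False).index
                             ).iloc[0]
    print(f"strongest association: {strongest.feature} vs {strongest.score} "
          f"(rho = {strongest.rho:+.2f})")


if __name__ == "__main__":
    main()
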