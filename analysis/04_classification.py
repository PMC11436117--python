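#!/usr/bin/env python
"""Classify MDD vs HC by logistic regression under leave-one-subject-out
cross-validation, over the ten-set feature-combination menu.

Reads results/feature_table.csv, writes results/classification.json
(per-set AUC with stratified-bootstrap 95% CIs, n = 1000 resamples).
"""

import argparse
from pathlib import Path

from specmdd import classify as clf
from specmdd.features import read_feature_table
from specmdd.io import write_json

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--nboot", type=int, default=1000)
    args = ap.parse_args()

    table = read_feature_table(RESULTS / "feature_table.csv")
    menu = clf.enumerate_feature_sets()
    results = clf.run_menu(table, menu, n_boot=args.nboot, seed=args.seed)

    payload = []
    for spec, res in zip(menu, results):
        d = res.to_dict()
        d["n_features"] = len(spec.keys)
        d["kind"] = spec.kind
        payload.append(d)
    write_json(payload, RESULTS / "classification.json")

    print(f"{'feature set':28s} {'kind':17s} n  AUC   [95% CI]")
    for spec, res in zip(menu, results):
        print(f"{spec.name:28s} {spec.kind:17s} {len(spec.keys)}  "
              f"{res.auc:.2f}  [{res.ci_low:.2f}, {res.ci_high:.2f}]")
    best = max(results, key=lambda r: r.auc)
    print(f"best set: {best.name} (AUC {best.auc:.2f})")


if __name__ == "__main__":
    main()
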