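#!/usr/bin/env python
"""Assemble the human-readable run summary from the stage outputs.

Regenerates results/report.txt from battery.csv, classification.json and
correlations.csv without recomputing anything.
"""

from pathlib import Path

from specmdd.pipeline import write_report

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    print(write_report(RESULTS))


if __name__ == "__main__":
    main()
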