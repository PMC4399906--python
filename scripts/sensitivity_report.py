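#!/usr/bin/env python
"""Post-hoc sensitivity classification over a power table.

Reads a long-format power table (as written by ``gwss simulate-study``:
columns method, scenario, power) plus a two-column mapping of scenario
pairs to contrast labels, and classifies each method's power drop per
contrast as sensitive (> 0.1), slightly sensitive (0.05-0.1) or
non-sensitive (< 0.05).  This is reporting convenience over existing
output, not a tested operation.

Usage:
  python scripts/sensitivity_report.py power_long.tsv contrasts.tsv

``contrasts.tsv`` columns: contrast_label, baseline_scenario, varied_scenario.
"""

import sys

import pandas as pd


def classify(diff: float) -> str:
    if diff > 0.1:
        return "sensitive"
    if diff >= 0.05:
        return "slightly sensitive"
    return "non-sensitive"


def main(power_path: str, contrasts_path: str):
    power = pd.read_csv(power_path, sep=None, engine="python")
    contrasts = pd.read_csv(contrasts_path, sep=None, engine="python",
                            header=None,
                            names=["label", "baseline", "varied"])
    wide = power.pivot(index="method", columns="scenario", values="power")
    rows = []
    for _, c in contrasts.iterrows():
        for method in wide.index:
            drop = wide.loc[method, c["baseline"]] - wide.loc[method, c["varied"]]
            rows.append({"contrast": c["label"], "method": method,
                         "power_drop": round(float(drop), 3),
                         "class": classify(float(drop))})
    print(pd.DataFrame(rows).to_string(index=False))


if __name__ == "__main__":
    if len(sys.argv) != 3:
        sys.exit(__doc__)
    main(sys.argv[1], sys.argv[2])
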