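#!/usr/bin/env python
"""Reliability report: MAD, variance components, ICC, SEM per parameter.

Builds the 12 parameter series (9 average-frame coordinates + 3 Euler
angles) from the tables written by 02_orientations.py, estimates crossed
random-effects variance components, and writes the per-parameter report to
results/reliability.csv (display rounding) plus a full-precision JSON.
Also writes a small SEM bar chart to results/sem_by_parameter.png.
"""

import json
from pathlib import Path

import pandas as pd

import scapreli as sr

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    coords = pd.read_csv(RESULTS / "coordinates.csv")
    angles = pd.read_csv(RESULTS / "orientations.csv")
    series = sr.build_parameter_series(coords, angles)
    rows = sr.reliability_table(series)
    display = sr.table_to_frame(rows, rounded=True)
    display.to_csv(RESULTS / "reliability.csv", index=False)
    full = sr.table_to_frame(rows, rounded=False)
    full.to_json(RESULTS / "reliability_full.json", orient="records", indent=2)
    print(display.to_string(index=False))

    worst = min((r for r in rows if r.icc_inter == r.icc_inter), key=lambda r: r.icc_inter)
    d = sr.effect_size_from_icc(max(0.0, worst.icc_inter), k=3)
    print(f"\nworst interobserver ICC: {worst.icc_inter:.2f} ({worst.parameter_id}) "
          f"-> effect size d = {d:.2f} for k = 3 observers")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 3.5))
        x = range(len(rows))
        ax.bar([i - 0.2 for i in x], [r.sem_intra for r in rows], 0.4, label="SEM intra")
        ax.bar([i + 0.2 for i in x], [r.sem_inter for r in rows], 0.4, label="SEM inter")
        ax.set_xticks(list(x), [r.parameter_id for r in rows], rotation=45)
        ax.set_ylabel("SEM (mm / deg)")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(RESULTS / "sem_by_parameter.png", dpi=120)
        print(f"figure: {RESULTS / 'sem_by_parameter.png'}")
    except ImportError:
        print("matplotlib unavailable; skipped the SEM figure")


if __name__ == "__main__":
    main()
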