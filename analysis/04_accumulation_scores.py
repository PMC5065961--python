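#!/usr/bin/env python
"""Compare accumulated plume exposure between treatment groups.

Reads the per-bird accumulation scores written by 02, runs the two-sided
Wilcoxon rank-sum comparison of smell-intact (ION) vs anosmic (ONS) birds,
and draws the group boxplot (results/figures/accumulation.png).
"""

import sys
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from plumetrace.plume_stats import AccumulationScore, compare_groups  # noqa: E402


def main():
    df = pd.read_csv(ROOT / "results" / "tables" / "accumulation_scores.csv")
    scores = [AccumulationScore(r.bird, r.group, r.total, r.n_locations)
              for r in df.itertuples()]
    res = compare_groups(scores)
    print("median accumulation score:",
          ", ".join(f"{g} = {m:.4g}" for g, m in res["medians"].items()))
    print(f"Wilcoxon rank-sum ({res['method']}): U = {res['U']:.1f}, "
          f"p = {res['p_value']:.3g}")
    direction = "<=" if res["medians"]["ION"] <= res["medians"]["ONS"] else ">"
    print(f"smell-intact median {direction} anosmic median "
          f"(plume-following predicts <=)")

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    groups = [df.loc[df.group == g, "score"] for g in ("ION", "ONS")]
    ax.boxplot(groups, tick_labels=["smell (ION)", "no smell (ONS)"])
    ax.set_ylabel("accumulated particles per location")
    fig.tight_layout()
    figdir = ROOT / "results" / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    fig.savefig(figdir / "accumulation.png", dpi=120)
    print(f"figure -> {figdir / 'accumulation.png'}")


if __name__ == "__main__":
    main()
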