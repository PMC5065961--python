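#!/usr/bin/env python
"""Plot and summarize the persistence of the modeled olfactory field.

Reads the per-bird lag correlogram written by 02, reports how quickly the
source-contribution rasters decorrelate, and draws the per-individual curves
with the grand mean +- sd band (results/figures/correlogram.png).
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent


def main():
    tables = ROOT / "results" / "tables"
    per = pd.read_csv(tables / "correlogram_birds.csv")
    grand = pd.read_csv(tables / "correlogram_grand.csv")

    r1 = grand.loc[grand.lag_h == 1, "mean_r"].iloc[0]
    r24 = grand.loc[grand.lag_h == 24, "mean_r"].iloc[0]
    near_zero = grand.loc[grand.mean_r < 0.05, "lag_h"]
    print(f"grand mean correlation: {r1:.3f} at lag 1 h, {r24:.3f} at lag 24 h")
    if len(near_zero):
        print(f"correlation first drops below 0.05 at lag {near_zero.iloc[0]} h")

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for bird, df in per.groupby("bird"):
        ax.plot(df.lag_h, df.mean_r, lw=0.7, alpha=0.5)
    ax.plot(grand.lag_h, grand.mean_r, "k-", lw=2, label="mean")
    ax.plot(grand.lag_h, grand.mean_r + grand.sd_r, "k--", lw=1, label="+- sd")
    ax.plot(grand.lag_h, grand.mean_r - grand.sd_r, "k--", lw=1)
    ax.set_xlabel("lag (h)")
    ax.set_ylabel("mean raster correlation")
    ax.legend()
    fig.tight_layout()
    figdir = ROOT / "results" / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    fig.savefig(figdir / "correlogram.png", dpi=120)
    print(f"figure -> {figdir / 'correlogram.png'}")


if __name__ == "__main__":
    main()
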