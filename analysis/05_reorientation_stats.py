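#!/usr/bin/env python
"""Reorientation after corridor-plume exposure: circular and contingency tests.

Reads the turn records written by 02 and reruns the statistics a reader will
care about: the group x reoriented contingency test, the V test of
post-exposure bearings against the plume-arrival direction, the paired
Hotelling test of before vs after bearings, and the regression of turn
magnitude on the plume-relative arrival angle (the "steeper correction for
headwind information" pattern). Draws the angle-turn scatter
(results/figures/angle_turn.png).
"""

import sys
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from plumetrace.geo import wrap360  # noqa: E402
from plumetrace.reorientation import (TurnRecord, angle_turn_relation,  # noqa: E402
                                      chi_square_contingency, hotelling_paired,
                                      v_test)


def main():
    tables = ROOT / "results" / "tables"
    turns = pd.read_csv(tables / "turn_records.csv")
    exposure = pd.read_csv(tables / "exposure_events.csv")

    exposed_birds = exposure.query("exposed").groupby("bird").size()
    groups = exposure.groupby("bird")["group"].first()
    reo = turns.set_index("bird")["reoriented"]
    table = np.zeros((2, 2), dtype=int)
    for bird, grp in groups.items():
        table[0 if grp == "ION" else 1,
              0 if bool(reo.get(bird, False)) else 1] += 1
    x2, df_, p = chi_square_contingency(table)
    print(f"exposed birds: {len(exposed_birds)} of {len(groups)}")
    print(f"contingency (group x reoriented) {table.tolist()}: "
          f"X2 = {x2:.2f}, df = {df_}, p = {p:.3g}")

    reo_df = turns.query("reoriented")
    angles = wrap360(reo_df.bearing_after - reo_df.plume_bearing)
    v = v_test(angles, mu0=360.0)
    print(f"V test (after-bearing vs plume direction): n = {v.n}, "
          f"r = {v.r:.2f}, mean = {v.mean_direction:.0f} deg, p = {v.p_value:.3g}")
    h = hotelling_paired(reo_df.bearing_before, reo_df.bearing_after)
    print(f"paired Hotelling (before vs after): F = {h.statistic:.1f}, "
          f"p = {h.p_value:.3g}")

    recs = [TurnRecord(r.bird, r.bearing_before, r.bearing_after,
                       r.plume_bearing) for r in reo_df.itertuples()]
    fit = angle_turn_relation(recs)
    print(f"turn ~ plume-relative angle: slope = {fit['slope']:.2f}, "
          f"r = {fit['correlation']:.2f}, p = {fit['p_value']:.3g}")

    fig, ax = plt.subplots(figsize=(5, 4.5))
    x = reo_df.plume_relative_angle
    y = reo_df.delta
    ax.scatter(x, y, c="tab:blue")
    xs = np.linspace(x.min(), x.max(), 10)
    ax.plot(xs, fit["intercept"] + fit["slope"] * xs, "k--", lw=1)
    ax.set_xlabel("plume arrival angle relative to flight direction (deg)")
    ax.set_ylabel("change in flight direction (deg)")
    fig.tight_layout()
    figdir = ROOT / "results" / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    fig.savefig(figdir / "angle_turn.png", dpi=120)
    print(f"figure -> {figdir / 'angle_turn.png'}")


if __name__ == "__main__":
    main()
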