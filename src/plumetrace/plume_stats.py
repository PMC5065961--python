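"""Raster-sequence statistics: time-lag correlogram and accumulation scores.

The correlogram asks how persistent the modeled olfactory information field
is: for each bird and each lag of 1..48 h it correlates randomly sampled pairs
of source-contribution rasters separated by that lag. The accumulation score
asks how much modeled plume material a bird "collected" along its journey:
for every hourly raster, sample the field at the bird's later actively-moving
positions, sum, and normalize by the number of track locations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import Track, active_mask

log = logging.getLogger(__name__)


def raster_correlation(r1, r2) -> float:
    """Pearson correlation of two rasters over all (flattened) cells.

    Returns ``nan`` (undefined marker) when either raster has zero variance.
    Raises on mismatched grids.
    """
    if not r1.same_grid(r2):
        raise ValueError("rasters are on different grids")
    a = r1.values.ravel()
    b = r2.values.ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class CorrelogramResult:
    per_individual: pd.DataFrame     # columns: bird, group, lag_h, mean_r, n_pairs
    grand: pd.DataFrame              # columns: lag_h, mean_r, sd_r, n_birds

    def grand_mean_at(self, lag: int) -> float:
        row = self.grand[self.grand["lag_h"] == lag]
        return float(row["mean_r"].iloc[0]) if len(row) else float("nan")


def correlogram(series_by_bird: dict, max_lag: int = 48,
                pairs_per_lag: int = 50, seed: int = 0,
                groups: dict | None = None) -> CorrelogramResult:
    """Mean raster correlation per bird as a function of time lag.

    Parameters
    ----------
    series_by_bird : dict
        ``bird_id -> list of (time_epoch_s, SourceRaster)`` hourly series.
    max_lag, pairs_per_lag :
        Lags 1..max_lag hours; up to ``pairs_per_lag`` random pairs (without
        replacement) per bird per lag.
    """
    if not series_by_bird:
        raise ValueError("no raster series supplied")
    rng = np.random.default_rng(seed)
    rows = []
    for bird, series in sorted(series_by_bird.items()):
        if len(series) < 2:
            raise ValueError(f"bird {bird}: need at least 2 rasters")
        times = np.array([round(t) for t, _ in series])
        rasters = [r for _, r in series]
        t2i = {int(t): i for i, t in enumerate(times)}
        for lag in range(1, max_lag + 1):
            pairs = [(i, t2i[int(t) + lag * 3600]) for i, t in enumerate(times)
                     if int(t) + lag * 3600 in t2i]
            if not pairs:
                continue
            if len(pairs) > pairs_per_lag:
                sel = rng.choice(len(pairs), size=pairs_per_lag, replace=False)
                pairs = [pairs[j] for j in sel]
            rs = np.array([raster_correlation(rasters[i], rasters[j])
                           for i, j in pairs])
            ok = ~np.isnan(rs)
            if (~ok).any():
                log.debug("bird %s lag %d: skipped %d zero-variance pair(s)",
                          bird, lag, int((~ok).sum()))
            if not ok.any():
                continue
            rows.append({"bird": bird,
                         "group": (groups or {}).get(bird, ""),
                         "lag_h": lag,
                         "mean_r": float(rs[ok].mean()),
                         "n_pairs": int(ok.sum())})
    per = pd.DataFrame(rows)
    if per.empty:
        raise ValueError("no valid lag pairs found in any series")
    grand = (per.groupby("lag_h")["mean_r"]
             .agg(mean_r="mean", sd_r="std", n_birds="count")
             .reset_index())
    return CorrelogramResult(per_individual=per, grand=grand)


@dataclass
class AccumulationScore:
    bird_id: str
    group: str
    total: float
    n_locations: int

    @property
    def score(self) -> float:
        return self.total / self.n_locations


def accumulation_score(raster_series, track: Track, v_min: float = 2.0,
                       positions: str = "future",
                       sampling: str = "bilinear") -> AccumulationScore:
    """Per-bird accumulated particle density normalized by track length.

    For each raster at time t, the field is sampled at the track positions
    with timestamps strictly later than t that pass the activity filter
    (ground speed >= ``v_min``); the sampled values are summed over positions
    and rasters and divided by the total number of track locations.

    ``positions="current"`` instead samples only the bird's own position at
    each raster time (the alternative reading of the score; active positions
    only).
    """
    if positions not in ("future", "current"):
        raise ValueError("positions must be 'future' or 'current'")
    n_loc = len(track)
    if n_loc == 0:
        raise ValueError("empty track")
    act = active_mask(track, v_min=v_min)
    if not act.any():
        log.warning("track %s: no active positions; score is 0", track.bird_id)
        return AccumulationScore(track.bird_id, track.group, 0.0, n_loc)
    tsec = track.epoch_seconds()
    lon, lat = track.lon, track.lat
    total = 0.0
    for entry in raster_series:
        _, t, raster = entry
        if positions == "future":
            sel = act & (tsec > t + 1e-6)
        else:
            sel = act & (np.abs(tsec - t) < 1.0)
        if not sel.any():
            continue
        vals = np.atleast_1d(raster.sample(lon[sel], lat[sel], method=sampling))
        total += float(vals.sum())
    return AccumulationScore(track.bird_id, track.group, total, n_loc)


def compare_groups(scores) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of the two groups.

    Uses the exact null distribution for combined n <= 20 without ties, and
    the tie-corrected normal approximation otherwise. Returns the U statistic
    of the first (ION) group, the p-value, and per-group medians.
    """
    by_group: dict[str, list] = {}
    for s in scores:
        by_group.setdefault(s.group, []).append(s.score)
    if len(by_group) != 2:
        raise ValueError(f"expected exactly two groups, got {sorted(by_group)}")
    g1, g2 = sorted(by_group)           # "ION" before "ONS"
    x, y = np.asarray(by_group[g1]), np.asarray(by_group[g2])
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    n = len(x) + len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": method,
        "medians": {g1: float(np.median(x)), g2: float(np.median(y))},
        "n": {g1: len(x), g2: len(y)},
    }


def scores_table(scores) -> pd.DataFrame:
    return pd.DataFrame([{"bird": s.bird_id, "group": s.group,
                          "total": s.total, "n_locations": s.n_locations,
                          "score": s.score} for s in scores])
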