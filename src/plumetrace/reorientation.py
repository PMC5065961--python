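"""Corridor-plume exposure, reorientation geometry and circular statistics.

Exposure asks whether the air arriving at a bird carried material from its
population's migratory corridor: the fraction of a source-contribution
raster's mass lying inside the corridor polygon, thresholded. For exposed
birds, the plume-arrival bearing (direction FROM which the corridor air
arrived, taken over the last 30 km of the particles' approach) is compared
with the bird's flight directions over path windows before and after the
exposure. The hypothesis tests mirror classical circular statistics: the
V test for concentration around a prespecified direction, the paired
Hotelling test on before/after direction vectors, plus a Pearson chi-square
contingency test and an OLS angle-turn regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import stats

from .geo import bearing, circular_mean_deg, gc_distance, wrap_signed
from .tracks import Track, window_bearing

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Exposure and plume geometry


@dataclass
class ExposureEvent:
    bird_id: str
    time: float                  # epoch seconds
    index: int                   # receptor index on the hourly track
    lon: float
    lat: float
    corridor_fraction: float
    exposed: bool
    plume_bearing: float = float("nan")
    plume_resultant: float = float("nan")


def corridor_exposure(raster, corridor, threshold: float = 0.05):
    """Fraction of raster mass whose cell centers fall inside the polygon.

    Returns ``(corridor_fraction, exposed)``; a zero-mass raster has fraction
    0 by convention.
    """
    if corridor is None or corridor.is_empty or not corridor.is_valid:
        raise ValueError("invalid corridor polygon")
    total = raster.values.sum()
    if total <= 0:
        return 0.0, False
    gx, gy = np.meshgrid(raster.lon_centers, raster.lat_centers)
    inside = shapely.contains_xy(corridor, gx.ravel(), gy.ravel()).reshape(gx.shape)
    frac = float(raster.values[inside].sum() / total)
    return frac, frac >= threshold


def plume_bearing(ensemble, receptor=None, trail_m: float = 30_000.0):
    """Mean direction FROM which the arriving air approached the receptor.

    For each particle, take its position at the first backward age at which it
    was at least ``trail_m`` (default 30 km) from the receptor — i.e. where it
    was last 30 km away on its way in — and the bearing from the receptor to
    that upstream position. Returns ``(circular mean bearing, resultant
    length)`` across particles; ``(nan, 0)`` when no particle ever reaches
    ``trail_m``.
    """
    rec = receptor or ensemble.receptor
    d = gc_distance(ensemble.lon, ensemble.lat,
                    np.full_like(ensemble.lon, rec.lon),
                    np.full_like(ensemble.lat, rec.lat))
    far = np.asarray(d) >= trail_m           # (n_steps+1, n_particles)
    far &= ensemble.alive
    any_far = far.any(axis=0)
    if not any_far.any():
        return float("nan"), 0.0
    first = np.argmax(far, axis=0)           # first age index beyond trail_m
    cols = np.flatnonzero(any_far)
    lon_u = ensemble.lon[first[cols], cols]
    lat_u = ensemble.lat[first[cols], cols]
    brgs = bearing(np.full(cols.shape, rec.lon), np.full(cols.shape, rec.lat),
                   lon_u, lat_u)
    mean, r = circular_mean_deg(brgs)
    return mean, r


# ---------------------------------------------------------------------------
# Turn records


@dataclass
class TurnRecord:
    bird_id: str
    bearing_before: float
    bearing_after: float
    plume_bearing: float
    before_truncated: bool = False
    after_truncated: bool = False

    @property
    def delta(self) -> float:
        """Signed heading change, degrees in (-180, 180], positive clockwise."""
        return wrap_signed(self.bearing_after - self.bearing_before)

    @property
    def plume_relative_angle(self) -> float:
        """Signed angle of the plume-arrival direction relative to the
        pre-exposure flight direction."""
        return wrap_signed(self.plume_bearing - self.bearing_before)


def turn_analysis(track: Track, event: ExposureEvent,
                  before_m: float = 500_000.0,
                  after_m: float = 200_000.0) -> TurnRecord:
    """Before/after flight bearings around an exposure event.

    ``bearing_before`` is the bearing from the start of the before-window to
    the event position; ``bearing_after`` from the event position to the end
    of the after-window. Windows are measured along the path and flagged
    (not rejected) when the track is too short for the full distance.
    """
    bb, btrunc = window_bearing(track, event.index, before_m, "before")
    ba, atrunc = window_bearing(track, event.index, after_m, "after")
    return TurnRecord(bird_id=event.bird_id, bearing_before=bb,
                      bearing_after=ba, plume_bearing=event.plume_bearing,
                      before_truncated=btrunc, after_truncated=atrunc)


# ---------------------------------------------------------------------------
# Circular and contingency statistics


@dataclass
class CircTestResult:
    n: int
    mean_direction: float
    r: float
    statistic: float
    p_value: float
    name: str


def v_test(angles_deg, mu0: float) -> CircTestResult:
    """V test for clustering of angles around a prespecified direction mu0.

    V = n * r * cos(mean - mu0); u = V * sqrt(2/n); one-sided p from the
    standard-normal upper tail of u.
    """
    a = np.asarray(angles_deg, dtype=float)
    n = len(a)
    if n < 2:
        raise ValueError("v_test needs at least 2 angles")
    mean, r = circular_mean_deg(a)
    V = n * r * np.cos(np.radians(mean - mu0))
    u = V * np.sqrt(2.0 / n)
    p = float(stats.norm.sf(u))
    return CircTestResult(n=n, mean_direction=mean, r=r, statistic=float(u),
                          p_value=p, name="V")


def hotelling_paired(before_deg, after_deg) -> CircTestResult:
    """Paired Hotelling test on before/after directions.

    Each pair contributes the difference of its unit vectors,
    d_i = (cos a_i - cos b_i, sin a_i - sin b_i); T^2 = n * dbar' S^-1 dbar
    with S the sample covariance of the d_i, and
    F = ((n - 2) / (2 (n - 1))) * T^2 with (2, n - 2) degrees of freedom.
    All-zero differences (no change at all) are reported as p = 1 by
    convention; an otherwise singular covariance raises.
    """
    b = np.radians(np.asarray(before_deg, dtype=float))
    a = np.radians(np.asarray(after_deg, dtype=float))
    if len(a) != len(b):
        raise ValueError("before/after must have equal lengths")
    n = len(a)
    if n < 3:
        raise ValueError("paired Hotelling test needs n >= 3")
    d = np.column_stack([np.cos(a) - np.cos(b), np.sin(a) - np.sin(b)])
    mean_after, r_after = circular_mean_deg(np.degrees(a))
    if np.allclose(d, 0.0):
        return CircTestResult(n=n, mean_direction=mean_after, r=r_after,
                              statistic=0.0, p_value=1.0, name="Hotelling-F")
    dbar = d.mean(axis=0)
    S = np.cov(d, rowvar=False)
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular covariance of difference vectors: {e}")
    T2 = float(n * dbar @ Sinv @ dbar)
    F = (n - 2) / (2.0 * (n - 1)) * T2
    p = float(stats.f.sf(F, 2, n - 2))
    return CircTestResult(n=n, mean_direction=mean_after, r=r_after,
                          statistic=float(F), p_value=p, name="Hotelling-F")


def chi_square_contingency(table, correction: bool = False):
    """Pearson chi-square test of independence on a counts table.

    Returns ``(X2, df, p)``. No continuity correction by default. A zero
    row or column margin raises.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row/column margin: test undefined")
    res = stats.chi2_contingency(t, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def angle_turn_relation(records) -> dict:
    """OLS of the heading change on the plume-relative arrival angle.

    Both variables are signed degrees on the (-180, 180] branch. Returns
    slope, intercept, Pearson correlation and its t-test p-value.
    """
    recs = list(records)
    if len(recs) < 3:
        raise ValueError("need at least 3 turn records")
    x = np.array([r.plume_relative_angle for r in recs])
    y = np.array([r.delta for r in recs])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in plume-relative angles")
    if np.ptp(y) == 0:
        # a flat response is a valid (null) outcome, not an error
        return {"slope": 0.0, "intercept": float(y[0]), "correlation": 0.0,
                "p_value": 1.0, "n": len(recs)}
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "correlation": float(res.rvalue), "p_value": float(res.pvalue),
            "n": len(recs)}
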