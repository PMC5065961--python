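"""Bird GPS tracks: Movebank-style CSV I/O, hourly interpolation and path geometry.

A :class:`Track` is a time-ordered sequence of (timestamp, lon, lat) positions
for one individual, together with its treatment group: ``ION`` for birds with
intact olfactory nerves (smell-capable) and ``ONS`` for birds whose olfactory
nerves were sectioned (anosmic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import bearing, gc_distance

log = logging.getLogger(__name__)

GROUPS = ("ION", "ONS")

#: required columns of the track CSV format (Movebank-like)
CSV_COLUMNS = ("individual-local-identifier", "timestamp",
               "location-long", "location-lat", "group")


@dataclass
class Track:
    """One individual's timestamped positions.

    Attributes
    ----------
    bird_id : str
    group : str
        ``"ION"`` (intact olfaction) or ``"ONS"`` (olfactory nerves sectioned).
    data : pandas.DataFrame
        Columns ``time`` (datetime64, UTC), ``lon``, ``lat`` (degrees) and
        ``interpolated`` (bool; True for positions added by
        :func:`interpolate_hourly`). Strictly increasing timestamps.
    flags : dict
        Free-form provenance flags (e.g. ``terminated="left_domain"``).
    """

    bird_id: str
    group: str
    data: pd.DataFrame
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        d = self.data
        for col in ("time", "lon", "lat"):
            if col not in d.columns:
                raise ValueError(f"track data missing column {col!r}")
        if "interpolated" not in d.columns:
            d = d.assign(interpolated=False)
        t = d["time"].to_numpy()
        if len(t) > 1 and not (np.diff(t.astype("datetime64[ns]").astype(np.int64)) > 0).all():
            raise ValueError("track timestamps must be strictly increasing")
        lon = d["lon"].to_numpy(dtype=float)
        lat = d["lat"].to_numpy(dtype=float)
        if np.any((lon < -180) | (lon >= 180)):
            raise ValueError("longitude out of [-180, 180)")
        if np.any((lat < -90) | (lat > 90)):
            raise ValueError("latitude out of [-90, 90]")
        self.data = d.reset_index(drop=True)

    def __len__(self):
        return len(self.data)

    @property
    def lon(self):
        return self.data["lon"].to_numpy(dtype=float)

    @property
    def lat(self):
        return self.data["lat"].to_numpy(dtype=float)

    @property
    def times(self):
        """Timestamps as numpy datetime64[ns]."""
        return self.data["time"].to_numpy().astype("datetime64[ns]")

    def epoch_seconds(self):
        return self.times.astype("datetime64[s]").astype(np.int64).astype(float)


def read_track(path) -> Track:
    """Read one track from a Movebank-style CSV file.

    Rows are sorted chronologically; duplicate timestamps are collapsed to the
    first occurrence with a warning. Validation errors name the offending
    (1-based, header excluded) row.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    try:
        times = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        # find the offending row for a useful message
        for i, v in enumerate(df["timestamp"]):
            try:
                pd.to_datetime(v, utc=True)
            except (ValueError, TypeError):
                raise ValueError(f"{path}: unparseable timestamp {v!r} in row {i + 1}")
        raise
    lon = df["location-long"].astype(float)
    lat = df["location-lat"].astype(float)
    bad = (lon < -180) | (lon >= 180) | (lat < -90) | (lat > 90)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: coordinate out of range in row {i + 1} "
            f"(lon={lon.iloc[i]}, lat={lat.iloc[i]})")
    ids = df["individual-local-identifier"].astype(str).unique()
    if len(ids) != 1:
        raise ValueError(f"{path}: expected one individual per file, found {list(ids)}")
    groups = df["group"].astype(str).unique()
    if len(groups) != 1:
        raise ValueError(f"{path}: expected one group per file, found {list(groups)}")

    out = pd.DataFrame({
        "time": times.dt.tz_convert("UTC").dt.tz_localize(None),
        "lon": lon, "lat": lat,
    }).sort_values("time", kind="stable")
    ndup = out["time"].duplicated().sum()
    if ndup:
        log.warning("%s: collapsed %d duplicate timestamp(s) to first occurrence",
                    path, ndup)
        out = out[~out["time"].duplicated()]
    out["interpolated"] = False
    return Track(bird_id=str(ids[0]), group=str(groups[0]), data=out)


def write_track(track: Track, path) -> None:
    """Write a track in the CSV layout understood by :func:`read_track`."""
    df = pd.DataFrame({
        "individual-local-identifier": track.bird_id,
        "timestamp": pd.Series(track.times).dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
        "location-long": track.data["lon"].to_numpy(),
        "location-lat": track.data["lat"].to_numpy(),
        "group": track.group,
        "interpolated": track.data["interpolated"].to_numpy(),
    })
    df.to_csv(path, index=False)


def interpolate_hourly(track: Track) -> Track:
    """Add positions at every whole hour between consecutive observations.

    Interpolation is linear independently in lon and lat (a straight-line
    connection in coordinate space); original observed points are preserved
    exactly and new points are flagged ``interpolated=True``.
    """
    if len(track) < 2:
        raise ValueError("hourly interpolation needs at least 2 points")
    t = track.times
    tsec = track.epoch_seconds()
    lon, lat = track.lon, track.lat

    rows = [track.data.iloc[[0]]]
    for i in range(len(t) - 1):
        t0, t1 = tsec[i], tsec[i + 1]
        # whole hours strictly inside the (t0, t1) interval
        first = np.ceil(t0 / 3600.0 + 1e-9) * 3600.0
        hours = np.arange(first, t1 - 1e-9, 3600.0)
        hours = hours[hours > t0 + 1e-9]
        if len(hours):
            f = (hours - t0) / (t1 - t0)
            rows.append(pd.DataFrame({
                "time": np.array(hours, dtype="datetime64[s]").astype("datetime64[ns]"),
                "lon": lon[i] + f * (lon[i + 1] - lon[i]),
                "lat": lat[i] + f * (lat[i + 1] - lat[i]),
                "interpolated": True,
            }))
        rows.append(track.data.iloc[[i + 1]])
    out = pd.concat(rows, ignore_index=True)
    return Track(track.bird_id, track.group, out, dict(track.flags))


def segment_speeds(track: Track):
    """Ground speed (m/s) of each segment between consecutive points."""
    d = gc_distance(track.lon[:-1], track.lat[:-1], track.lon[1:], track.lat[1:])
    dt = np.diff(track.epoch_seconds())
    return np.asarray(d) / dt


def active_mask(track: Track, v_min: float = 2.0):
    """Flag points where the bird is actively moving.

    A point is active iff the speed over the segment from it to the next point
    is >= ``v_min`` (default 2 m/s); the last point inherits the preceding
    segment's flag.
    """
    if len(track) < 2:
        raise ValueError("active_mask needs at least 2 points")
    v = segment_speeds(track)
    mask = np.empty(len(track), dtype=bool)
    mask[:-1] = v >= v_min
    mask[-1] = mask[-2]
    return mask


def path_window(track: Track, anchor_index: int, distance_m: float, direction: str):
    """Contiguous sub-track covering ``distance_m`` of along-path length.

    Walks from ``anchor_index`` backward (``direction="before"``) or forward
    (``direction="after"``) accumulating great-circle segment lengths until
    ``distance_m`` is first reached. Returns ``(sub_track_indices, truncated)``
    where ``truncated`` is True when the track ends before the distance is
    reached (the maximal available window is returned).
    """
    if direction not in ("before", "after"):
        raise ValueError("direction must be 'before' or 'after'")
    n = len(track)
    if not 0 <= anchor_index < n:
        raise IndexError(f"anchor_index {anchor_index} outside track of length {n}")
    if distance_m <= 0:
        return np.array([anchor_index]), False
    lon, lat = track.lon, track.lat
    idx = [anchor_index]
    total = 0.0
    step = -1 if direction == "before" else 1
    i = anchor_index
    while 0 < i if step < 0 else i < n - 1:
        j = i + step
        total += gc_distance(lon[i], lat[i], lon[j], lat[j])
        idx.append(j)
        i = j
        if total >= distance_m - 1e-6:      # micro-tolerance for exact ties
            break
    truncated = total < distance_m
    idx = np.array(sorted(idx))
    return idx, truncated


def window_bearing(track: Track, anchor_index: int, distance_m: float, direction: str):
    """Endpoint-to-endpoint bearing of a before/after path window.

    For ``before`` the bearing runs from the window start to the anchor; for
    ``after`` from the anchor to the window end — i.e. always along the
    direction of travel. Returns ``(bearing_deg, truncated)``.
    """
    idx, truncated = path_window(track, anchor_index, distance_m, direction)
    if len(idx) < 2:
        raise ValueError(f"empty {direction}-window at index {anchor_index}")
    lon, lat = track.lon, track.lat
    if direction == "before":
        a, b = idx[0], anchor_index
    else:
        a, b = anchor_index, idx[-1]
    return bearing(lon[a], lat[a], lon[b], lat[b]), truncated
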