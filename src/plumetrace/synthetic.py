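"""Seeded synthetic study generator: wind fields, corridor geometry, agent tracks.

This module produces the complete synthetic analog of a displacement
experiment: a smooth, temporally varying gridded wind field; a migratory
corridor and a goal region (GeoJSON polygons); and hourly agent tracks that
either do ("reactive", labeled ION for intact olfactory nerves) or do not
("non-reactive", labeled ONS for sectioned olfactory nerves) reorient toward
the corridor when wind-borne plume information from it reaches them.

Wind model
----------
``u``/``v`` are a mean flow whose direction may rotate at a constant rate,
plus a zero-mean sum of two traveling sinusoidal waves (prescribed amplitude,
spatial wavelength, temporal period; the second wave runs at incommensurate
wavelength/period so the field never exactly repeats). ``w`` is zero. This is
deliberately not mesoscale meteorology: it is smooth, seeded, and controllable
enough that correlograms decay with lag the way a real wind history makes
them decay.

Agent model
-----------
Agents fly great-circle segments at cruise speed on a baseline compass
heading, one step per hour. At every step a kinematic *exposure oracle*
reports the corridor mass fraction of the air arriving at the agent and the
plume-arrival bearing. Reactive agents whose exposure exceeds their threshold
rotate their heading toward the plume-arrival bearing by ``turn_gain`` per
step (turn_gain=1 snaps onto the plume direction); non-reactive agents ignore
the oracle entirely. Tracks end on leaving the domain or after a maximum
duration; an agent that reaches a rest region (the corridor stopover or the
goal) settles there and keeps logging stationary hourly fixes — the analog of
a bird resting at a known stopover site, which the downstream 2 m/s activity
filter then treats as inactive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon, shape, mapping

from .dispersion import WindField
from .geo import destination, wrap_signed, wrap360
from .tracks import Track, write_track
import pandas as pd

log = logging.getLogger(__name__)

GOLDEN = (1 + 5 ** 0.5) / 2


@dataclass
class WindParams:
    """Parameters of the synthetic wind model.

    mean_u, mean_v : m/s — mean flow at time zero.
    amplitude : m/s — total amplitude of the zero-mean perturbation waves.
    wavelength_deg : degrees — spatial wavelength of the primary wave.
    period_h : hours or None — temporal period of the primary wave; None
        freezes the perturbation in time (a time-invariant field when the
        rotation rate is also zero).
    rotation_deg_per_h : degrees/hour — rotation rate of the mean-flow
        direction (compass sense: positive rotates the TO-direction clockwise).
    rotation_start_h : hours after the field's start time at which the
        rotation begins (the mean flow is steady before that).
    """

    mean_u: float = 8.0
    mean_v: float = 0.0
    amplitude: float = 1.5
    wavelength_deg: float = 8.0
    period_h: float | None = 30.0
    rotation_deg_per_h: float = 0.0
    rotation_start_h: float = 0.0


@dataclass
class ScenarioSpec:
    """Complete description of one synthetic study."""

    lon_bounds: tuple = (2.0, 20.0)
    lat_bounds: tuple = (34.0, 60.0)
    start_time: str = "2015-08-01T00:00:00"        # UTC
    duration_h: float = 120.0
    wind_res_deg: float = 0.5
    wind_dt_h: float = 1.0
    wind: WindParams = field(default_factory=WindParams)
    corridor_lonlat: tuple = ((11.0, 38.0), (14.5, 38.0),
                              (14.5, 55.0), (11.0, 55.0))
    goal_lonlat: tuple = ((11.0, 34.5), (14.5, 34.5),
                          (14.5, 38.0), (11.0, 38.0))
    n_birds_reactive: int = 10
    n_birds_nonreactive: int = 10
    track_start_h: float = 36.0       # hours after field start (look-back margin)
    track_max_h: float = 72.0
    seed: int = 0

    def __post_init__(self):
        if not (self.lon_bounds[0] < self.lon_bounds[1]
                and self.lat_bounds[0] < self.lat_bounds[1]):
            raise ValueError("degenerate domain bounds")
        if self.duration_h <= 0:
            raise ValueError("time span must be positive (start < end)")
        if self.n_birds_reactive < 0 or self.n_birds_nonreactive < 0:
            raise ValueError("bird counts must be >= 0")
        dom = shapely.box(self.lon_bounds[0], self.lat_bounds[0],
                          self.lon_bounds[1], self.lat_bounds[1])
        for name in ("corridor", "goal"):
            if not dom.covers(self.polygon(name)):
                raise ValueError(f"{name} polygon not inside domain bounds")

    def polygon(self, which: str) -> Polygon:
        pts = self.corridor_lonlat if which == "corridor" else self.goal_lonlat
        return Polygon(pts)

    @property
    def t0_epoch(self) -> float:
        return float(np.datetime64(self.start_time, "s").astype(np.int64))


@dataclass
class AgentBehavior:
    """One agent's flight rule."""

    cruise_speed: float = 10.0        # m/s
    baseline_heading: float = 180.0   # degrees clockwise from North
    reactive: bool = True
    turn_gain: float = 0.6            # in [0, 1]
    exposure_threshold: float = 0.05  # corridor mass fraction triggering reaction

    def __post_init__(self):
        if self.cruise_speed <= 0:
            raise ValueError("cruise_speed must be > 0")
        if not (0.0 <= self.baseline_heading < 360.0):
            raise ValueError("baseline_heading must be in [0, 360)")
        if not (0.0 <= self.turn_gain <= 1.0):
            raise ValueError("turn_gain must be in [0, 1]")


# ---------------------------------------------------------------------------
# Wind field generation


def gen_wind_field(spec: ScenarioSpec) -> WindField:
    """Deterministic smooth wind field for a scenario (see module docstring).

    With zero perturbation amplitude and zero rotation the field is exactly
    the constant mean flow. The perturbation waves have seeded random phases
    and zero spatial-temporal mean by construction.
    """
    p = spec.wind
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    lon = np.arange(spec.lon_bounds[0], spec.lon_bounds[1] + 1e-9, spec.wind_res_deg)
    lat = np.arange(spec.lat_bounds[0], spec.lat_bounds[1] + 1e-9, spec.wind_res_deg)
    t_h = np.arange(0.0, spec.duration_h + 1e-9, spec.wind_dt_h)
    level = np.array([0.0, 5000.0])
    t_epoch = spec.t0_epoch + t_h * 3600.0

    T, Y, X = np.meshgrid(t_h, lat, lon, indexing="ij")

    # rotate the mean vector clockwise (compass sense) by the accrued angle;
    # exact identity (no trig round-off) when the rotation rate is zero
    rot = np.radians(p.rotation_deg_per_h * np.maximum(0.0, T - p.rotation_start_h))
    u = p.mean_u * np.cos(rot) + p.mean_v * np.sin(rot)
    v = p.mean_v * np.cos(rot) - p.mean_u * np.sin(rot)

    if p.amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=8)
        waves_u = np.zeros_like(u)
        waves_v = np.zeros_like(v)
        for i, (wl, per) in enumerate(
                [(p.wavelength_deg, p.period_h),
                 (p.wavelength_deg / GOLDEN,
                  None if p.period_h is None else p.period_h / GOLDEN)]):
            tf = 0.0 if per is None else T / per
            ph = phases[4 * i:4 * i + 4]
            waves_u += np.sin(2 * np.pi * (X / wl + tf) + ph[0]) \
                * np.cos(2 * np.pi * Y / wl + ph[1])
            waves_v += np.sin(2 * np.pi * (Y / wl + tf) + ph[2]) \
                * np.cos(2 * np.pi * X / wl + ph[3])
        u = u + (p.amplitude / 2.0) * waves_u
        v = v + (p.amplitude / 2.0) * waves_v

    # replicate over the (dynamically passive) vertical axis
    u4 = np.repeat(u[:, None, :, :], len(level), axis=1)
    v4 = np.repeat(v[:, None, :, :], len(level), axis=1)
    w4 = np.zeros_like(u4)
    return WindField(lon_axis=lon, lat_axis=lat, level_axis=level,
                     time_axis=t_epoch, u=u4, v=v4, w=w4)


# ---------------------------------------------------------------------------
# Kinematic exposure oracle


class KinematicPlumeOracle:
    """Cheap deterministic stand-in for the full backward dispersion run.

    Traces a single backward trajectory (pure advection, no diffusion) from a
    query position/time through the wind field and reports (a) the fraction of
    the look-back horizon the trajectory spends inside the corridor polygon
    and (b) the bearing from the query point to the trajectory position where
    the air was last ``trail_m`` away on its approach — the plume-arrival
    direction. Used to drive agent behavior during track generation; the
    analysis pipeline re-derives exposure independently from the particle
    model.
    """

    def __init__(self, wf: WindField, corridor: Polygon, horizon_h: float = 36.0,
                 dt_s: float = 1800.0, trail_m: float = 30_000.0):
        self.wf = wf
        self.corridor = corridor
        self.horizon_h = horizon_h
        self.dt_s = dt_s
        self.trail_m = trail_m

    def __call__(self, lon: float, lat: float, t_epoch: float):
        from .geo import M_PER_DEG_LAT, gc_distance, bearing as geo_bearing
        nsteps = int(round(self.horizon_h * 3600.0 / self.dt_s))
        x, y = float(lon), float(lat)
        t = float(t_epoch)
        inside = 0
        plume_brg = float("nan")
        lo_lon, hi_lon = self.wf.lon_axis[0], self.wf.lon_axis[-1]
        lo_lat, hi_lat = self.wf.lat_axis[0], self.wf.lat_axis[-1]
        for _ in range(nsteps):
            u, v, _w = self.wf.interp(x, y, 15.0, t)
            u, v = float(u[0]), float(v[0])
            x -= u * self.dt_s / (M_PER_DEG_LAT * np.cos(np.radians(y)))
            y -= v * self.dt_s / M_PER_DEG_LAT
            t -= self.dt_s
            if not (lo_lon <= x <= hi_lon and lo_lat <= y <= hi_lat):
                break
            if np.isnan(plume_brg) and gc_distance(lon, lat, x, y) >= self.trail_m:
                plume_brg = geo_bearing(lon, lat, x, y)
            if shapely.contains_xy(self.corridor, x, y):
                inside += 1
        return inside / nsteps, plume_brg


# ---------------------------------------------------------------------------
# Agent tracks


def gen_track(spec: ScenarioSpec, behavior: AgentBehavior, start,
              exposure_oracle, bird_id: str = "agent", group: str | None = None,
              start_time_epoch: float | None = None,
              rest_regions=()) -> Track:
    """Simulate one agent's hourly track (see module docstring for the rule).

    ``start`` is (lon, lat); ``exposure_oracle(lon, lat, t_epoch)`` returns
    ``(corridor_fraction, plume_bearing_deg)``. Leaving the domain terminates
    the track with a flag, not an error; entering a rest region makes the
    agent hold position (stationary hourly fixes) for the rest of the span.
    """
    lon0, lat0 = start
    if not (spec.lon_bounds[0] <= lon0 <= spec.lon_bounds[1]
            and spec.lat_bounds[0] <= lat0 <= spec.lat_bounds[1]):
        raise ValueError("start position outside domain")
    if group is None:
        group = "ION" if behavior.reactive else "ONS"
    t0 = (spec.t0_epoch + spec.track_start_h * 3600.0
          if start_time_epoch is None else float(start_time_epoch))

    heading = behavior.baseline_heading
    lon, lat, t = float(lon0), float(lat0), float(t0)
    times, lons, lats = [t], [lon], [lat]
    flags = {}
    resting = False
    n_steps = int(spec.track_max_h)
    for _ in range(n_steps):
        if resting:
            t += 3600.0
            times.append(t), lons.append(lon), lats.append(lat)
            continue
        frac, brg = exposure_oracle(lon, lat, t)
        if behavior.reactive and frac >= behavior.exposure_threshold \
                and np.isfinite(brg):
            heading = wrap360(heading + behavior.turn_gain
                              * wrap_signed(brg - heading))
        lon2, lat2 = destination(lon, lat, heading, behavior.cruise_speed * 3600.0)
        lon2, lat2 = float(lon2), float(lat2)
        t2 = t + 3600.0
        if not (spec.lon_bounds[0] <= lon2 <= spec.lon_bounds[1]
                and spec.lat_bounds[0] <= lat2 <= spec.lat_bounds[1]):
            flags["terminated"] = "left_domain"
            break
        lon, lat, t = lon2, lat2, t2
        times.append(t), lons.append(lon), lats.append(lat)
        if any(shapely.contains_xy(rg, lon, lat) for rg in rest_regions):
            flags["rested_at_region"] = True
            resting = True
    data = pd.DataFrame({
        "time": np.array(times, dtype="float64").astype("datetime64[s]").astype("datetime64[ns]"),
        "lon": lons, "lat": lats, "interpolated": False,
    })
    return Track(bird_id=bird_id, group=group, data=data, flags=flags)


# ---------------------------------------------------------------------------
# Whole scenarios


@dataclass
class ScenarioBundle:
    spec: ScenarioSpec
    wind: WindField
    corridor: Polygon
    goal: Polygon
    tracks: list
    manifest: dict


def default_behaviors(spec: ScenarioSpec, rng: np.random.Generator):
    """Per-agent behaviors and start points for a scenario.

    Reactive and non-reactive agents draw from the same distributions of
    start position (a band displaced west of the corridor) and baseline
    heading (southbound +- 3 degrees), differing only in whether they respond
    to the exposure oracle — the synthetic analog of the intact vs
    nerve-sectioned treatment groups.
    """
    out = []
    n_total = spec.n_birds_reactive + spec.n_birds_nonreactive
    for i in range(n_total):
        reactive = i < spec.n_birds_reactive
        behavior = AgentBehavior(
            cruise_speed=10.0,
            baseline_heading=float(wrap360(177.0 + 6.0 * rng.random())),
            reactive=reactive,
            turn_gain=0.6,
            exposure_threshold=0.05,
        )
        start = (8.0 + 1.0 * rng.random(), 54.5 + 2.0 * rng.random())
        out.append((behavior, start))
    return out


def gen_scenario(spec: ScenarioSpec, out_dir=None,
                 behaviors=None) -> ScenarioBundle:
    """Generate a complete synthetic study (wind, regions, tracks, manifest).

    Reactive agents are labeled ION (smell-intact), non-reactive ONS
    (anosmic). With ``out_dir`` set, writes wind NetCDF, GeoJSON regions, one
    CSV per track, and a JSON manifest recording the spec and seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    wind = gen_wind_field(spec)
    corridor = spec.polygon("corridor")
    goal = spec.polygon("goal")
    oracle = KinematicPlumeOracle(wind, corridor)
    if behaviors is None:
        behaviors = default_behaviors(spec, rng)

    tracks = []
    for i, (behavior, start) in enumerate(behaviors):
        grp = "ION" if behavior.reactive else "ONS"
        bird_id = f"{grp}{i:02d}"
        tracks.append(gen_track(spec, behavior, start, oracle, bird_id=bird_id,
                                rest_regions=(corridor, goal)))

    manifest = {
        "seed": spec.seed,
        "spec": _spec_dict(spec),
        "groups": {tr.bird_id: tr.group for tr in tracks},
        "n_tracks": len(tracks),
        "track_lengths": {tr.bird_id: len(tr) for tr in tracks},
        "track_flags": {tr.bird_id: tr.flags for tr in tracks},
    }
    bundle = ScenarioBundle(spec=spec, wind=wind, corridor=corridor, goal=goal,
                            tracks=tracks, manifest=manifest)
    if out_dir is not None:
        write_scenario(bundle, out_dir)
    return bundle


def _spec_dict(spec: ScenarioSpec) -> dict:
    d = asdict(spec)
    d["wind"] = asdict(spec.wind)
    return d


def write_scenario(bundle: ScenarioBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        bundle.wind.to_netcdf(out / "wind.nc")
        for which, poly in (("corridor", bundle.corridor), ("goal", bundle.goal)):
            with open(out / f"{which}.geojson", "w") as fh:
                json.dump({"type": "Feature", "properties": {"name": which},
                           "geometry": mapping(poly)}, fh)
        for tr in bundle.tracks:
            write_track(tr, out / f"track_{tr.bird_id}.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    except OSError as e:
        raise OSError(f"failed writing scenario to {out}: {e}") from e


def read_region(path) -> Polygon:
    with open(path) as fh:
        gj = json.load(fh)
    geom = gj["geometry"] if gj.get("type") == "Feature" else gj
    return shape(geom)


# ---------------------------------------------------------------------------
# The default demonstration scenario


def demo_spec(seed: int = 0) -> ScenarioSpec:
    """The package's reference desk-scale displacement scenario.

    A ~1,300 x 2,900 km domain; agents start in the north-west and migrate
    south, displaced west of their corridor (a meridional band to the east).
    The mean flow starts westerly and rotates at +9 degrees/hour once the
    tracks begin, so plume information from the corridor reaches the agents
    (wind from the east) roughly a day into their journey — late enough that
    a 500 km before-window exists, early enough that reactive agents can turn
    and reach the corridor stopover. As the rotation continues through south,
    corridor air later arrives along the migration axis itself, repeatedly
    exposing the still-moving non-reactive agents without deflecting the
    reactive ones (which are resting by then).
    """
    return ScenarioSpec(
        wind=WindParams(mean_u=12.0, mean_v=0.0, amplitude=1.5,
                        wavelength_deg=8.0, period_h=30.0,
                        rotation_deg_per_h=9.0, rotation_start_h=36.0),
        seed=seed,
    )
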