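"""Simplified backward Lagrangian particle dispersion.

For each receptor — a bird location and time with a short reception window in
the lowest 0–30 m of air — an ensemble of massless tracer particles is
released and stepped *backward* in time through a gridded wind field. Each
particle carries the deterministic advection by the interpolated wind plus a
constant-diffusivity Gaussian random walk (horizontal diffusivity ``kh``,
vertical ``kz``, reflecting ground). Binning the particles' residence time on
an output grid and multiplying by a spatially uniform emission rate yields a
source-contribution raster: how strongly each surface cell could have
contributed material to the air arriving at the receptor (the
source-receptor-sensitivity reading of a backward run).

The model keeps the semantics of a full transport model's backward
("retroplume") mode — uniform constant emissions, a maximum particle travel
age, altitude layers summed, a fixed-resolution output grid — while replacing
boundary-layer turbulence parametrizations with a constant-K random walk.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import xarray as xr

from .geo import M_PER_DEG_LAT

log = logging.getLogger(__name__)

__all__ = [
    "WindField", "DispersionConfig", "Receptor", "SourceRaster",
    "ParticleEnsemble", "interpolate_wind", "advect_backward",
    "source_contribution", "run_receptor_series",
]


# ---------------------------------------------------------------------------
# Wind fields


@dataclass
class WindField:
    """Gridded u/v/w wind components on (time, level, lat, lon) axes.

    ``time_axis`` is float seconds since the Unix epoch (UTC); ``level_axis``
    is meters above ground. All axes strictly increasing, all values finite.
    """

    lon_axis: np.ndarray
    lat_axis: np.ndarray
    level_axis: np.ndarray
    time_axis: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        for name in ("lon_axis", "lat_axis", "level_axis", "time_axis"):
            ax = np.asarray(getattr(self, name), dtype=float)
            if ax.ndim != 1 or len(ax) == 0:
                raise ValueError(f"{name} must be a non-empty 1-D array")
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} must be strictly increasing")
            setattr(self, name, ax)
        shape = (len(self.time_axis), len(self.level_axis),
                 len(self.lat_axis), len(self.lon_axis))
        for name in ("u", "v", "w"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)

    # -- I/O ---------------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {k: (("time", "level", "lat", "lon"), getattr(self, k),
                 {"units": "m s-1"}) for k in ("u", "v", "w")},
            coords={
                "time": ("time", self.time_axis,
                         {"units": "seconds since 1970-01-01T00:00:00Z"}),
                "level": ("level", self.level_axis, {"units": "m"}),
                "lat": ("lat", self.lat_axis, {"units": "degrees_north"}),
                "lon": ("lon", self.lon_axis, {"units": "degrees_east"}),
            },
            attrs={"Conventions": "CF-1.6"},
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "WindField":
        with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
            return cls(
                lon_axis=ds["lon"].values, lat_axis=ds["lat"].values,
                level_axis=ds["level"].values, time_axis=ds["time"].values,
                u=ds["u"].values, v=ds["v"].values, w=ds["w"].values,
            )

    # -- interpolation -----------------------------------------------------
    def interp(self, lon, lat, z, t):
        """Multilinear interpolation of (u, v, w) at query points.

        ``lon``, ``lat``, ``z`` may be arrays; ``t`` a scalar or an array of
        the same shape (seconds since epoch). Spatial/vertical queries are
        clamped to the grid; a query time outside the time axis by more than
        one time step raises.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        z = np.broadcast_to(np.asarray(z, dtype=float), lon.shape)
        t = np.broadcast_to(np.asarray(t, dtype=float), lon.shape)

        ta = self.time_axis
        step = ta[-1] - ta[-2] if len(ta) > 1 else np.inf
        tmin, tmax = ta[0], ta[-1]
        if np.any(t < tmin - step) or np.any(t > tmax + step):
            bad = t[(t < tmin - step) | (t > tmax + step)][0]
            raise ValueError(
                f"query time {bad!r} (epoch s) outside wind time axis "
                f"[{tmin}, {tmax}] by more than one step")

        idx_w = []
        for ax, q, clamp_note in ((self.lon_axis, lon, "lon"),
                                  (self.lat_axis, lat, "lat"),
                                  (self.level_axis, z, "level"),
                                  (ta, t, "time")):
            if len(ax) == 1:
                idx_w.append((np.zeros(q.shape, dtype=np.intp),
                              np.zeros(q.shape, dtype=np.intp),
                              np.zeros(q.shape)))
                continue
            qc = np.clip(q, ax[0], ax[-1])
            i1 = np.clip(np.searchsorted(ax, qc, side="right"), 1, len(ax) - 1)
            i0 = i1 - 1
            f = (qc - ax[i0]) / (ax[i1] - ax[i0])
            idx_w.append((i0, i1, f))

        (xi0, xi1, xf), (yi0, yi1, yf), (zi0, zi1, zf), (ti0, ti1, tf) = idx_w

        def gather(arr):
            out = np.zeros(lon.shape)
            for tw, ti in ((1 - tf, ti0), (tf, ti1)):
                for zw, zi in ((1 - zf, zi0), (zf, zi1)):
                    tz = tw * zw
                    if np.all(tz == 0):
                        continue
                    for yw, yi in ((1 - yf, yi0), (yf, yi1)):
                        for xw, xi in ((1 - xf, xi0), (xf, xi1)):
                            wgt = tz * yw * xw
                            out += wgt * arr[ti, zi, yi, xi]
            return out

        return gather(self.u), gather(self.v), gather(self.w)


def interpolate_wind(wf: WindField, lon, lat, z, t):
    """Functional alias for :meth:`WindField.interp` (scalar-friendly)."""
    u, v, w = wf.interp(lon, lat, z, t)
    if np.ndim(lon) == 0:
        return float(u[0]), float(v[0]), float(w[0])
    return u, v, w


# ---------------------------------------------------------------------------
# Configuration and receptors


@dataclass(frozen=True)
class DispersionConfig:
    """Simulator settings.

    The reference configuration of the study this mirrors used 100,000
    particles per receptor, a 3-day maximum particle age, a 0.2-degree output
    grid, altitude layers with tops at 100 / 3,000 / 50,000 m, a 5-minute
    reception window and a 0–30 m receptor layer. ``n_particles`` defaults to
    a desk-scale 10,000; raise it for production runs.
    """

    n_particles: int = 10_000
    max_age_h: float = 72.0
    dt: float = 600.0                      # s
    kh: float = 5_000.0                    # m^2/s horizontal diffusivity
    kz: float = 10.0                       # m^2/s vertical diffusivity
    out_res: float = 0.2                   # degrees
    layer_tops: tuple = (100.0, 3000.0, 50_000.0)   # m
    reception_window: float = 300.0        # s
    receptor_layer: tuple = (0.0, 30.0)    # m
    emission_rate: float = 1.0             # relative units per s of residence
    seed: int = 0
    boundary: str = "terminate"            # terminate | reflect | wrap_lon

    def __post_init__(self):
        if self.n_particles <= 0 or self.dt <= 0 or self.max_age_h <= 0:
            raise ValueError("n_particles, dt and max_age_h must be positive")
        if self.out_res <= 0:
            raise ValueError("out_res must be positive")
        if self.kh < 0 or self.kz < 0:
            raise ValueError("diffusivities must be non-negative")
        if not np.all(np.diff(self.layer_tops) > 0):
            raise ValueError("layer_tops must be strictly increasing")
        if not self.receptor_layer[0] < self.receptor_layer[1]:
            raise ValueError("receptor_layer must be an increasing pair")
        if self.boundary not in ("terminate", "reflect", "wrap_lon"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.max_age_h * 3600.0 / self.dt))

    def digest(self) -> str:
        payload = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass(frozen=True)
class Receptor:
    """A target location and time at which arriving air is evaluated."""

    lon: float
    lat: float
    time: float          # seconds since epoch, UTC
    window: float = 300.0

    def __post_init__(self):
        if not (-180.0 <= self.lon < 180.0):
            raise ValueError(f"lon {self.lon} outside [-180, 180)")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"lat {self.lat} outside [-90, 90]")


@dataclass
class ParticleEnsemble:
    """Backward trajectories of one receptor's particle release.

    ``lon``/``lat``/``z`` have shape (n_steps + 1, n_particles): row k is the
    position at age ``k * dt`` before reception (row 0 = release at the
    receptor). ``alive[k, p]`` is True while particle p is still inside the
    domain at age k*dt; once a particle leaves (boundary mode ``terminate``)
    it stays dead. ``release_times`` are per-particle reception times within
    the receptor window.
    """

    receptor: Receptor
    config: DispersionConfig
    lon: np.ndarray
    lat: np.ndarray
    z: np.ndarray
    alive: np.ndarray
    release_times: np.ndarray

    @property
    def n_particles(self) -> int:
        return self.lon.shape[1]

    def residence_seconds(self) -> float:
        """Total in-domain particle residence time (s), summed over the ensemble.

        Each completed backward step contributes ``dt`` for every particle
        still alive after the step.
        """
        return float(self.alive[1:].sum()) * self.config.dt


@dataclass
class SourceRaster:
    """Gridded source contribution for one receptor (values >= 0, lat x lon)."""

    lon_centers: np.ndarray
    lat_centers: np.ndarray
    values: np.ndarray        # (lat, lon)
    receptor: Receptor
    config_digest: str
    layers: np.ndarray | None = None   # optional (n_layers, lat, lon)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lat_centers), len(self.lon_centers)):
            raise ValueError("raster shape inconsistent with axes")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("raster values must be finite and non-negative")

    def total(self) -> float:
        return float(self.values.sum())

    def same_grid(self, other: "SourceRaster") -> bool:
        return (len(self.lon_centers) == len(other.lon_centers)
                and len(self.lat_centers) == len(other.lat_centers)
                and np.allclose(self.lon_centers, other.lon_centers)
                and np.allclose(self.lat_centers, other.lat_centers))

    def sample(self, lon, lat, method: str = "bilinear"):
        """Sample the raster at points (bilinear in cell-center space by default)."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        xc, yc = self.lon_centers, self.lat_centers
        if method == "nearest":
            xi = np.clip(np.rint((lon - xc[0]) / (xc[1] - xc[0])).astype(int), 0, len(xc) - 1)
            yi = np.clip(np.rint((lat - yc[0]) / (yc[1] - yc[0])).astype(int), 0, len(yc) - 1)
            out = self.values[yi, xi]
        elif method == "bilinear":
            out = _bilinear(self.values, xc, yc, lon, lat)
        else:
            raise ValueError(f"unknown sampling method {method!r}")
        return out if out.size > 1 else float(out[0])

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"source_contribution": (("lat", "lon"), self.values)},
            coords={"lat": self.lat_centers, "lon": self.lon_centers},
            attrs={
                "receptor_lon": self.receptor.lon,
                "receptor_lat": self.receptor.lat,
                "receptor_time": self.receptor.time,
                "config_digest": self.config_digest,
            },
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")


def _bilinear(values, xc, yc, lon, lat):
    xq = np.clip(lon, xc[0], xc[-1])
    yq = np.clip(lat, yc[0], yc[-1])
    xi1 = np.clip(np.searchsorted(xc, xq, side="right"), 1, len(xc) - 1)
    yi1 = np.clip(np.searchsorted(yc, yq, side="right"), 1, len(yc) - 1)
    xi0, yi0 = xi1 - 1, yi1 - 1
    fx = (xq - xc[xi0]) / (xc[xi1] - xc[xi0])
    fy = (yq - yc[yi0]) / (yc[yi1] - yc[yi0])
    return ((1 - fy) * (1 - fx) * values[yi0, xi0]
            + (1 - fy) * fx * values[yi0, xi1]
            + fy * (1 - fx) * values[yi1, xi0]
            + fy * fx * values[yi1, xi1])


# ---------------------------------------------------------------------------
# Backward advection


def advect_backward(receptor: Receptor, wf: WindField, cfg: DispersionConfig,
                    rng: np.random.Generator | None = None) -> ParticleEnsemble:
    """Release particles at a receptor and step them backward in time.

    Particles are released uniformly over the reception window, with initial
    heights uniform in the receptor layer, then stepped backward with step
    ``dt``: displacement ``-(u, v) * dt`` plus Gaussian increments of standard
    deviation ``sqrt(2*kh*dt)`` per horizontal axis and ``sqrt(2*kz*dt)``
    vertically, reflected at the ground. Meter displacements become degrees
    via the local per-latitude metric. Deterministic given ``cfg.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    earliest = receptor.time - receptor.window - cfg.max_age_h * 3600.0
    ta = wf.time_axis
    tstep = ta[-1] - ta[-2] if len(ta) > 1 else np.inf
    if earliest < ta[0] - tstep:
        raise ValueError(
            f"receptor at epoch {receptor.time}s needs wind back to {earliest}s "
            f"but the wind time axis starts at {ta[0]}s")

    n = cfg.n_particles
    nsteps = cfg.n_steps
    release = receptor.time - rng.uniform(0.0, receptor.window, size=n)
    lon = np.empty((nsteps + 1, n))
    lat = np.empty((nsteps + 1, n))
    z = np.empty((nsteps + 1, n))
    alive = np.zeros((nsteps + 1, n), dtype=bool)
    lon[0] = receptor.lon
    lat[0] = receptor.lat
    z[0] = rng.uniform(cfg.receptor_layer[0], cfg.receptor_layer[1], size=n)
    alive[0] = True

    sig_h = np.sqrt(2.0 * cfg.kh * cfg.dt)
    sig_z = np.sqrt(2.0 * cfg.kz * cfg.dt)
    lon_lo, lon_hi = wf.lon_axis[0], wf.lon_axis[-1]
    lat_lo, lat_hi = wf.lat_axis[0], wf.lat_axis[-1]

    cur_lon, cur_lat, cur_z = lon[0].copy(), lat[0].copy(), z[0].copy()
    cur_alive = alive[0].copy()
    for k in range(1, nsteps + 1):
        t_now = release - (k - 1) * cfg.dt
        u, v, w = wf.interp(cur_lon, cur_lat, cur_z, t_now)
        dx = -u * cfg.dt
        dy = -v * cfg.dt
        dz = -w * cfg.dt
        if cfg.kh > 0:
            dx = dx + rng.normal(0.0, sig_h, size=n)
            dy = dy + rng.normal(0.0, sig_h, size=n)
        if cfg.kz > 0:
            dz = dz + rng.normal(0.0, sig_z, size=n)
        coslat = np.cos(np.radians(np.clip(cur_lat, -89.9, 89.9)))
        nxt_lon = cur_lon + dx / (M_PER_DEG_LAT * coslat)
        nxt_lat = cur_lat + dy / M_PER_DEG_LAT
        nxt_z = np.abs(cur_z + dz)          # reflect at ground

        if cfg.boundary == "wrap_lon":
            span = lon_hi - lon_lo
            nxt_lon = lon_lo + np.mod(nxt_lon - lon_lo, span)
            nxt_lat = np.clip(nxt_lat, lat_lo, lat_hi)
        elif cfg.boundary == "reflect":
            nxt_lon = _reflect(nxt_lon, lon_lo, lon_hi)
            nxt_lat = _reflect(nxt_lat, lat_lo, lat_hi)
        else:   # terminate on domain exit
            out = ((nxt_lon < lon_lo) | (nxt_lon > lon_hi)
                   | (nxt_lat < lat_lo) | (nxt_lat > lat_hi))
            cur_alive = cur_alive & ~out
            nxt_lon = np.clip(nxt_lon, lon_lo, lon_hi)
            nxt_lat = np.clip(nxt_lat, lat_lo, lat_hi)

        cur_lon, cur_lat, cur_z = nxt_lon, nxt_lat, nxt_z
        lon[k], lat[k], z[k] = cur_lon, cur_lat, cur_z
        alive[k] = cur_alive

    return ParticleEnsemble(receptor=receptor, config=cfg, lon=lon, lat=lat,
                            z=z, alive=alive, release_times=release)


def _reflect(x, lo, hi):
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


# ---------------------------------------------------------------------------
# Gridding


def make_output_grid(lon_lo, lon_hi, lat_lo, lat_hi, res):
    """Cell-center axes at (k + 0.5)*res offsets from the (lon_lo, lat_lo) origin."""
    nx = max(1, int(np.ceil((lon_hi - lon_lo) / res - 1e-9)))
    ny = max(1, int(np.ceil((lat_hi - lat_lo) / res - 1e-9)))
    lon_c = lon_lo + (np.arange(nx) + 0.5) * res
    lat_c = lat_lo + (np.arange(ny) + 0.5) * res
    return lon_c, lat_c


def source_contribution(ensemble: ParticleEnsemble, cfg: DispersionConfig,
                        grid=None) -> SourceRaster:
    """Bin an ensemble's residence time onto the output grid.

    Each particle alive after a backward step deposits ``dt * emission_rate``
    into the half-open cell [west, east) x [south, north) containing its
    post-step horizontal position, accumulated per altitude layer and then
    summed over layers and ages. Total raster mass therefore equals
    ``emission_rate`` x the ensemble's in-domain residence time (for particles
    below the top layer boundary).
    """
    if grid is None:
        raise ValueError("an explicit grid (lon_centers, lat_centers) is required")
    lon_c, lat_c = grid
    res_x = lon_c[1] - lon_c[0] if len(lon_c) > 1 else cfg.out_res
    res_y = lat_c[1] - lat_c[0] if len(lat_c) > 1 else cfg.out_res
    west = lon_c[0] - res_x / 2.0
    south = lat_c[0] - res_y / 2.0

    tops = np.asarray(cfg.layer_tops, dtype=float)
    nlay = len(tops)
    layers = np.zeros((nlay, len(lat_c), len(lon_c)))
    dt_q = cfg.dt * cfg.emission_rate
    for k in range(1, ensemble.lon.shape[0]):
        m = ensemble.alive[k]
        if not m.any():
            break
        xs, ys, zs = ensemble.lon[k][m], ensemble.lat[k][m], ensemble.z[k][m]
        xi = np.floor((xs - west) / res_x).astype(np.intp)
        yi = np.floor((ys - south) / res_y).astype(np.intp)
        li = np.searchsorted(tops, zs, side="left")
        keep = ((xi >= 0) & (xi < len(lon_c)) & (yi >= 0) & (yi < len(lat_c))
                & (li < nlay))
        np.add.at(layers, (li[keep], yi[keep], xi[keep]), dt_q)

    return SourceRaster(lon_centers=np.asarray(lon_c, dtype=float),
                        lat_centers=np.asarray(lat_c, dtype=float),
                        values=layers.sum(axis=0),
                        receptor=ensemble.receptor,
                        config_digest=cfg.digest(),
                        layers=layers)


def receptor_seed(base_seed: int, index: int) -> np.random.Generator:
    """Deterministic per-receptor RNG independent of execution order."""
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(index,)))


def run_receptor_series(track, wf: WindField, cfg: DispersionConfig,
                        grid=None, keep_ensembles: bool = False):
    """One source-contribution raster per hourly track position.

    Positions whose look-back window would leave the wind data's time span are
    skipped with a warning. Per-receptor seeds derive deterministically from
    ``(cfg.seed, receptor index)``. Returns a list of
    ``(index, time_epoch_s, SourceRaster)`` tuples in track order (plus the
    ensembles when ``keep_ensembles``).
    """
    if len(track) == 0:
        raise ValueError("empty track")
    if grid is None:
        grid = make_output_grid(wf.lon_axis[0], wf.lon_axis[-1],
                                wf.lat_axis[0], wf.lat_axis[-1], cfg.out_res)
    tsec = track.epoch_seconds()
    lon, lat = track.lon, track.lat
    out = []
    ensembles = []
    for i in range(len(track)):
        rec = Receptor(lon=float(lon[i]), lat=float(lat[i]), time=float(tsec[i]),
                       window=cfg.reception_window)
        try:
            ens = advect_backward(rec, wf, cfg, rng=receptor_seed(cfg.seed, i))
        except ValueError as e:
            log.warning("skipping receptor %d of track %s: %s", i, track.bird_id, e)
            continue
        out.append((i, float(tsec[i]), source_contribution(ens, cfg, grid=grid)))
        if keep_ensembles:
            ensembles.append((i, ens))
    if keep_ensembles:
        return out, ensembles
    return out
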