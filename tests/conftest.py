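import numpy as np
import pandas as pd
import pytest

from plumetrace.dispersion import WindField
from plumetrace.tracks import Track


def uniform_wind(u=10.0, v=0.0, lon=(-5.0, 5.0), lat=(-5.0, 5.0),
                 res=1.0, t0=0.0, hours=48, levels=(0.0, 1000.0)) -> WindField:
    """Constant wind field on a small grid (times in epoch seconds from t0)."""
    lon_ax = np.arange(lon[0], lon[1] + 1e-9, res)
    lat_ax = np.arange(lat[0], lat[1] + 1e-9, res)
    lev_ax = np.asarray(levels, dtype=float)
    t_ax = t0 + np.arange(hours + 1) * 3600.0
    shape = (len(t_ax), len(lev_ax), len(lat_ax), len(lon_ax))
    return WindField(lon_ax, lat_ax, lev_ax, t_ax,
                     np.full(shape, float(u)), np.full(shape, float(v)),
                     np.zeros(shape))


def hourly_track(lons, lats, t0_epoch=0.0, bird_id="b1", group="ION") -> Track:
    n = len(lons)
    times = (t0_epoch + np.arange(n) * 3600.0).astype("datetime64[s]")
    return Track(bird_id, group, pd.DataFrame({
        "time": times.astype("datetime64[ns]"),
        "lon": np.asarray(lons, dtype=float),
        "lat": np.asarray(lats, dtype=float),
        "interpolated": False,
    }))


@pytest.fixture(scope="session")
def demo_results():
    """One shared desk-scale demo run (the reference synthetic study)."""
    from plumetrace.pipeline import make_demo
    return make_demo(seed=1, n_particles=200)


@pytest.fixture(scope="session")
def demo_bundle(demo_results):
    return demo_results["bundle"]
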