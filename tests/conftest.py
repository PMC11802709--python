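import numpy as np
import pandas as pd
import pytest

from flocknet import DetectionStream, WorldConfig, make_world


def make_stream(times, individuals, antenna="A1", location="L1", epoch=None):
    """Build a DetectionStream from parallel time/individual lists."""
    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "individual": list(individuals),
        "antenna": antenna,
        "location": location,
    })
    kw = {"epoch": epoch} if epoch is not None else {}
    return DetectionStream(df=df, **kw)


def random_stream(rng, n=30, n_individuals=5, t_max=60.0, n_locations=1):
    inds = [f"B{i}" for i in rng.integers(0, n_individuals, size=n)]
    locs = [f"L{i}" for i in rng.integers(0, n_locations, size=n)]
    df = pd.DataFrame({
        "time": np.sort(rng.uniform(0, t_max, size=n)),
        "individual": inds,
        "antenna": "A1",
        "location": locs,
    })
    return DetectionStream(df=df)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_world():
    cfg = WorldConfig(n_individuals=12, n_units=3, p_join=0.8, sigma_social=0.5,
                      solo_rate=0.3, flock_rate=1.0, arrival_jitter_sd=10.0,
                      stay_mean=20.0, p_read=0.7, hours_per_day=1.0,
                      n_weeks=2, seed=11)
    return make_world(cfg)
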