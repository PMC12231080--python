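import numpy as np
import pandas as pd
import pytest

from fireprogress import GridSpec, SpreadParams, sample_detections, simulate_fire
from fireprogress.landcover import CODE, LandcoverGrid
from fireprogress.pipeline import make_fixture


@pytest.fixture(scope="session")
def barrier_ring():
    """Landscape with a closed impermeable aspen annulus and the fire it
    confines (dense, unjittered detections)."""
    return make_fixture("barrier_ring")


@pytest.fixture(scope="session")
def two_day_strip():
    """Rectangular burn split into days {1, 2} at a known Voronoi bisector."""
    return make_fixture("two_day_strip")


@pytest.fixture(scope="session")
def spot_fire():
    """DOB grid with an isolated day-3 spot-fire patch and its detection."""
    return make_fixture("spot_fire")


@pytest.fixture(scope="session")
def dense_fire():
    """A moderate stochastic fire with every burned cell detected exactly.

    Used wherever a realistic patch mosaic with exact ground truth is
    needed (oracle comparisons, round trips).
    """
    spec = GridSpec(60, 60)
    classes = np.full(spec.shape, CODE["warm_conifer"], dtype=np.int16)
    lc = LandcoverGrid(spec, classes)
    params = SpreadParams(base_spread_prob=0.4, max_days=18, rng_seed=21,
                          substeps_per_day=2)
    fire = simulate_fire(lc, (30, 30), params, fire_id="dense")
    fire.detections = sample_detections(fire.true_dob, rate=100.0,
                                        jitter_sigma=0.0, seed=21,
                                        fire_id="dense")
    return {"landcover": lc, "fire": fire}


def synth_patch_table(rng, n_fires=40, patches_per_fire=20, slope=-0.008,
                      intercept_mean=3.0, intercept_sd=0.3, resid_sd=0.3,
                      response="y"):
    """Synthetic patch table with known mixed-model generative truth.

    Per-fire random intercepts ~ N(intercept_mean, intercept_sd^2); aspen
    cover in percent ~ U(0, 60); response = intercept + slope * aspen + eps
    with eps ~ N(0, resid_sd^2).
    """
    rows = []
    for f in range(n_fires):
        a_f = rng.normal(intercept_mean, intercept_sd)
        aspen = rng.uniform(0.0, 60.0, patches_per_fire)
        y = a_f + slope * aspen + rng.normal(0.0, resid_sd, patches_per_fire)
        for val, asp in zip(y, aspen):
            rows.append({"fire_id": f"f{f:03d}", "aspen_pct": asp, response: val})
    return pd.DataFrame(rows)
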