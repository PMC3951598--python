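"""Shared fixtures: downscaled synthetic datasets so unit tests stay fast.

The 64x64 image grid keeps the full study structure (designs, kinetics,
panel, masks) at ~1/16 the pixel count of the default simulation size.
"""

import numpy as np
import pytest

import bakevision as bv


@pytest.fixture(scope="session")
def fast_cfg() -> bv.SimulationConfig:
    return bv.SimulationConfig(image_size=(64, 64), cookie_radius_px=24)


@pytest.fixture(scope="session")
def set1_fast(fast_cfg):
    return bv.generate_set("set1", fast_cfg, seed=0)


@pytest.fixture(scope="session")
def masks1_fast(set1_fast):
    return [bv.segment(img) for img in set1_fast.images]


@pytest.fixture(scope="session")
def set2_fast(fast_cfg):
    return bv.generate_set("set2", fast_cfg, seed=500)


@pytest.fixture(scope="session")
def masks2_fast(set2_fast):
    return [bv.segment(img) for img in set2_fast.images]


@pytest.fixture(scope="session")
def fda_fast(set1_fast, masks1_fast):
    """Browning model trained on the fast first set, with class limits."""
    labels = [
        bv.consensus_class(r.votes_under, r.votes_adequate, r.votes_over)
        for r in set1_fast.records.itertuples()
    ]
    pixels, groups = bv.build_pixel_dataset(set1_fast.images, masks1_fast, labels)
    model = bv.fit_fda(pixels, groups)
    model.wavelengths_nm = set1_fast.images[0].wavelengths_nm
    scores = [
        bv.mean_browning_score(bv.score_pixels(img, m, model), m)
        for img, m in zip(set1_fast.images, masks1_fast)
    ]
    df = set1_fast.records.assign(mean_score=scores)
    limits = bv.compute_class_limits(df.groupby("time_min")["mean_score"].mean().to_dict())
    model.limit_under_adequate, model.limit_adequate_over = limits
    return model, df


@pytest.fixture(scope="session")
def water_xy_fast(set2_fast, masks2_fast):
    """Mean spectra and gravimetric water percent of the fast second set."""
    X = np.vstack(
        [bv.mean_spectrum(img, m) for img, m in zip(set2_fast.images, masks2_fast)]
    )
    y = np.array(
        [
            bv.water_fraction(r.initial_mass_g, r.dried_mass_g)
            for r in set2_fast.records.itertuples()
        ]
    )
    return X, y
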