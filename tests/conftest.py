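import numpy as np
import pytest

from ribofret.simulate import (
    CameraModel,
    DeliveryModel,
    ExpMixture,
    KineticScheme,
    PhotophysicsModel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_state_scheme():
    """Fast two-state exchange with single-exponential dwells."""
    return KineticScheme(
        states=("SEMI", "NON"),
        dwell_dists={"SEMI": ExpMixture.single(0.97), "NON": ExpMixture.single(0.38)},
    )


@pytest.fixture
def photo():
    return PhotophysicsModel(
        fret_means={"SEMI": 0.22, "NON": 0.34, "ROT": 0.17},
        total_intensity=1000.0,
        noise_sd=40.0,
        donor_bleach_tau=200.0,
        acceptor_bleach_tau=400.0,
        background=50.0,
    )


@pytest.fixture
def quiet_photo(photo):
    from dataclasses import replace
    return replace(photo, noise_sd=0.0, background=0.0,
                   donor_bleach_tau=1e9, acceptor_bleach_tau=1e9)


@pytest.fixture
def camera_100ms():
    return CameraModel(exposure_s=0.100, n_frames=600)


@pytest.fixture
def preformed():
    return DeliveryModel(mode="preformed", window_s=60.0, active_fraction=1.0)
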