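import numpy as np
import pytest

import ifshear as ifs


@pytest.fixture
def straight_channel_volume():
    """One noiseless channel along y: analytic tube, exactly rasterised."""
    spec = ifs.PoreVolumeSpec(
        shape=(32, 16, 32),
        spacing=(0.1, 0.1, 0.1),
        n_channels=1,
        lognormal_mu=np.log(0.8),
        lognormal_sigma=0.2,
        orientation_axis=(0, 1, 0),
        orientation_jitter=0.0,
        noise_sd=0.0,
        seed=7,
    )
    vol, gt = ifs.generate_pore_volume(spec)
    return spec, vol, gt


@pytest.fixture
def resting_beat_series():
    """600-s artifact-free series with LF and HF oscillations."""
    spec = ifs.BeatSeriesSpec(seed=11)
    series, gt = ifs.generate_beat_series(spec)
    return spec, series, gt
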