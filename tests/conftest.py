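import numpy as np
import pytest

from spindlequant.frap import FrapTrace, RecoveryParams
from spindlequant.presets import CONDITIONS
from spindlequant.synthetic import ImageSimConfig, TraceSimConfig


@pytest.fixture
def oocyte_params() -> RecoveryParams:
    return CONDITIONS["oocyte_metaphase_I"]


@pytest.fixture
def clean_trace_cfg(oocyte_params) -> TraceSimConfig:
    """Noise- and bleaching-free configuration for exact pipeline checks."""
    return TraceSimConfig(
        params=oocyte_params, noise_sd=0.0, acq_bleach_rate=0.0, seed=0
    )


@pytest.fixture
def flat_image_cfg() -> ImageSimConfig:
    """Noise-free spindle with no pole enrichment: flat axial profile."""
    return ImageSimConfig(pole_enrichment=1.0, noise_sd=0.0, seed=0)


def make_trace(times, intensities, n_pre=3, label=""):
    return FrapTrace(
        times=np.asarray(times, float),
        intensities=np.asarray(intensities, float),
        n_pre=n_pre,
        label=label,
    )
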