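import numpy as np
import pytest

from csfpulse import PhantomSpec, WaveformTerm, generate_cine_series


@pytest.fixture
def plug_spec():
    """Noise-free plug-flow circle phantom with closed-form SV ~= 22.5 uL."""
    return PhantomSpec(
        geometry="circle",
        radius_mm=1.5,
        profile="plug",
        waveform=(WaveformTerm(1.0, 1, 0.0),),
        period_s=1.0,
        n_phases=32,
        venc_cms=10.0,
        pixel_spacing_mm=(0.3, 0.3),
        grid_shape=(32, 32),
    )


@pytest.fixture
def poiseuille_spec(plug_spec):
    """Same phantom with a parabolic velocity profile."""
    return PhantomSpec(
        geometry="circle",
        radius_mm=1.5,
        profile="poiseuille",
        waveform=(WaveformTerm(1.0, 1, 0.0),),
        period_s=1.0,
        n_phases=32,
        venc_cms=10.0,
        pixel_spacing_mm=(0.3, 0.3),
        grid_shape=(32, 32),
    )


@pytest.fixture
def fine_poiseuille_spec():
    """Rasterization-converged (0.1 mm) Poiseuille phantom for chain checks."""
    return PhantomSpec(
        geometry="circle",
        radius_mm=1.5,
        profile="poiseuille",
        waveform=(WaveformTerm(1.0, 1, 0.0),),
        period_s=1.0,
        n_phases=32,
        venc_cms=10.0,
        pixel_spacing_mm=(0.1, 0.1),
        grid_shape=(45, 45),
    )


@pytest.fixture
def plug_series(plug_spec):
    return generate_cine_series(plug_spec)


@pytest.fixture
def lumen_center(plug_series):
    _, truth = plug_series
    return tuple(np.argwhere(truth.lumen_mask_true).mean(axis=0).astype(int))
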