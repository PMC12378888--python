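import numpy as np
import pytest

from nmrdesk.core import AcquisitionMeta, AxisCalibration, Spectrum
from nmrdesk.synthetic import GroundTruth, TruthPeak, generate_fid


@pytest.fixture
def hsqc_meta():
    return AcquisitionMeta(
        n_complex_direct=256, n_complex_indirect=64,
        sw_direct_hz=8000.0, sw_indirect_hz=2000.0,
        obs_direct_mhz=600.13, obs_indirect_mhz=60.81,
        car_direct_ppm=4.7, car_indirect_ppm=118.0,
    )


@pytest.fixture
def three_peak_truth(hsqc_meta):
    peaks = [TruthPeak(8.2, 120.5, 1.0, 30.0, 15.0),
             TruthPeak(7.1, 110.0, 0.7, 30.0, 15.0),
             TruthPeak(6.0, 125.0, 0.5, 30.0, 15.0)]
    return GroundTruth(peaks=peaks, acquisition=hsqc_meta)


@pytest.fixture
def three_peak_td(three_peak_truth):
    return generate_fid(three_peak_truth)


@pytest.fixture
def small_axes():
    ax_d = AxisCalibration.from_carrier(96, 8000.0, 600.13, 4.7 * 600.13)
    ax_i = AxisCalibration.from_carrier(64, 2000.0, 60.81, 118.0 * 60.81)
    return ax_d, ax_i


@pytest.fixture
def random_spectrum(small_axes):
    ax_d, ax_i = small_axes
    rng = np.random.default_rng(42)
    data = rng.normal(size=(1, ax_i.n_points, ax_d.n_points))
    return Spectrum(data_real=data, axis_direct=ax_d, axis_indirect=ax_i)
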