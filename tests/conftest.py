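import numpy as np
import pytest

from vestkit.prescriptions import ExercisePrescription
from vestkit.session import SessionRecord
from vestkit.synthetic import SyntheticSpec, generate_exercise_series


@pytest.fixture(scope="session")
def vor_prescription():
    return ExercisePrescription.default("vor_yaw")


@pytest.fixture(scope="session")
def clean_vor(vor_prescription):
    """Disturbance-free prescribed VOR-yaw trial (neutral-relative)."""
    return generate_exercise_series(SyntheticSpec.clean(vor_prescription))


@pytest.fixture(scope="session")
def noisy_vor(vor_prescription):
    """Default-noise VOR-yaw trial with calibration hold (absolute reference)."""
    return generate_exercise_series(SyntheticSpec(prescription=vor_prescription, seed=7))


@pytest.fixture
def vor_record(vor_prescription, noisy_vor):
    return SessionRecord(
        subject_id="S000",
        condition="app",
        prescription=vor_prescription,
        series=noisy_vor.series,
    )


def sine_series(
    amplitude=20.0, freq=1.0, duration=60.0, fs=50.0, frame="head",
    reference="neutral-relative", channel="yaw",
):
    """Hand-built pure-sinusoid AngleSeries (independent of the generator)."""
    from vestkit.series import AngleSeries

    t = np.arange(int(round(duration * fs))) / fs
    x = amplitude * np.sin(2 * np.pi * freq * t)
    channels = {"roll": np.zeros_like(t), "pitch": np.zeros_like(t), "yaw": np.zeros_like(t)}
    channels[channel] = x
    return AngleSeries(
        t=t, sample_rate_hz=fs, frame=frame, reference=reference, **channels
    )
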