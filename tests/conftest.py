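import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from i2spair.gait_sim import SimConfig, generate_dataset
from i2spair.imu_signals import ImuRecording
from i2spair.pipeline import train_models

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def sine_recording(
    period: float = 1.0,
    duration: float = 10.0,
    fs: float = 200.0,
    axis: int = 2,
    amplitude: float = 100.0,
) -> ImuRecording:
    """Gyro sinusoid on one axis, accelerometer at rest (gravity on Y)."""
    t = np.arange(int(round(duration * fs))) / fs
    gyr = np.zeros((t.size, 3))
    gyr[:, axis] = amplitude * np.sin(2 * np.pi * t / period)
    acc = np.zeros((t.size, 3))
    acc[:, 1] = 1.0
    return ImuRecording(sensor_id="sine", fs=fs, gyr=gyr, acc=acc)


@pytest.fixture(scope="session")
def healthy_cohort():
    bouts, manifest = generate_dataset(SimConfig(n_subjects=12, bouts_per_subject=6, seed=0))
    return bouts


@pytest.fixture(scope="session")
def models(healthy_cohort):
    """Segment + foot-side models trained on a small healthy cohort."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_models(healthy_cohort, run_selection=False)
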