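import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from erpdecode import EpochSet, Montage

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def toy_montage(n_channels: int, seed: int = 0) -> Montage:
    """Generic unit-sphere montage for detector/decoder unit tests; the last
    channel plays the infra-orbital EOG role."""
    rng = np.random.default_rng(seed)
    pos = rng.standard_normal((n_channels, 3))
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    names = tuple(f"ch{i:02d}" for i in range(n_channels - 1)) + ("eogL",)
    return Montage(
        channel_names=names,
        n_scalp=n_channels - 1,
        eog_lower="eogL",
        veog_upper=names[0],
        positions=pos,
    )


def make_epochs(
    data: np.ndarray,
    srate: float = 250.0,
    t0: float = 0.0,
    labels: np.ndarray | None = None,
    M: int = 2,
    montage: Montage | None = None,
) -> EpochSet:
    data = np.asarray(data, dtype=float)
    n_ep, n_ch, n_sa = data.shape
    if labels is None:
        labels = np.arange(n_ep) % M
    return EpochSet(
        data=data,
        times=t0 + np.arange(n_sa) * (1000.0 / srate),
        srate=srate,
        labels=np.asarray(labels),
        M=M,
        montage=montage or toy_montage(n_ch),
        keep=np.ones(n_ep, dtype=bool),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
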