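import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_260_919)


@pytest.fixture()
def toy_recording():
    """A small two-channel labelled recording for windowing tests."""
    from emgrasp.recording import EmgRecording

    gen = np.random.default_rng(5)
    n = 1000
    return EmgRecording(
        samples=gen.standard_normal((n, 2)),
        channel_roles=("extrinsic", "intrinsic"),
        labels=np.full(n, "chuck", dtype=object),
        wrist_condition="static:neutral",
    )


@pytest.fixture(scope="session")
def gaussian_blobs():
    """Three well-separated spherical Gaussian classes in 4-D."""
    gen = np.random.default_rng(11)
    means = np.array([[0.0, 0, 0, 0], [6.0, 0, 3, 0], [0.0, 6, 0, 3]])
    X = np.vstack([gen.normal(m, 1.0, size=(120, 4)) for m in means])
    y = np.repeat(["a", "b", "c"], 120)
    return X, y
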