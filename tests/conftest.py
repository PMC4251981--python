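import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import ndimage

from embryoflow.motion import extract_motion_record
from embryoflow.synthetic import SyntheticConfig, render_sequence

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def texture():
    """Smooth speckle image in [0, 1] with plenty of trackable corners."""
    rng = np.random.default_rng(0)
    img = ndimage.gaussian_filter(rng.normal(size=(200, 200)), 2.0)
    return (img - img.min()) / np.ptp(img)


@pytest.fixture(scope="session")
def rendered_flick():
    """Rendered sequence with three scripted tail flicks, plus its ground truth."""
    cfg = SyntheticConfig(seed=7, n_frames=150, flick_onsets_s=(2.0, 5.0, 8.0))
    seq, truth = render_sequence(cfg)
    return cfg, seq, truth


@pytest.fixture(scope="session")
def rendered_flick_record(rendered_flick):
    """Motion record extracted from the scripted-flick rendering."""
    _, seq, _ = rendered_flick
    return extract_motion_record(seq)
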