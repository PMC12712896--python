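import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from noex import keypoints as kp  # noqa: E402


def make_clean_track(positions, fps=30.0):
    """CleanTrack from per-part (n, 2) arrays; missing parts default to the
    nose positions (collapsed body)."""
    nose = np.asarray(positions["nose"], dtype=float)
    xy = {p: np.asarray(positions.get(p, nose), dtype=float).copy()
          for p in kp.PARTS}
    flags = {p: np.zeros(len(nose), dtype=bool) for p in kp.PARTS}
    return kp.CleanTrack(xy=xy, interpolated=flags, fps=fps)


@pytest.fixture
def arena():
    return kp.ArenaConfig()
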