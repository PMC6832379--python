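import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def full_scale_phantom():
    """Hockey-stick phantom at the radiographs' 0.15 mm/px scale."""
    from femurbow.synthetic import generate_three_arc_femur

    return generate_three_arc_femur()


@pytest.fixture(scope="session")
def coarse_phantom():
    """Small, fast phantom (coarse pixel spacing) for plumbing tests."""
    from femurbow.synthetic import generate_three_arc_femur

    return generate_three_arc_femur(pixel_spacing=0.45, segment_length_mm=80.0)


def rigid_transform(xy, angle_deg, shift):
    """Rotate then translate a point set (test helper)."""
    t = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    return np.atleast_2d(xy) @ rot.T + np.asarray(shift)
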