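import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from arscope import CameraModel, Pose


@pytest.fixture
def simple_camera():
    """Distortion-free 640x480 pinhole used by most geometry tests."""
    return CameraModel(f=600.0, u=320.0, v=240.0, image_size=(640, 480))


@pytest.fixture
def small_camera():
    """Small distortion-free frame for fast render round-trip tests."""
    return CameraModel(f=300.0, u=160.0, v=120.0, image_size=(320, 240))


def random_marker_pose(rng, tilt_max_deg=50.0, tz_range=(380.0, 550.0),
                       lateral=(30.0, 20.0)):
    """A random marker pose: off-plane tilt about a random in-plane axis,
    arbitrary in-plane spin, bounded lateral offset and depth (mm)."""
    tilt = np.radians(rng.uniform(0.0, tilt_max_deg))
    aa = rng.uniform(0, 2 * np.pi)
    axis = np.array([np.cos(aa), np.sin(aa), 0.0])
    R = (Rotation.from_rotvec(axis * tilt).as_matrix()
         @ Rotation.from_euler('z', rng.uniform(0, 360), degrees=True).as_matrix())
    t = np.array([rng.uniform(-lateral[0], lateral[0]),
                  rng.uniform(-lateral[1], lateral[1]),
                  rng.uniform(*tz_range)])
    return Pose(R=R, t=t)


def rotation_angle_deg(R1, R2):
    """Geodesic angle between two rotations, degrees."""
    c = (np.trace(R1.T @ R2) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
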