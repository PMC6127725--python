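import numpy as np
import pytest

from filotrack.core import FilopodiumInstance, Track, VoxelCalibration
from filotrack.simulate import SimConfig, simulate_movie


@pytest.fixture(scope="session")
def calibration() -> VoxelCalibration:
    return VoxelCalibration(dx=0.1, dy=0.1, dz=0.7, dt=15.0)


def tiny_sim_config(**overrides) -> SimConfig:
    """A desk-sized scene: 6 frames, 2 opposite filopodia, 128x128 field."""
    kwargs = dict(
        frames=6,
        slices=6,
        height=128,
        width=128,
        body_center_zyx=(2.5, 64.0, 64.0),
        body_radii_zyx=(1.8, 20.0, 20.0),
        n_filopodia=2,
        azimuths_rad=(0.0, np.pi),
        max_length_cap_um=4.0,
        bend_px=2.0,
        drift_px_per_frame=1.5,
        seed=7,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_movie():
    return simulate_movie(tiny_sim_config())


def solid_tube_mask(shape=(24, 48, 48), radius=2.0, x_range=(4, 44)) -> np.ndarray:
    """Solid cylinder along x, centered in z and y."""
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    cz, cy = shape[0] // 2, shape[1] // 2
    return ((zz - cz) ** 2 + (yy - cy) ** 2 <= radius**2) & (xx >= x_range[0]) & (xx < x_range[1])


def make_instance(
    instance_id: int,
    frame: int,
    origin=(0, 0, 0),
    length_vox: int = 10,
    direction=(0, 0, 1),
    calibration: VoxelCalibration | None = None,
) -> FilopodiumInstance:
    """A straight filopodium instance for tracking tests."""
    cal = calibration or VoxelCalibration(dx=0.1, dy=0.1)
    d = np.asarray(direction)
    path = np.asarray(origin) + np.arange(length_vox)[:, None] * d
    return FilopodiumInstance.from_path(instance_id, frame, path, cal)


def make_track(track_id: int, frames, lengths_um, calibration=None) -> Track:
    """A track with prescribed per-frame lengths (geometry is a stub)."""
    cal = calibration or VoxelCalibration(dx=0.1, dy=0.1)
    tr = Track(track_id=track_id)
    for f, length in zip(frames, lengths_um):
        inst = FilopodiumInstance(
            instance_id=track_id * 1000 + f,
            frame=f,
            path=np.array([[0, 0, 0], [0, 0, 1]]),
            path_length_vox=1.0,
            path_length_um=length,
            mean_direction=np.array([0.0, 0.0, 1.0]),
        )
        tr.add(inst)
    return tr
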