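"""Shared fixtures: all test data is generated procedurally at session scope."""

import numpy as np
import pytest

from herdrecon.camera import PinholeIntrinsics
from herdrecon.io import RGBDFrame
from herdrecon.pointcloud import PointCloud, depth_to_pointcloud, estimate_normals, voxel_downsample
from herdrecon.synthetic import (
    default_intrinsics,
    look_at_pose,
    make_animal_mesh,
    make_orbit_trajectory,
    render_frame,
)


@pytest.fixture(scope="session")
def animal():
    """Procedural animal mesh + per-vertex albedo (seed fixed)."""
    mesh, albedo = make_animal_mesh(size=2.2, seed=1)
    return mesh, albedo


@pytest.fixture(scope="session")
def intrinsics():
    return default_intrinsics(160, 120)


@pytest.fixture(scope="session")
def intrinsics_hi():
    return default_intrinsics(320, 240)


@pytest.fixture(scope="session")
def side_pose():
    """Camera on the orbit circle looking at the body center (oblique view:
    on-axis views make yaw and lateral translation near-degenerate)."""
    a = np.radians(25.0)
    return look_at_pose((2.5 * np.cos(a), 2.5 * np.sin(a), 0.4), (0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def side_frame(animal, intrinsics_hi, side_pose):
    mesh, albedo = animal
    gray, depth = render_frame(mesh, albedo, intrinsics_hi, side_pose)
    return RGBDFrame(gray, depth)


@pytest.fixture(scope="session")
def surface_patch(animal, intrinsics, side_pose):
    """A one-view surface cloud of the animal (world frame), with normals + intensity."""
    mesh, albedo = animal
    gray, depth = render_frame(mesh, albedo, intrinsics, side_pose)
    pc = depth_to_pointcloud(RGBDFrame(gray, depth), intrinsics)
    pc = PointCloud(side_pose.apply(pc.points), intensity=pc.intensity)
    pc = voxel_downsample(pc, 0.01)
    return estimate_normals(pc, k_neighbors=12, viewpoint=side_pose.translation)


@pytest.fixture(scope="session")
def orbit60(animal, intrinsics_hi):
    """A noise-free 60-frame, 72-degree orbit sequence with ground truth
    (1.2-degree steps, the odometry-friendly scan density)."""
    from herdrecon.synthetic import NoiseSpec, SceneSpec, render_sequence

    mesh, albedo = animal
    traj = make_orbit_trajectory(60, radius=2.5, arc=72.0, height=0.4)
    spec = SceneSpec(mesh=mesh, albedo=albedo, trajectory=traj,
                     noise=NoiseSpec.none(), seed=7)
    frames, gt = render_sequence(spec, intrinsics_hi)
    return frames, gt, spec
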