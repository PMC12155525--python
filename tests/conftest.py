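"""Shared fixtures: small synthetic scans and rendering helpers."""

from __future__ import annotations

import numpy as np
import pytest

from dentalseg.mesh import LabeledMesh, default_label_scheme
from dentalseg.render import CameraPose, LightingConfig, render_pair
from dentalseg.synthetic import ArchParams, generate_arch


@pytest.fixture(scope="session")
def scheme():
    return default_label_scheme()


@pytest.fixture(scope="session")
def small_arch():
    """A coarse labeled arch + landmarks (shared, read-only)."""
    return generate_arch(ArchParams(seed=11, mesh_resolution=1500))


@pytest.fixture()
def tiny_mesh(scheme):
    """Two triangles with distinct labels and colors."""
    vertices = np.array([
        [0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0], [10.0, 10.0, 1.0],
    ])
    faces = np.array([[0, 1, 2], [1, 3, 2]])
    color = np.array([[200, 50, 50]] * 2 + [[50, 200, 50]] * 2, dtype=np.uint8)
    label = np.array([9, 9, 17, 17])
    return LabeledMesh(vertices, faces, color, label, scheme)


def protocol_pairs(scan_seed, pose_seed, n_views, size=64, mesh_resolution=2000):
    """Render ImagePairs of one synthetic scan under a standardized
    acquisition protocol (narrow anterior viewing sector)."""
    from dentalseg.nn import ImagePair
    from dentalseg.render import sample_camera_poses

    mesh, _ = generate_arch(ArchParams(seed=scan_seed, mesh_resolution=mesh_resolution))
    lo, hi = mesh.vertices.min(0), mesh.vertices.max(0)
    center = (lo + hi) / 2
    radius = float(np.linalg.norm(hi - lo)) / 2
    poses = sample_camera_poses(
        n_views, pose_seed, 1.7 * radius, center, image_size=size,
        elevation_range_deg=(55.0, 80.0), azimuth_range_deg=(-30.0, 30.0),
        roll_range_deg=(-9.0, 9.0),
    )
    pairs = []
    for pose in poses:
        rv = render_pair(mesh, pose, LightingConfig("ambient"))
        pairs.append(ImagePair(
            rv.texture_image.transpose(2, 0, 1).astype(np.float32) / 255.0,
            rv.label_ids, scan_id=scan_seed,
        ))
    return pairs
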