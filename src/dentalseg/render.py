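"""Simulated-camera projection of textured and labeled meshes.

Every training pair is produced by the same pinhole projection: the
texture image is shaded according to a lighting mode (glow = raw vertex
colors, ambient = Lambertian directional light at infinity, spot = two
point lights with inverse-square falloff and randomized intensity),
while the label image is flat, unlit and un-anti-aliased — each covered
pixel takes the palette color of the nearest vertex (in barycentric
terms) of its face, so label images contain palette colors only and
never mix classes at boundaries.  Texture and label share one
rasterization, hence identical coverage and depth, which is what makes
exact back-projection possible later.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ._raster import rasterize
from .mesh import LabeledMesh

__all__ = [
    "CameraPose",
    "LightingConfig",
    "ViewRender",
    "generate_dataset",
    "label_pixel_stats",
    "render_label_image",
    "render_pair",
    "render_view",
    "sample_camera_poses",
]

BACKGROUND = -1  #: pix2face sentinel for uncovered pixels


@dataclass(frozen=True)
class CameraPose:
    """Pinhole camera: position on a hemisphere, optical axis toward look_at.

    ``focal`` is in pixels; the principal point defaults to the image
    center.  ``roll`` rotates the camera about its optical axis.
    ``fov_jitter`` records the perspective-distortion factor already
    folded into ``focal`` (1.0 = none).
    """

    position: tuple[float, float, float]
    look_at: tuple[float, float, float]
    roll: float = 0.0
    focal: float = 280.0
    width: int = 256
    height: int = 256
    cx: float | None = None
    cy: float | None = None
    fov_jitter: float = 1.0

    @property
    def principal_point(self) -> tuple[float, float]:
        cx = (self.width - 1) / 2.0 if self.cx is None else self.cx
        cy = (self.height - 1) / 2.0 if self.cy is None else self.cy
        return cx, cy

    @property
    def optical_axis(self) -> np.ndarray:
        d = np.asarray(self.look_at, float) - np.asarray(self.position, float)
        return d / np.linalg.norm(d)

    def rotation(self) -> np.ndarray:
        """World-to-camera rotation; rows are camera x (right), y (down), z (forward)."""
        zc = self.optical_axis
        up = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(zc, up)) > 0.999:
            up = np.array([1.0, 0.0, 0.0])
        xc = np.cross(up, zc)
        xc /= np.linalg.norm(xc)
        yc = np.cross(zc, xc)
        c, s = np.cos(self.roll), np.sin(self.roll)
        xr = c * xc + s * yc
        yr = -s * xc + c * yc
        return np.stack([xr, yr, zc])

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project world points; returns pixel (x, y) coords and camera depth."""
        R = self.rotation()
        cam = (np.asarray(points, float) - np.asarray(self.position, float)) @ R.T
        z = cam[:, 2]
        cx, cy = self.principal_point
        with np.errstate(divide="ignore", invalid="ignore"):
            u = self.focal * cam[:, 0] / z + cx
            v = self.focal * cam[:, 1] / z + cy
        return np.column_stack([u, v]), z


@dataclass(frozen=True)
class LightingConfig:
    """Rendering illumination: one of glow / ambient / spot."""

    mode: str = "glow"
    ambient_direction: tuple[float, float, float] = (0.35, 0.25, 1.0)
    spot_positions: np.ndarray | None = None  # (2, 3); auto-placed when None
    spot_intensity: float = 1.0  # random scalar, drawn per render by the dataset generator
    base: float = 0.35  # ambient floor so unlit faces stay visible

    def __post_init__(self) -> None:
        if self.mode not in ("glow", "ambient", "spot"):
            raise ValueError(f"unknown lighting mode {self.mode!r}")


@dataclass
class ViewRender:
    """One camera's output: texture and/or label raster plus depth and pix2face."""

    texture_image: np.ndarray | None
    label_image: np.ndarray | None
    depth: np.ndarray
    pix2face: np.ndarray
    pose: CameraPose
    label_ids: np.ndarray | None = None  # (H, W) int64, void on background

    @property
    def coverage(self) -> np.ndarray:
        return self.pix2face != BACKGROUND


def sample_camera_poses(
    n: int,
    seed: int,
    hemisphere_radius: float,
    center=(0.0, 0.0, 0.0),
    min_elevation_deg: float = 15.0,
    image_size: int = 256,
    focal: float | None = None,
    elevation_range_deg: tuple[float, float] | None = None,
    azimuth_range_deg: tuple[float, float] = (0.0, 360.0),
    roll_range_deg: tuple[float, float] = (0.0, 360.0),
) -> list[CameraPose]:
    """Poses uniform in solid angle on the upper hemisphere cap.

    Elevation is kept above ``min_elevation_deg`` to avoid grazing
    projections; the optical axis points at ``center`` and the roll about
    it is uniform in [0, 2pi).  The three optional ranges restrict the
    band, e.g. to emulate a standardized acquisition protocol where the
    scanner views the arch from a narrow anterior sector; sampling stays
    solid-angle uniform within the band.
    """
    if n < 1:
        raise ValueError("need at least one pose")
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=np.float64)
    el_lo, el_hi = elevation_range_deg or (min_elevation_deg, 90.0)
    zmin, zmax = np.sin(np.deg2rad([el_lo, el_hi]))
    # uniform solid angle on a cap/band: z ~ U[zmin, zmax], azimuth uniform
    zs = rng.uniform(zmin, zmax, n)
    az = rng.uniform(*np.deg2rad(azimuth_range_deg), n)
    rolls = rng.uniform(*np.deg2rad(roll_range_deg), n)
    f = focal if focal is not None else 1.1 * image_size
    poses = []
    for zc, a, roll in zip(zs, az, rolls):
        rxy = np.sqrt(1.0 - zc**2)
        p = center + hemisphere_radius * np.array([rxy * np.cos(a), rxy * np.sin(a), zc])
        poses.append(
            CameraPose(tuple(p), tuple(center), roll=float(roll), focal=float(f),
                       width=image_size, height=image_size)
        )
    return poses


def _vertex_shading(mesh: LabeledMesh, lighting: LightingConfig) -> np.ndarray:
    """Per-vertex scalar intensity for the texture render (Gouraud)."""
    n = mesh.n_vertices
    if lighting.mode == "glow":
        return np.ones(n)
    normals = mesh.vertex_normals()
    if lighting.mode == "ambient":
        d = np.asarray(lighting.ambient_direction, float)
        d = d / np.linalg.norm(d)
        lam = np.clip(normals @ d, 0.0, None)
        return lighting.base + (1.0 - lighting.base) * lam
    # spot: two point lights, inverse-square falloff, random intensity
    lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
    c = (lo + hi) / 2.0
    scale = float(np.linalg.norm(hi - lo))
    spots = lighting.spot_positions
    if spots is None:
        spots = np.array([
            c + scale * np.array([0.6, 0.6, 0.9]),
            c + scale * np.array([-0.6, -0.4, 0.9]),
        ])
    ref2 = scale**2  # distance normalisation so intensities are O(1)
    out = np.full(n, lighting.base)
    for s in np.asarray(spots, float):
        delta = s - mesh.vertices
        d2 = np.sum(delta**2, axis=1)
        lam = np.clip(np.sum(normals * delta, axis=1) / np.sqrt(d2), 0.0, None)
        out = out + lighting.spot_intensity * lam * ref2 / (2.0 * d2)
    return np.clip(out, 0.0, 1.4)


def _rasterize_mesh(mesh: LabeledMesh, pose: CameraPose):
    uv, z = pose.project(mesh.vertices)
    return rasterize(uv, z, mesh.faces, pose.height, pose.width)


def render_pair(
    mesh: LabeledMesh,
    pose: CameraPose,
    lighting: LightingConfig | None = None,
    with_texture: bool = True,
    with_label: bool = True,
) -> ViewRender:
    """Render texture and/or label images from one shared rasterization."""
    lighting = lighting or LightingConfig()
    depth, pix2face, bary = _rasterize_mesh(mesh, pose)
    covered = pix2face != BACKGROUND
    fidx = pix2face[covered]
    tri = mesh.faces[fidx]  # (P, 3) vertex ids per covered pixel
    w = bary[covered]  # (P, 3)

    texture = None
    if with_texture and mesh.n_faces:
        shade = _vertex_shading(mesh, lighting)
        colors = mesh.texture_color.astype(np.float64) * shade[:, None]
        px = np.einsum("pk,pkc->pc", w, colors[tri])
        texture = np.zeros((pose.height, pose.width, 3), dtype=np.uint8)
        texture[covered] = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    elif with_texture:
        texture = np.zeros((pose.height, pose.width, 3), dtype=np.uint8)

    label_img = None
    label_ids = None
    if with_label:
        label_ids = np.full((pose.height, pose.width), mesh.scheme.void_id, dtype=np.int64)
        if mesh.n_faces:
            nearest = tri[np.arange(len(tri)), np.argmax(w, axis=1)]
            label_ids[covered] = mesh.label[nearest]
        label_img = mesh.scheme.palette[label_ids]

    return ViewRender(texture, label_img, depth, pix2face, pose, label_ids)


def render_view(mesh: LabeledMesh, pose: CameraPose,
                lighting: LightingConfig | None = None) -> ViewRender:
    """Texture render (pinhole projection + z-buffer + lighting mode)."""
    return render_pair(mesh, pose, lighting, with_texture=True, with_label=False)


def render_label_image(mesh: LabeledMesh, pose: CameraPose) -> ViewRender:
    """Label render: flat palette colors, no lighting, no anti-aliasing."""
    return render_pair(mesh, pose, None, with_texture=False, with_label=True)


# ---------------------------------------------------------------------------
# Dataset generation


def _pose_record(pose: CameraPose) -> dict:
    R = pose.rotation()
    rec = {
        "pos_x": pose.position[0], "pos_y": pose.position[1], "pos_z": pose.position[2],
        "look_x": pose.look_at[0], "look_y": pose.look_at[1], "look_z": pose.look_at[2],
        "roll": pose.roll, "focal": pose.focal,
        "width": pose.width, "height": pose.height, "fov_jitter": pose.fov_jitter,
    }
    for i in range(3):  # rotation serialized row-major for external consumers
        for j in range(3):
            rec[f"R{i}{j}"] = R[i, j]
    return rec


def pose_from_record(rec) -> CameraPose:
    """Rebuild a CameraPose from one manifest row."""
    return CameraPose(
        (float(rec["pos_x"]), float(rec["pos_y"]), float(rec["pos_z"])),
        (float(rec["look_x"]), float(rec["look_y"]), float(rec["look_z"])),
        roll=float(rec["roll"]), focal=float(rec["focal"]),
        width=int(rec["width"]), height=int(rec["height"]),
        fov_jitter=float(rec["fov_jitter"]),
    )


def generate_dataset(
    meshes,
    n_views_per_mesh: int,
    seed: int,
    out_dir,
    lighting_modes=("glow", "ambient", "spot"),
    image_size: int = 256,
    hemisphere_radius_factor: float = 2.5,
    min_elevation_deg: float = 15.0,
    fov_jitter_range: tuple[float, float] = (0.85, 1.2),
) -> pd.DataFrame:
    """Paired (texture, label) images for each mesh under randomized views.

    For every mesh, ``n_views_per_mesh`` camera poses are sampled on a
    hemisphere of radius ``hemisphere_radius_factor`` x the mesh bounding
    radius; each view draws a lighting mode, a spot intensity and a
    perspective (focal) jitter.  Images are written as lossless PNG so
    palette colors survive exactly; the manifest (one row per pair, with
    the full pose) is written as ``manifest.csv`` in ``out_dir``.
    """
    meshes = list(meshes)
    if not meshes:
        raise ValueError("need at least one mesh")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    rng = np.random.default_rng(seed)
    rows = []
    for mesh_id, mesh in enumerate(meshes):
        lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
        center = (lo + hi) / 2.0
        radius = float(np.linalg.norm(hi - lo)) / 2.0
        poses = sample_camera_poses(
            n_views_per_mesh, int(rng.integers(0, 2**31)),
            hemisphere_radius_factor * radius, center,
            min_elevation_deg=min_elevation_deg, image_size=image_size,
        )
        for view_id, pose in enumerate(poses):
            mode = lighting_modes[int(rng.integers(0, len(lighting_modes)))]
            intensity = float(rng.uniform(0.5, 1.5))
            jitter = float(rng.uniform(*fov_jitter_range))
            pose = replace(pose, focal=pose.focal * jitter, fov_jitter=jitter)
            lighting = LightingConfig(mode=mode, spot_intensity=intensity)
            rv = render_pair(mesh, pose, lighting)
            tex_path = out_dir / f"mesh{mesh_id:03d}_view{view_id:03d}_tex.png"
            lab_path = out_dir / f"mesh{mesh_id:03d}_view{view_id:03d}_lab.png"
            Image.fromarray(rv.texture_image).save(tex_path)
            Image.fromarray(rv.label_image).save(lab_path)
            rows.append({
                "mesh_id": mesh_id, "view_id": view_id,
                "texture_path": tex_path.name, "label_path": lab_path.name,
                "lighting": mode, "spot_intensity": intensity,
                **_pose_record(pose),
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def label_pixel_stats(manifest: pd.DataFrame, meshes, data_dir) -> pd.DataFrame:
    """Per-label pixel/vertex counts and their ratio across a dataset.

    If the random viewpoints are unbiased, the number of rendered pixels
    per label is proportional to the label's vertex count; the per-label
    ratio (pixels / vertices) and its spread across labels quantify that.
    Labels rendering zero pixels are reported but flagged and excluded
    from the mean/SD summary (stored in ``DataFrame.attrs``).
    """
    meshes = list(meshes)
    data_dir = Path(data_dir)
    scheme = meshes[0].scheme
    palette = scheme.palette.astype(np.int64)
    code = palette[:, 0] * 65536 + palette[:, 1] * 256 + palette[:, 2]
    pixel_counts = np.zeros(len(code), dtype=np.int64)
    for _, row in manifest.iterrows():
        img = np.asarray(Image.open(data_dir / row["label_path"]).convert("RGB"), np.int64)
        flat = img[..., 0] * 65536 + img[..., 1] * 256 + img[..., 2]
        for lid, c in enumerate(code):
            if lid == scheme.void_id:
                continue
            pixel_counts[lid] += int((flat == c).sum())
    vertex_counts = np.zeros(len(code), dtype=np.int64)
    for mesh in meshes:
        ids, counts = np.unique(mesh.label, return_counts=True)
        vertex_counts[ids] += counts
    rows = []
    for e in scheme.entries:
        if e.label_id == scheme.void_id:
            continue
        pix = int(pixel_counts[e.label_id])
        nv = int(vertex_counts[e.label_id])
        rows.append({
            "label_id": e.label_id, "label": e.name, "pixels": pix, "vertices": nv,
            "ratio": pix / nv if nv and pix else np.nan,
            "flagged": not (nv and pix),
        })
    table = pd.DataFrame(rows)
    valid = table.loc[~table["flagged"], "ratio"]
    table.attrs["ratio_mean"] = float(valid.mean()) if len(valid) else np.nan
    table.attrs["ratio_sd"] = float(valid.std(ddof=1)) if len(valid) > 1 else np.nan
    return table
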