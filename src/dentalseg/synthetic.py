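"""Synthetic labeled maxillary-arch meshes with known ground truth.

Real intraoral scans are not redistributable, so this module generates
stand-ins with the features the pipeline exercises: a palate vault with
a ridged rugae patch on the anterior midline, tooth-shaped protrusions
arranged on a parabolic arch curve (one per dental class, sized per
class), per-vertex labels from the 28-class scheme, six anatomical
landmarks, and — for motion experiments — application of known per-tooth
rigid displacements with optional smooth mucosa deformation.

The meshes are height fields over an elliptical palate domain: teeth are
superellipsoid-like bumps with a per-tooth cusp modulation (which breaks
rotational symmetry, so per-tooth ICP has a unique optimum), and the
rugae are transverse sinusoidal ridges.  No anatomical realism beyond
that is claimed; see docs/methods.md for what this does and does not
emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .landmarks import LandmarkSet
from .mesh import RUGAE, VOID, LabeledMesh, default_label_scheme
from .motion import RigidTransform

__all__ = ["ArchParams", "add_scan_noise", "apply_tooth_motion", "generate_arch"]

# Per-class tooth presets: (mesiodistal width, buccolingual depth, crown height), mm.
_TOOTH_PRESETS = {
    "central incisor": (8.0, 6.0, 7.0),
    "lateral incisor": (6.4, 5.6, 6.5),
    "canine": (7.2, 7.0, 7.5),
    "first bicuspid": (6.8, 8.0, 6.5),
    "second bicuspid": (6.4, 8.2, 6.3),
    "first molar": (9.8, 10.4, 6.0),
    "second molar": (9.2, 10.0, 5.8),
    "third molar": (8.4, 9.6, 5.5),
}
# Midline-outward placement order of the permanent arch (one side).
_ARCH_ORDER = (
    "central incisor", "lateral incisor", "canine", "first bicuspid",
    "second bicuspid", "first molar", "second molar", "third molar",
)

MUCOSA_COLOR = np.array([226, 158, 148], dtype=np.float64)
TOOTH_COLOR = np.array([246, 240, 222], dtype=np.float64)


@dataclass
class ArchParams:
    """Generator settings; defaults approximate an adult maxillary arch."""

    n_teeth: int = 14  # full permanent dentition excluding third molars
    arch_width: float = 46.0  # mm across the molars
    arch_depth: float = 48.0  # mm incisors to distal molars
    tooth_size_range: tuple[float, float] = (0.95, 1.05)  # per-tooth scale jitter
    rugae_ridge_count: int = 4
    rugae_amplitude: float = 0.5  # mm
    palate_vault_depth: float = 4.0  # mm
    mesh_resolution: int = 3000  # target vertex count
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_teeth <= 16):
            raise ValueError("n_teeth must be in [0, 16]")
        for name in ("arch_width", "arch_depth", "rugae_amplitude", "palate_vault_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mesh_resolution <= 0:
            raise ValueError("mesh_resolution must be positive")


def _tooth_layout(params: ArchParams, rng: np.random.Generator, scheme):
    """Positions, orientations and sizes for the first n_teeth classes.

    Teeth are placed pairwise from the midline outward along a parabolic
    arch curve x = xf - k*y^2, spaced by their mesiodistal widths.
    """
    half_w = params.arch_width / 2.0
    xf = params.arch_depth / 2.0  # anterior-most arch point
    k = params.arch_depth / (half_w**2)  # molar ends near the posterior rim

    ys = np.linspace(0.0, half_w, 400)
    xs = xf - k * ys**2
    seg = np.hypot(np.diff(xs), np.diff(ys))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    half_arc = float(cum[-1])

    def arch_point(s):
        # arc-length parameterisation of the half arch (numeric)
        y = np.interp(s, cum, ys)
        return xf - k * y**2, y

    # midline-outward class order interleaving left/right
    sides = []
    for kind in _ARCH_ORDER:
        for side in ("left", "right"):
            sides.append((side, kind))
    sides = sides[: params.n_teeth]

    lo, hi = params.tooth_size_range
    # compress spacing if the dentition would overrun the arch curve
    per_side = {}
    for side, kind in sides:
        per_side.setdefault(side, []).append(_TOOTH_PRESETS[kind][0])
    needed = max((sum(w) * 1.04 for w in per_side.values()), default=0.0)
    fit = min(1.0, half_arc / needed) if needed else 1.0

    teeth = []
    arc_pos = {"left": 0.0, "right": 0.0}
    for side, kind in sides:
        w, d, h = _TOOTH_PRESETS[kind]
        scale = rng.uniform(lo, hi)
        w, d, h = w * scale, d * scale, h * scale
        s_center = arc_pos[side] + w * fit / 2.0
        arc_pos[side] += w * fit * 1.04  # small interdental gap
        x, y = arch_point(s_center)
        if side == "right":
            y = -y
        # tangent of the parabola at y (for tooth orientation)
        tangent = np.array([-2.0 * k * abs(y), 1.0 if side == "left" else -1.0])
        tangent /= np.linalg.norm(tangent)
        teeth.append({
            "label": scheme.by_name(f"{side} {kind}").label_id,
            "center": (x, y),
            "tangent": tangent,
            "half_w": w / 2.0,
            "half_d": d / 2.0,
            "height": h,
            "phase": rng.uniform(0.0, 2 * np.pi),
        })
    return teeth


def _tooth_bump(x, y, tooth):
    """Height contribution of one tooth at grid points (vectorised)."""
    cx, cy = tooth["center"]
    tx, ty = tooth["tangent"]
    dx, dy = x - cx, y - cy
    u = dx * tx + dy * ty  # along the arch
    v = -dx * ty + dy * tx  # across the arch
    rho = (np.abs(u) / tooth["half_w"]) ** 3 + (np.abs(v) / tooth["half_d"]) ** 3
    core = np.clip(1.0 - rho, 0.0, None) ** 0.7
    # asymmetric cusp modulation: breaks the 180-degree symmetry of the
    # superellipsoid so per-tooth ICP has a unique rigid optimum
    mod = 1.0 + 0.12 * np.sin(1.7 * u / tooth["half_w"] + tooth["phase"]) * np.cos(
        1.3 * v / tooth["half_d"]
    )
    return tooth["height"] * core * mod


def generate_arch(params: ArchParams | None = None) -> tuple[LabeledMesh, LandmarkSet]:
    """Generate a labeled synthetic maxillary arch and its six landmarks."""
    params = params or ArchParams()
    rng = np.random.default_rng(params.seed)
    scheme = default_label_scheme()

    # --- triangulated grid over an elliptical domain -----------------------
    ax = params.arch_depth / 2.0 + 8.0  # x semi-axis incl. gingival margin
    ay = params.arch_width / 2.0 + 8.0
    area = np.pi * ax * ay
    spacing = np.sqrt(area / params.mesh_resolution)
    nx = int(np.ceil(2 * ax / spacing)) + 1
    ny = int(np.ceil(2 * ay / spacing)) + 1
    gx = np.linspace(-ax, ax, nx)
    gy = np.linspace(-ay, ay, ny)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    inside = (X / ax) ** 2 + (Y / ay) ** 2 <= 1.0
    idx = -np.ones((nx, ny), dtype=np.int64)
    idx[inside] = np.arange(inside.sum())
    x, y = X[inside], Y[inside]

    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b = idx[i, j], idx[i + 1, j]
            c, d = idx[i + 1, j + 1], idx[i, j + 1]
            if a >= 0 and b >= 0 and c >= 0:
                faces.append((a, b, c))
            if a >= 0 and c >= 0 and d >= 0:
                faces.append((a, c, d))
    faces = np.asarray(faces, dtype=np.int64)

    # --- height field: palate vault + rugae ridges + tooth bumps -----------
    r2 = (x / ax) ** 2 + (y / ay) ** 2
    z = params.palate_vault_depth * (r2 - 1.0)  # vault: deepest at the centre

    xf = params.arch_depth / 2.0
    rug_x0, rug_x1 = xf - 22.0, xf - 6.0  # anterior-median patch
    rug_half_w = 8.0
    in_rugae = (x >= rug_x0) & (x <= rug_x1) & (np.abs(y) <= rug_half_w)
    wx = np.sin(np.pi * np.clip((x - rug_x0) / (rug_x1 - rug_x0), 0, 1))
    wy = np.cos(0.5 * np.pi * np.clip(np.abs(y) / rug_half_w, 0, 1))
    ridges = params.rugae_amplitude * np.sin(
        2 * np.pi * params.rugae_ridge_count * (x - rug_x0) / (rug_x1 - rug_x0)
    )
    z = z + np.where(in_rugae, ridges * wx * wy, 0.0)

    teeth = _tooth_layout(params, rng, scheme)
    label = np.full(len(x), VOID, dtype=np.int64)
    label[in_rugae] = RUGAE
    if teeth:
        bumps = np.stack([_tooth_bump(x, y, t) for t in teeth])
        best = np.argmax(bumps, axis=0)
        bump_h = bumps[best, np.arange(len(x))]
        z = z + bump_h
        tooth_ids = np.array([t["label"] for t in teeth])
        on_tooth = bump_h > 0.5  # mm: crown region, not the faint skirt
        label[on_tooth] = tooth_ids[best[on_tooth]]

    vertices = np.column_stack([x, y, z])

    # --- texture: pink mucosa, whitish teeth, per-vertex noise -------------
    color = np.where(
        (label[:, None] != VOID) & (label[:, None] != RUGAE), TOOTH_COLOR, MUCOSA_COLOR
    )
    color = color + rng.normal(0.0, 6.0, size=color.shape)
    color = np.clip(color, 0, 255).astype(np.uint8)

    mesh = LabeledMesh(vertices, faces, color, label, scheme)

    # --- landmarks on the analytic surface ---------------------------------
    def surface_z(px, py):
        pr2 = (px / ax) ** 2 + (py / ay) ** 2
        pz = params.palate_vault_depth * (pr2 - 1.0)
        if rug_x0 <= px <= rug_x1 and abs(py) <= rug_half_w:
            pwx = np.sin(np.pi * (px - rug_x0) / (rug_x1 - rug_x0))
            pwy = np.cos(0.5 * np.pi * abs(py) / rug_half_w)
            pz += (
                params.rugae_amplitude
                * np.sin(2 * np.pi * params.rugae_ridge_count * (px - rug_x0) / (rug_x1 - rug_x0))
                * pwx * pwy
            )
        for t in teeth:
            pz += float(_tooth_bump(np.array([px]), np.array([py]), t)[0])
        return float(pz)

    def apex(side):
        # cusp of the most distal tooth on that side; rim point if edentulous
        cand = [t for t in teeth if (t["center"][1] > 0) == (side == "left")]
        if cand:
            cx, cy = max(cand, key=lambda t: abs(t["center"][1]))["center"]
        else:
            cx, cy = -ax * 0.5, (ay * 0.7 if side == "left" else -ay * 0.7)
        return np.array([cx, cy, surface_z(cx, cy)])

    if teeth:
        ix = teeth[0]["center"][0]  # central incisor x
    else:
        ix = xf
    incisor_edge = np.array([ix, 0.0, surface_z(ix, 0.0)])
    raphae_x = np.array([rug_x0 + 1.5, (rug_x0 + rug_x1) / 2.0, rug_x1 - 1.5])
    raphae = np.stack([np.array([rx, 0.0, surface_z(rx, 0.0)]) for rx in raphae_x])
    landmarks = LandmarkSet(apex("left"), apex("right"), incisor_edge, raphae)
    return mesh, landmarks


def apply_tooth_motion(
    mesh: LabeledMesh,
    motions: Mapping[int | str, RigidTransform],
    mucosa_wobble: float = 0.0,
    seed: int = 0,
) -> LabeledMesh:
    """Apply known rigid transforms to individual teeth ("treatment").

    Each key names a tooth class present in the mesh (id or name); its
    vertices are transformed by the associated matrix.  Rugae vertices
    are never moved (they are the stable reference).  With
    ``mucosa_wobble > 0`` the void (gingiva/mucosa) vertices receive a
    smooth radial-basis deformation of that amplitude (mm), tapered to
    zero near the rugae patch, emulating soft-tissue change between
    scans.  Labels are unchanged.
    """
    scheme = mesh.scheme
    out = mesh.copy()
    tooth_ids = set(scheme.tooth_ids)
    for key, transform in motions.items():
        lid = scheme.by_name(key).label_id if isinstance(key, str) else int(key)
        if lid not in tooth_ids:
            raise ValueError(
                f"label {scheme[lid].name!r} is not a movable tooth class"
            )
        sel = mesh.label == lid
        if not sel.any():
            raise ValueError(f"tooth {scheme[lid].name!r} is not present in the mesh")
        out.vertices[sel] = transform.apply(mesh.vertices[sel])

    if mucosa_wobble > 0.0:
        rng = np.random.default_rng(seed)
        sel = mesh.label == VOID
        pts = out.vertices[sel]
        lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
        centers = rng.uniform(lo, hi, size=(8, 3))
        amps = rng.normal(0.0, 1.0, size=(8, 3))
        amps *= mucosa_wobble / max(np.abs(amps).max(), 1e-12)
        ell = 0.25 * float(np.linalg.norm(hi - lo))
        disp = np.zeros_like(pts)
        for c, a in zip(centers, amps):
            w = np.exp(-np.sum((pts - c) ** 2, axis=1) / (2 * ell**2))
            disp += w[:, None] * a
        # taper to zero near the rugae patch so the anchor stays rigid
        rugae_pts = mesh.vertices[mesh.label == RUGAE]
        if len(rugae_pts):
            from scipy.spatial import cKDTree

            d, _ = cKDTree(rugae_pts).query(pts)
            disp *= np.clip(d / 10.0, 0.0, 1.0)[:, None]
        out.vertices[sel] = pts + disp
    return out


def add_scan_noise(mesh: LabeledMesh, sigma_mm: float, seed: int = 0) -> LabeledMesh:
    """i.i.d. Gaussian jitter along vertex normals (scanner noise); labels kept."""
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    out = mesh.copy()
    if sigma_mm == 0.0:
        return out
    rng = np.random.default_rng(seed)
    normals = mesh.vertex_normals()
    out.vertices = mesh.vertices + normals * rng.normal(0.0, sigma_mm, len(normals))[:, None]
    return out
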