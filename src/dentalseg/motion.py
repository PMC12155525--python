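"""Rigid-motion estimation of individual teeth between two scans.

The motion model: a tooth moves rigidly between the pre- and
post-treatment scan while the palatal rugae stay geometrically stable.
Alignment is therefore two-staged: the whole post scan is first
registered to the pre scan by ICP restricted to the rugae patch (which
cancels the arbitrary global pose difference between acquisitions), and
each tooth is then registered individually; the per-tooth residual
transform IS the orthodontic movement.

A recovered 4x4 homogeneous transform ``H`` is decomposed into six
clinical parameters — rotations ``alpha`` (about z), ``beta`` (about y),
``gamma`` (about x) in degrees and translations ``Tx, Ty, Tz`` in mm —
via the factorisation ``H = T · Rz(alpha) · Ry(beta) · Rx(gamma)``.

Sign convention
---------------
The inverse kinematics used here reads::

    beta  = -asin(R31)
    gamma = -atan2(R32, R33)
    alpha = -atan2(R21, R11)

These equations are exact inverses of the factorisation above only under
one axis-rotation sign convention: rotations about **x and z are
clockwise-positive** (the transpose of the usual right-hand matrices)
while the rotation about **y is counterclockwise-positive**.  This
module adopts that convention everywhere; the round trip
``decompose(compose(p)) == p`` holds to 1e-9 for ``|beta| < 90°``.  The
``|beta| <= 90°`` branch of the arcsine is always selected — rotations
beyond 90° are implausible for tooth movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .landmarks import LandmarkSet
from .mesh import RUGAE, LabeledMesh

__all__ = [
    "CoordinateFrame",
    "ICPParams",
    "ICPResult",
    "MotionParameters",
    "RigidTransform",
    "ToothMotion",
    "ToothMotionReport",
    "build_frame",
    "compose_transform",
    "decompose_transform",
    "estimate_tooth_motions",
    "icp",
    "rotation_angle_deg",
]


# ---------------------------------------------------------------------------
# Rigid transforms and Euler parameters


class RigidTransform:
    """A 4x4 homogeneous rigid-body transform (proper rotation + translation)."""

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray):
        H = np.asarray(matrix, dtype=np.float64)
        if H.shape != (4, 4):
            raise ValueError("rigid transform must be 4x4")
        R = H[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-7):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block must be proper (det = +1)")
        if not np.allclose(H[3], [0, 0, 0, 1], atol=1e-12):
            raise ValueError("last row must be (0, 0, 0, 1)")
        self.matrix = H.copy()
        self.matrix[3] = (0, 0, 0, 1)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        H = np.eye(4)
        H[:3, :3] = R
        H[:3, 3] = np.asarray(t, dtype=np.float64).reshape(3)
        return cls(H)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        R = self.rotation.T
        return RigidTransform.from_rotation_translation(R, -R @ self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.matrix @ other.matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation

    def __repr__(self) -> str:
        return f"RigidTransform(\n{self.matrix!r})"


@dataclass(frozen=True)
class MotionParameters:
    """Six-parameter tooth motion: Euler angles in degrees, translation in mm."""

    alpha: float  # rotation about z, degrees
    beta: float  # rotation about y, degrees (always in [-90, 90])
    gamma: float  # rotation about x, degrees
    tx: float
    ty: float
    tz: float
    gimbal_lock: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.tx, self.ty, self.tz])


def _rx(gamma_rad: float) -> np.ndarray:
    # clockwise-positive about x (see module docstring)
    c, s = np.cos(gamma_rad), np.sin(gamma_rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])


def _ry(beta_rad: float) -> np.ndarray:
    # counterclockwise-positive about y
    c, s = np.cos(beta_rad), np.sin(beta_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rz(alpha_rad: float) -> np.ndarray:
    # clockwise-positive about z
    c, s = np.cos(alpha_rad), np.sin(alpha_rad)
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def compose_transform(params: MotionParameters) -> RigidTransform:
    """Build ``H = T · Rz(alpha) · Ry(beta) · Rx(gamma)`` from six parameters."""
    a, b, g = np.deg2rad([params.alpha, params.beta, params.gamma])
    R = _rz(a) @ _ry(b) @ _rx(g)
    return RigidTransform.from_rotation_translation(R, (params.tx, params.ty, params.tz))


def decompose_transform(H: RigidTransform, gimbal_tol: float = 1e-9) -> MotionParameters:
    """Recover the six motion parameters from a rigid transform.

    ``beta`` is taken from the arcsine branch with ``|beta| <= 90°``.  At
    gimbal lock (``|R31| = 1``, i.e. ``beta = ±90°``) only the sum/
    difference of ``alpha`` and ``gamma`` is observable; ``gamma`` is set
    to zero, the residual folded into ``alpha``, and ``gimbal_lock`` is
    flagged.  Away from the singularity this is the exact inverse of
    :func:`compose_transform`.
    """
    R = H.rotation
    t = H.translation
    r31 = float(np.clip(R[2, 0], -1.0, 1.0))
    beta = -np.arcsin(r31)
    if 1.0 - abs(r31) < gimbal_tol:
        alpha = np.arctan2(R[0, 1], R[1, 1])
        gamma = 0.0
        lock = True
    else:
        gamma = -np.arctan2(R[2, 1], R[2, 2])
        alpha = -np.arctan2(R[1, 0], R[0, 0])
        lock = False
    a, b, g = np.rad2deg([alpha, beta, gamma])
    return MotionParameters(float(a), float(b), float(g), float(t[0]), float(t[1]),
                            float(t[2]), gimbal_lock=lock)


def rotation_angle_deg(R: np.ndarray) -> float:
    """Geodesic rotation angle of a 3x3 rotation matrix, in degrees."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Anatomical coordinate frame


@dataclass(frozen=True)
class CoordinateFrame:
    """Right-handed orthonormal frame: rows of ``axes`` are x, y, z in world."""

    origin: np.ndarray
    axes: np.ndarray  # (3, 3), rows x, y, z

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, float).reshape(3))
        A = np.asarray(self.axes, dtype=np.float64)
        if not np.allclose(A @ A.T, np.eye(3), atol=1e-9):
            raise ValueError("axes must be orthonormal")
        if np.linalg.det(A) < 0:
            raise ValueError("axes must be right-handed (det = +1)")
        object.__setattr__(self, "axes", A)

    @property
    def world_from_frame(self) -> RigidTransform:
        """Transform mapping frame coordinates to world coordinates."""
        return RigidTransform.from_rotation_translation(self.axes.T, self.origin)

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.origin) @ self.axes.T


def build_frame(landmarks: LandmarkSet) -> CoordinateFrame:
    """Anatomical frame from the six landmarks.

    The occlusal plane passes through the two molar cusps and the incisor
    edge; z is its normal, oriented away from the palate (the raphae
    points lie on the palatal side).  The sagittal plane contains the
    least-squares line through the raphae points and the occlusal normal;
    x runs along the intersection of the two planes, oriented anteriorly
    (toward the incisor edge).  y completes the right-handed frame, and
    the origin is the normal projection of the incisive papilla onto the
    occlusal plane.
    """
    occ = landmarks.occlusal_points
    n = np.cross(occ[1] - occ[0], occ[2] - occ[0])
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise ValueError("occlusal landmarks are collinear; plane is degenerate")
    z = n / norm
    raphae = landmarks.raphae_points
    raphae_mean = raphae.mean(axis=0)
    side = float(np.dot(z, raphae_mean - occ[0]))
    if side > 1e-12:
        z = -z  # palate must be on the negative-z side
    # least-squares direction of the raphae midline
    centered = raphae - raphae_mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9:
        raise ValueError("raphae points are coincident; sagittal plane is degenerate")
    d = vt[0]
    x = d - np.dot(d, z) * z  # intersection direction of occlusal & sagittal planes
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise ValueError("raphae line is normal to the occlusal plane")
    x = x / nx
    if np.dot(x, landmarks.incisor_edge - raphae_mean) < 0:
        x = -x  # anterior orientation
    y = np.cross(z, x)
    papilla = landmarks.incisive_papilla
    origin = papilla - np.dot(z, papilla - occ[0]) * z
    return CoordinateFrame(origin, np.stack([x, y, z]))


# ---------------------------------------------------------------------------
# ICP


@dataclass
class ICPParams:
    max_iter: int = 100
    tol: float = 1e-12  # stop when the RMS improves by less than this
    trim_fraction: float = 0.0  # drop this fraction of worst correspondences


@dataclass
class ICPResult:
    transform: RigidTransform  # source -> target
    rms: float
    n_iter: int
    converged: bool


def _kabsch(src: np.ndarray, tgt: np.ndarray) -> RigidTransform:
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - cs).T @ (tgt - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform.from_rotation_translation(R, ct - R @ cs)


def icp(
    source_points: np.ndarray,
    target_points: np.ndarray,
    params: ICPParams | None = None,
    init: RigidTransform | None = None,
) -> ICPResult:
    """Point-to-point ICP: returns the rigid transform mapping source onto target.

    Alternates nearest-neighbour correspondence (k-d tree on the target)
    with a closed-form least-squares rigid fit (Kabsch/SVD, reflection
    corrected), optionally trimming the worst correspondences.
    """
    params = params or ICPParams()
    src = np.asarray(source_points, dtype=np.float64)
    tgt = np.asarray(target_points, dtype=np.float64)
    if src.ndim != 2 or src.shape[1] != 3 or tgt.ndim != 2 or tgt.shape[1] != 3:
        raise ValueError("point sets must be (N, 3)")
    if len(src) < 3 or len(tgt) < 3:
        raise ValueError("ICP needs at least 3 points on each side")
    for pts in (src, tgt):
        if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-12) < 2:
            raise ValueError("degenerate (collinear) point set")
    tree = cKDTree(tgt)
    T = init if init is not None else RigidTransform.identity()
    moved = T.apply(src)
    prev_rms = np.inf
    n_keep = max(3, int(round(len(src) * (1.0 - params.trim_fraction))))
    rms = np.inf
    it = 0
    converged = False
    for it in range(1, params.max_iter + 1):
        dist, idx = tree.query(moved)
        if n_keep < len(src):
            keep = np.argsort(dist)[:n_keep]
        else:
            keep = slice(None)
        step = _kabsch(moved[keep], tgt[idx[keep]])
        T = step @ T
        moved = T.apply(src)
        dist, idx = tree.query(moved)
        if n_keep < len(src):
            d = np.sort(dist)[:n_keep]
        else:
            d = dist
        rms = float(np.sqrt(np.mean(d**2)))
        if prev_rms - rms < params.tol:
            converged = True
            break
        prev_rms = rms
    return ICPResult(T, rms, it, converged)


def _axis_rotation(axis: int, angle_deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg))
    R = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    R[i, i] = R[j, j] = c
    R[i, j], R[j, i] = -s, s
    return R


def _multistart_icp(src: np.ndarray, tgt: np.ndarray, params: ICPParams) -> ICPResult:
    """ICP with centroid initialisation plus coarse rotational restarts.

    Point-to-point ICP has a limited capture range; a tooth rotated by
    10-20 degrees can trap a cold-started run in a local minimum.  Each
    candidate start rotates the source about its centroid by a coarse
    angle, runs a short ICP, and the best short run (by RMS) is refined
    to convergence.  Deterministic: candidates are a fixed grid.
    """
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    starts = [np.eye(3)]
    for axis in range(3):
        for ang in (-20.0, -10.0, 10.0, 20.0):
            starts.append(_axis_rotation(axis, ang))
    short = ICPParams(max_iter=12, tol=params.tol, trim_fraction=params.trim_fraction)
    best = None
    for R0 in starts:
        init = RigidTransform.from_rotation_translation(R0, ct - R0 @ cs)
        res = icp(src, tgt, short, init=init)
        if best is None or res.rms < best.rms:
            best = res
    return icp(src, tgt, params, init=best.transform)


# ---------------------------------------------------------------------------
# Two-stage per-tooth motion estimation


@dataclass
class ToothMotion:
    label_id: int
    name: str
    transform: RigidTransform  # pre -> post motion, in rugae-aligned pre coords
    params: MotionParameters  # decomposed in the anatomical frame when given
    icp_rms: float


@dataclass
class ToothMotionReport:
    teeth: dict[int, ToothMotion]
    rugae_rms: float
    unmatched: list[int] = field(default_factory=list)
    global_alignment: RigidTransform = field(default_factory=RigidTransform.identity)

    def to_frame(self) -> "object":
        """Motion table as a pandas DataFrame (one row per tooth)."""
        import pandas as pd

        rows = []
        for lid in sorted(self.teeth):
            m = self.teeth[lid]
            p = m.params
            rows.append({
                "label_id": lid, "label": m.name,
                "alpha_deg": p.alpha, "beta_deg": p.beta, "gamma_deg": p.gamma,
                "Tx_mm": p.tx, "Ty_mm": p.ty, "Tz_mm": p.tz,
                "icp_rms_mm": m.icp_rms,
            })
        return pd.DataFrame(rows)


def estimate_tooth_motions(
    pre_mesh: LabeledMesh,
    post_mesh: LabeledMesh,
    pre_landmarks: LandmarkSet | None = None,
    post_landmarks: LandmarkSet | None = None,
    icp_params: ICPParams | None = None,
    rugae_trim_fraction: float = 0.0,
) -> ToothMotionReport:
    """Per-tooth rigid motion between a pre- and a post-treatment scan.

    Stage 0 (rough): if landmark sets are given, the post scan is brought
    into the pre scan's space by matching the two anatomical frames.
    Stage 1 (anchor): ICP restricted to the rugae vertices aligns the
    whole post scan to the pre scan; the rugae patch is assumed
    geometrically stable, so this cancels global pose while leaving true
    tooth movement intact.  Stage 2 (per tooth): each tooth present in
    both scans is registered individually; the inverse of that alignment
    is the tooth's pre→post motion, reported as a 4x4 transform and, when
    landmarks are available, decomposed in the pre scan's anatomical
    frame (otherwise in world coordinates).

    Teeth present in only one scan are reported in ``unmatched`` and
    skipped.  Missing rugae in either scan is an error — the method has
    no stable anchor without them.
    """
    scheme = pre_mesh.scheme
    pre_rugae = pre_mesh.vertices[pre_mesh.label == RUGAE]
    post_rugae_idx = post_mesh.label == RUGAE
    if len(pre_rugae) < 3 or post_rugae_idx.sum() < 3:
        raise ValueError("rugae patch missing (or too small) in one of the scans")

    if (pre_landmarks is None) != (post_landmarks is None):
        raise ValueError("provide landmarks for both scans or for neither")
    pre_frame = build_frame(pre_landmarks) if pre_landmarks is not None else None
    if post_landmarks is not None:
        post_frame = build_frame(post_landmarks)
        G0 = pre_frame.world_from_frame @ post_frame.world_from_frame.inverse()
    else:
        G0 = RigidTransform.identity()

    params = icp_params or ICPParams()
    rugae_params = ICPParams(params.max_iter, params.tol,
                             max(params.trim_fraction, rugae_trim_fraction))
    stage1 = icp(post_mesh.vertices[post_rugae_idx], pre_rugae, rugae_params, init=G0)
    G = stage1.transform  # post world -> rugae-aligned pre world

    pre_labels = set(pre_mesh.present_labels().tolist())
    post_labels = set(post_mesh.present_labels().tolist())
    tooth_ids = [t for t in scheme.tooth_ids if t in pre_labels | post_labels]
    teeth: dict[int, ToothMotion] = {}
    unmatched = [t for t in tooth_ids if t not in pre_labels & post_labels]
    for lid in tooth_ids:
        if lid in unmatched:
            continue
        src = G.apply(post_mesh.vertices[post_mesh.label == lid])
        tgt = pre_mesh.vertices[pre_mesh.label == lid]
        res = _multistart_icp(src, tgt, params)
        motion = res.transform.inverse()  # pre -> post, in aligned pre coords
        if pre_frame is not None:
            W = pre_frame.world_from_frame
            local = W.inverse() @ motion @ W
        else:
            local = motion
        teeth[lid] = ToothMotion(
            label_id=lid,
            name=scheme[lid].name,
            transform=motion,
            params=decompose_transform(local),
            icp_rms=res.rms,
        )
    return ToothMotionReport(
        teeth=teeth,
        rugae_rms=stage1.rms,
        unmatched=unmatched,
        global_alignment=G,
    )
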