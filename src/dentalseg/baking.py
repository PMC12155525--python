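"""Back-projection ("baking") of per-pixel labels onto mesh vertices.

Each rendered view knows its exact camera pose and depth buffer, so a
predicted label image can be shot back onto the mesh: a vertex is
visible in a view iff its projected depth agrees with the depth buffer
(the standard shadow-mapping test), and every visible vertex observes
the predicted class at its projected pixel.  Observations from all
views are tallied per vertex and the majority label wins; vertices never
seen by any camera fall back to void.  The result is the 3D semantic
segmentation, scored with vertex-level IoU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import LabeledMesh, LabelScheme
from .render import BACKGROUND, CameraPose

__all__ = [
    "Metrics3D",
    "VoteTally",
    "accumulate_votes",
    "bake_view",
    "finalize_labels",
    "metrics_3d",
    "segment_components",
]

DEPTH_TOL_FACTOR = 1e-3  # visibility tolerance as a fraction of scene scale


@dataclass
class VoteTally:
    """Per-vertex histogram of observed labels across views."""

    votes: np.ndarray  # (N, n_labels) int64
    visibility: np.ndarray  # (N,) number of views in which the vertex was visible

    def __post_init__(self) -> None:
        assert (self.votes.sum(axis=1) == self.visibility).all(), (
            "each visible observation casts exactly one vote"
        )


def bake_view(
    mesh: LabeledMesh,
    pose: CameraPose,
    predicted_labels: np.ndarray,
    depth: np.ndarray,
    depth_tol: float | None = None,
) -> np.ndarray:
    """Per-vertex observed labels for one view (-1 where not visible).

    ``predicted_labels`` is an (H, W) integer label image (use
    ``scheme.decode_colors`` first if the prediction is RGB);``depth`` is
    the depth buffer of the render the prediction was made on, and
    ``pose`` must be that render's exact pose.
    """
    predicted_labels = np.asarray(predicted_labels)
    if predicted_labels.shape != depth.shape:
        raise ValueError("label image and depth buffer sizes differ")
    if predicted_labels.shape != (pose.height, pose.width):
        raise ValueError("image size does not match the camera pose")
    if depth_tol is None:
        lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
        depth_tol = DEPTH_TOL_FACTOR * float(np.linalg.norm(hi - lo))
    uv, z = pose.project(mesh.vertices)
    px = np.round(uv[:, 0]).astype(np.int64)
    py = np.round(uv[:, 1]).astype(np.int64)
    inside = (
        (z > 1e-6)
        & (px >= 0) & (px < pose.width)
        & (py >= 0) & (py < pose.height)
    )
    observed = np.full(mesh.n_vertices, -1, dtype=np.int64)
    idx = np.flatnonzero(inside)
    buf = depth[py[idx], px[idx]]
    visible = np.isfinite(buf) & (np.abs(buf - z[idx]) <= depth_tol)
    idx = idx[visible]
    observed[idx] = predicted_labels[py[idx], px[idx]]
    return observed


def accumulate_votes(observations, scheme: LabelScheme) -> VoteTally:
    """Tally per-view observations (lists from :func:`bake_view`)."""
    observations = list(observations)
    n_labels = len(scheme.palette)
    if not observations:
        return VoteTally(np.zeros((0, n_labels), np.int64), np.zeros(0, np.int64))
    n = len(observations[0])
    votes = np.zeros((n, n_labels), dtype=np.int64)
    for obs in observations:
        obs = np.asarray(obs)
        if len(obs) != n:
            raise ValueError("observations reference different meshes")
        seen = obs >= 0
        np.add.at(votes, (np.flatnonzero(seen), obs[seen]), 1)
    return VoteTally(votes, votes.sum(axis=1))


def finalize_labels(tally: VoteTally, scheme: LabelScheme) -> np.ndarray:
    """Majority label per vertex; never-visible vertices become void.

    Ties break toward the lowest label id, so results are deterministic.
    """
    labels = np.argmax(tally.votes, axis=1)  # argmax takes the first (lowest id) max
    labels[tally.visibility == 0] = scheme.void_id
    return labels.astype(np.int64)


def segment_components(mesh: LabeledMesh) -> dict[int, LabeledMesh]:
    """Split a labeled mesh into one submesh per non-void label present.

    Faces spanning several labels go to the majority label of their three
    vertices (tie: lowest id).  Vertices are partitioned by their own label.
    """
    out: dict[int, LabeledMesh] = {}
    face_labels = mesh.label[mesh.faces]  # (M, 3)
    lo = face_labels.min(axis=1)
    hi = face_labels.max(axis=1)
    mid = face_labels.sum(axis=1) - lo - hi
    majority = np.where(mid == hi, hi, lo)  # two-of-three, else lowest id
    for lid in mesh.present_labels():
        lid = int(lid)
        if lid == mesh.scheme.void_id:
            continue
        vsel = np.flatnonzero(mesh.label == lid)
        remap = -np.ones(mesh.n_vertices, dtype=np.int64)
        remap[vsel] = np.arange(len(vsel))
        fsel = mesh.faces[(majority == lid)]
        fsel = fsel[(remap[fsel] >= 0).all(axis=1)]  # faces fully inside the part
        out[lid] = LabeledMesh(
            mesh.vertices[vsel], remap[fsel], mesh.texture_color[vsel],
            mesh.label[vsel], mesh.scheme,
        )
    return out


@dataclass
class Metrics3D:
    """Vertex-level IoU per class and their mean for one mesh."""

    per_class_iou: dict[int, float]
    mean_iou: float


def metrics_3d(
    pred_labels: np.ndarray,
    true_labels: np.ndarray,
    scheme: LabelScheme,
    mask: np.ndarray | None = None,
) -> Metrics3D:
    """Per-class vertex IoU between predicted and true labelings.

    Classes absent from both prediction and truth are excluded from the
    mean (the convention used for sparsely represented classes).  An
    optional boolean ``mask`` restricts scoring to a vertex subset, e.g.
    vertices visible in at least one view.
    """
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    if pred_labels.shape != true_labels.shape:
        raise ValueError("label arrays have different lengths")
    if mask is not None:
        pred_labels = pred_labels[mask]
        true_labels = true_labels[mask]
    per_class: dict[int, float] = {}
    for e in scheme.entries:
        p = pred_labels == e.label_id
        t = true_labels == e.label_id
        union = int(np.logical_or(p, t).sum())
        if union == 0:
            continue
        per_class[e.label_id] = float(np.logical_and(p, t).sum() / union)
    mean = float(np.mean(list(per_class.values()))) if per_class else float("nan")
    return Metrics3D(per_class, mean)
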