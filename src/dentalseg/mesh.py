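"""Labeled triangle meshes and the 28-class dental label scheme.

A maxillary scan is represented as a triangle mesh with two per-vertex
channels: the acquired texture color (RGB) and a semantic class label.
The label scheme covers 26 tooth classes (16 permanent including third
molars, 10 primary), one class for the palatal rugae patch, and a void
class (gingiva plus background, colored black).  Labels are stored as
small integers; on disk they travel as palette colors in ordinary PLY
vertex-color channels, so any mesh viewer displays the segmentation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import trimesh

__all__ = [
    "LabelEntry",
    "LabelScheme",
    "LabeledMesh",
    "PLYFormatError",
    "default_label_scheme",
    "labels_from_colors",
    "read_ply",
    "write_ply",
]

# Role tags for scheme entries.
ROLE_PERMANENT = "permanent-tooth"
ROLE_PRIMARY = "primary-tooth"
ROLE_THIRD_MOLAR = "third-molar"
ROLE_RUGAE = "rugae"
ROLE_VOID = "void"

VOID = 0  #: label id of the void (gingiva + background) class
RUGAE = 17  #: label id of the palatal rugae class


class PLYFormatError(ValueError):
    """Raised when a PLY file does not meet the expected layout."""


@dataclass(frozen=True)
class LabelEntry:
    """One class of the label scheme: id, human name, palette color, role."""

    label_id: int
    name: str
    color: tuple[int, int, int]
    role: str


class LabelScheme:
    """Bidirectional mapping between label ids, names and palette colors.

    Colors must be unique across entries (they encode labels on disk and in
    rendered label images); the void class is always black.
    """

    def __init__(self, entries: Sequence[LabelEntry]):
        self.entries = tuple(entries)
        colors = [e.color for e in self.entries]
        if len(set(colors)) != len(colors):
            raise ValueError("label scheme colors must be unique")
        voids = [e for e in self.entries if e.role == ROLE_VOID]
        if len(voids) != 1 or voids[0].color != (0, 0, 0):
            raise ValueError("scheme needs exactly one void entry, colored black")
        self._by_id = {e.label_id: e for e in self.entries}
        self._by_name = {e.name: e for e in self.entries}
        self._by_color = {e.color: e.label_id for e in self.entries}
        self.void_id = voids[0].label_id
        n = max(self._by_id) + 1
        self._palette = np.zeros((n, 3), dtype=np.uint8)
        for e in self.entries:
            self._palette[e.label_id] = e.color

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, label_id: int) -> bool:
        return int(label_id) in self._by_id

    def __getitem__(self, label_id: int) -> LabelEntry:
        return self._by_id[int(label_id)]

    def by_name(self, name: str) -> LabelEntry:
        return self._by_name[name]

    @property
    def palette(self) -> np.ndarray:
        """(max_id+1, 3) uint8 array mapping label id -> RGB color."""
        return self._palette

    def ids_with_role(self, *roles: str) -> tuple[int, ...]:
        return tuple(e.label_id for e in self.entries if e.role in roles)

    @property
    def tooth_ids(self) -> tuple[int, ...]:
        """All 26 tooth classes (permanent, third molars, primary)."""
        return self.ids_with_role(ROLE_PERMANENT, ROLE_THIRD_MOLAR, ROLE_PRIMARY)

    @property
    def adult_tooth_ids(self) -> tuple[int, ...]:
        """Permanent teeth excluding third molars (the 'adult teeth' subset)."""
        return self.ids_with_role(ROLE_PERMANENT)

    def colors_for(self, labels: np.ndarray) -> np.ndarray:
        """Palette colors (uint8, N x 3) for an array of label ids."""
        labels = np.asarray(labels, dtype=np.int64)
        if labels.size and (labels.min() < 0 or labels.max() >= len(self._palette)):
            raise ValueError("label id outside the scheme")
        return self._palette[labels]

    def decode_colors(self, colors: np.ndarray) -> np.ndarray:
        """Exact-match decoding of RGB colors to label ids.

        Any color not in the palette raises: label channels are produced
        without anti-aliasing, so a mixed color always indicates a bug
        upstream, and nearest-color guessing would hide it.
        """
        colors = np.asarray(colors)
        if colors.ndim != 2 or colors.shape[1] != 3:
            raise ValueError("expected an (N, 3) color array")
        out = np.empty(len(colors), dtype=np.int64)
        for i, c in enumerate(colors):
            key = (int(c[0]), int(c[1]), int(c[2]))
            try:
                out[i] = self._by_color[key]
            except KeyError:
                raise ValueError(
                    f"color {key} at vertex {i} is not in the label palette"
                ) from None
        return out


def _permanent_names() -> list[tuple[str, str]]:
    kinds = [
        "central incisor", "lateral incisor", "canine", "first bicuspid",
        "second bicuspid", "first molar", "second molar", "third molar",
    ]
    out = []
    for side in ("left", "right"):
        for k in kinds:
            role = ROLE_THIRD_MOLAR if k == "third molar" else ROLE_PERMANENT
            out.append((f"{side} {k}", role))
    return out


def _primary_names() -> list[str]:
    kinds = [
        "primary central incisor", "primary lateral incisor", "primary canine",
        "first primary molar", "second primary molar",
    ]
    return [f"{side} {k}" for side in ("left", "right") for k in kinds]


def _lattice_colors() -> list[tuple[int, int, int]]:
    # Maximally separated RGB lattice {0, 85, 170, 255}^3, enumerated in a
    # fixed order; black is reserved for void and [85,85,0] for the right
    # central incisor (the one color the scheme inherits from convention).
    levels = (255, 170, 85, 0)
    reserved = {(0, 0, 0), (85, 85, 0)}
    out = []
    for r in levels:
        for g in levels:
            for b in levels:
                c = (r, g, b)
                if c not in reserved:
                    out.append(c)
    return out


def default_label_scheme() -> LabelScheme:
    """The fixed 28-class scheme: 26 teeth, rugae, and void.

    The right central incisor is [85, 85, 0] and void is black; the
    remaining 26 colors are drawn deterministically from the
    {0, 85, 170, 255}^3 lattice so they are unique and stable across runs.
    """
    free = iter(_lattice_colors())
    entries = [LabelEntry(VOID, "void", (0, 0, 0), ROLE_VOID)]
    next_id = 1
    for name, role in _permanent_names():
        color = (85, 85, 0) if name == "right central incisor" else next(free)
        entries.append(LabelEntry(next_id, name, color, role))
        next_id += 1
    entries.append(LabelEntry(RUGAE, "rugae", next(free), ROLE_RUGAE))
    next_id += 1
    for name in _primary_names():
        entries.append(LabelEntry(next_id, name, next(free), ROLE_PRIMARY))
        next_id += 1
    assert len(entries) == 28
    return LabelScheme(entries)


@dataclass
class LabeledMesh:
    """Triangle mesh with per-vertex texture color and class label.

    Coordinates are millimetres throughout; no unit conversion happens
    anywhere in the package.
    """

    vertices: np.ndarray  # (N, 3) float64, mm
    faces: np.ndarray  # (M, 3) int64 vertex indices
    texture_color: np.ndarray  # (N, 3) uint8 RGB
    label: np.ndarray  # (N,) int64 label ids
    scheme: LabelScheme = field(default_factory=default_label_scheme)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        self.texture_color = np.ascontiguousarray(self.texture_color, dtype=np.uint8)
        self.label = np.ascontiguousarray(self.label, dtype=np.int64)
        n = len(self.vertices)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if not np.isfinite(self.vertices).all():
            raise ValueError("vertex coordinates must be finite")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("face index out of range")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (M, 3) triangles")
        if self.texture_color.shape != (n, 3):
            raise ValueError("texture_color must be (N, 3)")
        if self.label.shape != (n,):
            raise ValueError("label must be (N,)")
        for lid in np.unique(self.label):
            if int(lid) not in self.scheme:
                raise ValueError(f"label id {int(lid)} not in the scheme")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex normals (unit length, (N, 3))."""
        v, f = self.vertices, self.faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        out = np.zeros_like(v)
        for k in range(3):
            np.add.at(out, f[:, k], fn)
        norm = np.linalg.norm(out, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return out / norm

    def vertices_with_label(self, label_id: int) -> np.ndarray:
        return np.flatnonzero(self.label == label_id)

    def present_labels(self) -> np.ndarray:
        return np.unique(self.label)

    def copy(self) -> "LabeledMesh":
        return LabeledMesh(
            self.vertices.copy(), self.faces.copy(),
            self.texture_color.copy(), self.label.copy(), self.scheme,
        )


def labels_from_colors(mesh_or_colors, scheme: LabelScheme) -> np.ndarray:
    """Decode per-vertex labels from palette colors (exact match, black=void)."""
    colors = (
        mesh_or_colors.texture_color
        if isinstance(mesh_or_colors, LabeledMesh)
        else mesh_or_colors
    )
    return scheme.decode_colors(colors)


def _read_ply_header(path: Path) -> dict:
    """Minimal header scan used to validate layout before delegating to trimesh."""
    info: dict = {"vertex_props": [], "n_faces": None}
    with open(path, "rb") as fh:
        first = fh.readline().strip()
        if first != b"ply":
            raise PLYFormatError(f"{path}: not a PLY file")
        element = None
        while True:
            line = fh.readline()
            if not line:
                raise PLYFormatError(f"{path}: truncated header")
            parts = line.decode("ascii", "replace").split()
            if not parts:
                continue
            if parts[0] == "end_header":
                break
            if parts[0] == "element":
                element = parts[1]
                if element == "face":
                    info["n_faces"] = int(parts[2])
            elif parts[0] == "property" and element == "vertex":
                info["vertex_props"].append(parts[-1])
    return info


def read_ply(path, scheme: LabelScheme | None = None) -> LabeledMesh:
    """Read a textured PLY mesh (ASCII or binary little-endian).

    The file must carry per-vertex ``x/y/z`` and ``red/green/blue``
    properties and triangle faces.  If ``scheme`` is given the vertex
    colors are decoded as labels (exact palette match); otherwise every
    vertex is void and the colors are kept as texture.
    """
    path = Path(path)
    header = _read_ply_header(path)
    for prop in ("red", "green", "blue"):
        if prop not in header["vertex_props"]:
            raise PLYFormatError(f"{path}: missing vertex color property '{prop}'")
    tm = trimesh.load(path, file_type="ply", process=False)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if header["n_faces"] is not None and len(faces) != header["n_faces"]:
        raise PLYFormatError(f"{path}: non-triangle faces are not supported")
    colors = np.asarray(tm.visual.vertex_colors)[:, :3].astype(np.uint8)
    if scheme is None:
        scheme = default_label_scheme()
        label = np.zeros(len(tm.vertices), dtype=np.int64)
    else:
        label = scheme.decode_colors(colors)
    return LabeledMesh(np.asarray(tm.vertices), faces, colors, label, scheme)


def write_ply(
    mesh: LabeledMesh,
    path,
    encode_labels_as_colors: bool = False,
    binary: bool = False,
) -> None:
    """Write a LabeledMesh as PLY with uchar vertex colors.

    With ``encode_labels_as_colors`` the color channel carries the label
    palette instead of the texture, which is how segmentations are stored
    and exchanged.
    """
    colors = (
        mesh.scheme.colors_for(mesh.label)
        if encode_labels_as_colors
        else mesh.texture_color
    )
    rgba = np.column_stack([colors, np.full(len(colors), 255, dtype=np.uint8)])
    tm = trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.faces, vertex_colors=rgba, process=False
    )
    encoding = "binary" if binary else "ascii"
    data = tm.export(file_type="ply", encoding=encoding)
    if isinstance(data, str):
        data = data.encode("ascii")
    try:
        Path(path).write_bytes(data)
    except OSError as exc:
        raise IOError(f"cannot write PLY to {path}: {exc}") from exc
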