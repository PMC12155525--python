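"""Anatomical landmark sets for the maxillary coordinate frame.

Six landmarks define the anatomical frame of a scan: the cusps of the
left and right last molars and the incisor edge (three non-collinear
points spanning the occlusal plane), plus three points along the median
raphae on the palate midline, the most anterior of which is the incisive
papilla.  Landmark files are plain text, one ``name x y z`` line per
point, coordinates in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["LandmarkSet", "read_landmarks", "write_landmarks"]

_RAPHAE_NAMES = ("incisive_papilla", "raphae_mid", "raphae_posterior")
_OCCLUSAL_NAMES = ("molar_cusp_left", "molar_cusp_right", "incisor_edge")


@dataclass(frozen=True)
class LandmarkSet:
    """Six anatomical points: three occlusal, three along the median raphae.

    ``raphae_points`` is ordered anterior to posterior; its first row is
    the incisive papilla.
    """

    molar_cusp_left: np.ndarray
    molar_cusp_right: np.ndarray
    incisor_edge: np.ndarray
    raphae_points: np.ndarray  # (3, 3), row 0 = incisive papilla

    def __post_init__(self) -> None:
        for name in _OCCLUSAL_NAMES:
            p = np.asarray(getattr(self, name), dtype=np.float64).reshape(3)
            object.__setattr__(self, name, p)
        r = np.asarray(self.raphae_points, dtype=np.float64)
        if r.shape != (3, 3):
            raise ValueError("raphae_points must be (3, 3): three midline points")
        object.__setattr__(self, "raphae_points", r)
        a = self.occlusal_points
        if np.linalg.norm(np.cross(a[1] - a[0], a[2] - a[0])) < 1e-9:
            raise ValueError("occlusal landmarks are collinear")

    @property
    def incisive_papilla(self) -> np.ndarray:
        return self.raphae_points[0]

    @property
    def occlusal_points(self) -> np.ndarray:
        return np.stack([self.molar_cusp_left, self.molar_cusp_right, self.incisor_edge])

    @property
    def all_points(self) -> np.ndarray:
        return np.vstack([self.occlusal_points, self.raphae_points])

    def transformed(self, transform) -> "LandmarkSet":
        """Apply a rigid transform (4x4 or RigidTransform) to all six points."""
        H = np.asarray(getattr(transform, "matrix", transform), dtype=np.float64)
        move = lambda p: H[:3, :3] @ p + H[:3, 3]
        return LandmarkSet(
            move(self.molar_cusp_left),
            move(self.molar_cusp_right),
            move(self.incisor_edge),
            self.raphae_points @ H[:3, :3].T + H[:3, 3],
        )


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    lines = []
    for name, p in zip(_OCCLUSAL_NAMES, landmarks.occlusal_points):
        lines.append(f"{name} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    for name, p in zip(_RAPHAE_NAMES, landmarks.raphae_points):
        lines.append(f"{name} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_landmarks(path) -> LandmarkSet:
    points = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, *coords = line.split()
        if len(coords) != 3:
            raise ValueError(f"bad landmark line: {line!r}")
        points[name] = np.array([float(c) for c in coords])
    missing = [n for n in _OCCLUSAL_NAMES + _RAPHAE_NAMES if n not in points]
    if missing:
        raise ValueError(f"landmark file {path} is missing {missing}")
    return LandmarkSet(
        points["molar_cusp_left"],
        points["molar_cusp_right"],
        points["incisor_edge"],
        np.stack([points[n] for n in _RAPHAE_NAMES]),
    )
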