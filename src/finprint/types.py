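"""Core containers shared across the pipeline.

Coordinate convention (fixed throughout the package): images are numpy
arrays indexed ``[row, col]``; a *point* is ``(x, y)`` with ``x`` = column
(rightward along the body axis) and ``y`` = row (downward), 0-based, pixel
centers at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class FishImage:
    """One RGB still of a single fish on a green background.

    ``truth`` carries generator ground truth (landmarks, dot centroids,
    applied scene transform) when the image is synthetic; it is ``None``
    for real photographs.
    """

    image: np.ndarray  # (H, W, 3) uint8
    fish_id: Optional[int] = None
    session: str = "SS"
    image_id: str = ""
    condition: str = "tent"  # tent | aquarium
    truth: Optional[dict] = None


@dataclass
class Landmarks:
    """Anatomical reference points in de-skewed fish-object coordinates.

    EP = eye centroid, UP = upper-fin beginning, BP = belly border point
    directly below UP, NP = x-column of the narrowest pre-tail width.
    """

    EP: tuple[float, float]
    UP: tuple[float, float]
    BP: tuple[float, float]
    NP: int

    def as_dict(self) -> dict:
        return {
            "EP": list(self.EP),
            "UP": list(self.UP),
            "BP": list(self.BP),
            "NP": int(self.NP),
        }


@dataclass
class FishObject:
    """Segmented, optionally de-skewed fish region.

    ``transform`` is the 3x3 homogeneous matrix mapping original canvas
    (x, y, 1) coordinates into this object's frame; it accumulates the
    bounding-box crop, the de-skew rotation and any head-left flip, so
    ground-truth points can be projected for validation.
    """

    mask: np.ndarray  # (h, w) bool, exactly one connected component
    gray: np.ndarray  # (h, w) float, 0-255 grayscale crop
    rgb: Optional[np.ndarray] = None
    orientation_applied_deg: float = 0.0
    length_px: float = 0.0
    transform: np.ndarray = field(default_factory=lambda: np.eye(3))

    def to_object(self, points_xy: np.ndarray) -> np.ndarray:
        """Map canvas (x, y) points into this object's frame."""
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        h = np.hstack([pts, np.ones((len(pts), 1))])
        out = (self.transform @ h.T).T
        return out[:, :2]


@dataclass
class NormalizedROI:
    """Grayscale ROI resampled to the standard width of 1000 px.

    Height preserves the source crop's aspect ratio.  ``origin`` is the
    ROI's top-left corner in fish-object coordinates and ``scale`` the
    (sx, sy) factors applied, so object-frame points can be projected
    into ROI coordinates.
    """

    image: np.ndarray  # (h, 1000) float 0-255
    landmarks: Optional[Landmarks] = None
    origin: tuple[float, float] = (0.0, 0.0)
    scale: tuple[float, float] = (1.0, 1.0)

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def height(self) -> int:
        return self.image.shape[0]

    def project(self, points_obj_xy: np.ndarray) -> np.ndarray:
        """Project fish-object (x, y) points into normalized-ROI pixels."""
        pts = np.atleast_2d(np.asarray(points_obj_xy, dtype=float))
        out = np.empty_like(pts)
        out[:, 0] = (pts[:, 0] - self.origin[0]) * self.scale[0]
        out[:, 1] = (pts[:, 1] - self.origin[1]) * self.scale[1]
        return out


@dataclass
class DotPattern:
    """Unordered set of dot centroids in normalized-ROI coordinates.

    This is the fish's biometric signature: positions only, no shape or
    size descriptors.
    """

    points: np.ndarray  # (n, 2) float, columns (x, y)
    image_id: str = ""
    fish_id: Optional[int] = None
    session: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class RepresentativePattern:
    """Consensus subset of one fish's dots, in the reference frame.

    ``support[i]`` counts how many of the fish's aligned patterns contain
    a point within the acceptance radius of ``points[i]``.
    """

    points: np.ndarray
    support: np.ndarray
    n_source_patterns: int
    fish_id: Optional[int] = None
    session: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.support = np.asarray(self.support, dtype=int).reshape(-1)

    def __len__(self) -> int:
        return len(self.points)

    def as_pattern(self) -> DotPattern:
        return DotPattern(self.points, fish_id=self.fish_id, session=self.session)


@dataclass
class MatchResult:
    """Outcome of identifying one query against a gallery."""

    query_id: str
    true_id: Optional[int]
    predicted_id: int
    distances: dict  # fish_id -> final trimmed distance
    best_shifts: dict  # fish_id -> (dx, dy) of the best template shift
    session_pair: tuple[str, str] = ("", "")

    @property
    def correct(self) -> bool:
        return self.true_id is not None and self.predicted_id == self.true_id
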