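"""Facial regions of interest for remote photoplethysmography.

This module houses the 28 anatomically named facial regions used throughout
the package, each defined as an ordered list of keypoint indices in the
468-point face-mesh convention, together with the machinery that turns
per-frame landmarks into pixel masks and mean RGB traces.

Coordinate convention
---------------------
Landmarks are pixel coordinates with the origin at the top-left pixel's
*corner*: x grows rightward, y grows downward, and pixel ``(row i, col j)``
has its center at ``(j + 0.5, i + 0.5)``.  Adapters converting from
normalized ``[0, 1]`` face-mesh output should multiply by frame width and
height respectively.

A pixel belongs to a region iff its center lies inside the polygon formed by
connecting the region's keypoints in listed order (closing back to the
first) under the even-odd rule.  Polygons are implicitly clipped to the
frame bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, InputError

N_LANDMARKS = 468

# The 28 facial regions: (index k, name, keypoint list).  Keypoints refer to
# the 468-point face-mesh numbering (0-467); the listed order defines the
# polygon boundary.
_ROI_TABLE: tuple[tuple[int, str, tuple[int, ...]], ...] = (
    (1, "medial forehead", (10, 109, 108, 151, 337, 338)),
    (2, "left lateral forehead", (67, 103, 104, 105, 66, 107, 108, 109)),
    (3, "right lateral forehead", (297, 338, 337, 336, 296, 334, 333, 332)),
    (4, "glabella", (151, 108, 107, 55, 8, 285, 336, 337)),
    (5, "upper nasal dorsum", (8, 55, 193, 122, 196, 197, 419, 351, 417, 285)),
    (6, "lower nasal dorsum", (197, 196, 3, 51, 5, 281, 248, 419)),
    (7, "soft triangle", (4, 45, 134, 220, 237, 44, 1, 274, 457, 440, 363, 275)),
    (8, "left ala", (134, 131, 49, 102, 64, 219, 218, 237, 220)),
    (9, "right ala", (363, 440, 457, 438, 439, 294, 331, 279, 360)),
    (10, "nasal tip", (5, 51, 45, 4, 275, 281)),
    (11, "left lower nasal sidewall", (3, 217, 126, 209, 131, 134)),
    (12, "right lower nasal sidewall", (248, 363, 360, 429, 355, 437)),
    (13, "left mid nasal sidewall", (188, 114, 217, 236, 196)),
    (14, "right mid nasal sidewall", (412, 419, 456, 437, 343)),
    (15, "philtrum", (2, 97, 167, 37, 0, 267, 393, 326)),
    (16, "left upper lip", (97, 165, 185, 40, 39, 37, 167)),
    (17, "right upper lip", (326, 393, 267, 269, 270, 409, 391)),
    (18, "left nasolabial fold", (97, 98, 203, 186, 185, 165)),
    (19, "right nasolabial fold", (326, 391, 409, 410, 423, 327)),
    (20, "left temporal", (54, 21, 162, 127, 116, 143, 156, 70, 63, 68)),
    (21, "right temporal", (284, 298, 293, 300, 383, 372, 345, 356, 389, 251)),
    (22, "left malar", (126, 100, 118, 117, 116, 123, 147, 187, 205, 203, 129, 209)),
    (23, "right malar", (355, 429, 358, 423, 425, 411, 376, 352, 345, 346, 347, 329)),
    (24, "left lower cheek", (203, 205, 187, 147, 177, 215, 138, 172, 136, 135, 212, 186, 206)),
    (25, "right lower cheek", (423, 426, 410, 432, 364, 365, 397, 367, 435, 401, 376, 411, 425)),
    (26, "chin", (18, 83, 182, 194, 32, 140, 176, 148, 152, 377, 400, 369, 262, 418, 406, 313)),
    (27, "left marionette fold", (57, 212, 210, 169, 150, 149, 176, 140, 204, 43)),
    (28, "right marionette fold", (287, 273, 424, 369, 400, 378, 379, 394, 430, 432)),
)


@dataclass(frozen=True)
class ROIDefinition:
    """One named facial region: an ordered polygon over face-mesh keypoints."""

    index_k: int
    name: str
    keypoint_list: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.index_k <= 28:
            raise ConfigError(f"ROI index {self.index_k} outside 1-28")
        if len(self.keypoint_list) < 3:
            raise ConfigError(f"ROI {self.name!r} needs >= 3 keypoints")
        if len(set(self.keypoint_list)) != len(self.keypoint_list):
            raise ConfigError(f"ROI {self.name!r} has duplicate keypoints")
        for idx in self.keypoint_list:
            if not 0 <= idx < N_LANDMARKS:
                raise ConfigError(
                    f"ROI {self.name!r} keypoint {idx} outside 0-{N_LANDMARKS - 1}"
                )


@dataclass(frozen=True)
class FaceMeshFrame:
    """Per-frame landmarks: 468 (x, y) pixel coordinates.

    Coordinates may lie outside the frame bounds; clipping happens when the
    polygon mask is rasterized.  Depth values, if the upstream detector
    produced any, are dropped before this object is built.
    """

    frame_index: int
    landmarks: np.ndarray  # (468, 2) float array

    def __post_init__(self) -> None:
        pts = np.asarray(self.landmarks, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise InputError(
                f"expected {N_LANDMARKS} (x, y) landmarks, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise InputError("landmark coordinates must be finite")
        if self.frame_index < 0:
            raise InputError("frame_index must be non-negative")
        object.__setattr__(self, "landmarks", pts)


@dataclass(frozen=True)
class ROIMask:
    """Boolean inclusion grid for one region on one frame."""

    mask: np.ndarray  # (height, width) bool

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class RGBTrace:
    """Per-frame mean (R, G, B) intensities for one region.

    ``samples`` is an (n_frames, 3) array on the 0-255 scale; ``valid_mask``
    is False on frames whose region mask was empty (the sample there is a
    placeholder and must not be consumed).
    """

    frame_rate: float
    samples: np.ndarray  # (n, 3) float
    valid_mask: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.frame_rate <= 0:
            raise InputError("frame_rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise InputError("samples must be an (n, 3) array")
        if self.valid_mask.shape != (self.samples.shape[0],):
            raise InputError("valid_mask length must match samples")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


def load_roi_table() -> tuple[ROIDefinition, ...]:
    """Return all 28 region definitions in index order."""
    return tuple(ROIDefinition(k, name, kps) for k, name, kps in _ROI_TABLE)


def get_roi(key: int | str) -> ROIDefinition:
    """Look one region up by index (1-28) or by exact name."""
    for roi in load_roi_table():
        if roi.index_k == key or roi.name == key:
            return roi
    raise ConfigError(f"unknown ROI {key!r}")


def roi_table_as_json() -> str:
    """Canonical JSON export of the region table."""
    payload = [
        {"index": r.index_k, "name": r.name, "keypoints": list(r.keypoint_list)}
        for r in load_roi_table()
    ]
    return json.dumps(payload, separators=(",", ":"), sort_keys=True)


def export_roi_table(path) -> None:
    with open(path, "w") as fh:
        fh.write(roi_table_as_json())


def _even_odd_inside(vertices: np.ndarray, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Vectorized even-odd point-in-polygon test.

    ``vertices`` is (m, 2); ``px``/``py`` are broadcastable arrays of query
    coordinates.  Uses the half-open crossing rule, so points exactly on a
    horizontal edge are handled consistently.
    """
    inside = np.zeros(np.broadcast(px, py).shape, dtype=bool)
    x1, y1 = vertices[:, 0], vertices[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for k in range(len(vertices)):
        if y1[k] == y2[k]:
            continue  # horizontal edge never crosses the upward ray rule
        crosses = (y1[k] > py) != (y2[k] > py)
        if not np.any(crosses):
            continue
        x_int = x1[k] + (py - y1[k]) * (x2[k] - x1[k]) / (y2[k] - y1[k])
        inside ^= crosses & (px < x_int)
    return inside


def polygon_mask(
    frame: FaceMeshFrame, roi: ROIDefinition, height: int, width: int
) -> ROIMask:
    """Rasterize one region's polygon on a ``height`` x ``width`` frame.

    A pixel is included iff its center lies inside the closed polygon under
    the even-odd rule; parts of the polygon outside the frame are clipped.
    """
    if height < 1 or width < 1:
        raise InputError("frame dimensions must be >= 1")
    verts = frame.landmarks[list(roi.keypoint_list)]
    mask = np.zeros((height, width), dtype=bool)
    # Restrict rasterization to the polygon's bounding box within the frame.
    r0 = max(int(np.floor(verts[:, 1].min() - 0.5)), 0)
    r1 = min(int(np.ceil(verts[:, 1].max() - 0.5)) + 1, height)
    c0 = max(int(np.floor(verts[:, 0].min() - 0.5)), 0)
    c1 = min(int(np.ceil(verts[:, 0].max() - 0.5)) + 1, width)
    if r0 >= r1 or c0 >= c1:
        return ROIMask(mask)
    px = np.arange(c0, c1) + 0.5
    py = (np.arange(r0, r1) + 0.5)[:, None]
    mask[r0:r1, c0:c1] = _even_odd_inside(verts, px, py)
    return ROIMask(mask)


def extract_rgb_trace(
    frames: Iterable[np.ndarray],
    mesh_frames: Sequence[FaceMeshFrame],
    roi: ROIDefinition,
    frame_rate: float,
) -> RGBTrace:
    """Average each frame's pixels over the region mask into an RGB trace.

    ``frames`` yields (H, W, 3) arrays on the 0-255 scale, one per landmark
    record.  Frames whose mask is empty get ``valid_mask=False`` and a
    placeholder sample of zeros.
    """
    if frame_rate <= 0:
        raise InputError("frame_rate must be positive")
    samples: list[np.ndarray] = []
    valid: list[bool] = []
    n_mesh = len(mesh_frames)
    count = 0
    for i, frame in enumerate(frames):
        if i >= n_mesh:
            raise InputError(
                f"frame/landmark count mismatch: {n_mesh} landmark records "
                f"but more frames supplied"
            )
        arr = np.asarray(frame, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise InputError("frames must be (H, W, 3) arrays")
        m = polygon_mask(mesh_frames[i], roi, arr.shape[0], arr.shape[1])
        if m.pixel_count == 0:
            samples.append(np.zeros(3))
            valid.append(False)
        else:
            samples.append(arr[m.mask].mean(axis=0))
            valid.append(True)
        count += 1
    if count != n_mesh:
        raise InputError(
            f"frame/landmark count mismatch: {count} frames vs {n_mesh} landmark records"
        )
    return RGBTrace(frame_rate, np.array(samples), np.array(valid, dtype=bool))
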