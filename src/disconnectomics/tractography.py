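"""Streamline data model, TRK/TCK I/O, resampling and visitation maps.

Streamlines are polylines in world mm. Format quirks (TRK's voxel-space
points) are normalized to world mm at read time via nibabel, so nothing
downstream ever sees format-specific coordinates.

Voxel visitation uses dense arc-length resampling followed by
nearest-voxel snapping: with a step no larger than half the smallest voxel
edge a segment cannot skip over a voxel it crosses, so the visitation map
is exact for practical purposes and bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import nibabel as nib
import numpy as np

from .volumes import ImageVolume, LesionMask, check_same_grid, voxel_indices

__all__ = [
    "Tractogram",
    "read_tractogram",
    "write_tractogram",
    "resample_streamline",
    "streamline_voxels",
    "streamlines_through_mask",
    "visitation_map",
    "default_step",
]


@dataclasses.dataclass
class Tractogram:
    """Whole-brain streamline set of one normative control, in world mm."""

    streamlines: list  # list of (N_i, 3) float arrays, N_i >= 2
    control_id: str = ""
    space: str = "MNI152"

    def __post_init__(self) -> None:
        cleaned = []
        for i, sl in enumerate(self.streamlines):
            arr = np.asarray(sl, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError(
                    f"streamline {i} of {self.control_id!r}: need >=2 points x 3 coords,"
                    f" got shape {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(
                    f"streamline {i} of {self.control_id!r} has non-finite coordinates"
                )
            cleaned.append(arr)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)


def default_step(grid: ImageVolume) -> float:
    """Default resampling step: half the smallest voxel edge (mm)."""
    return 0.5 * float(min(grid.voxel_sizes))


def read_tractogram(path: str | Path, control_id: str | None = None) -> Tractogram:
    """Read a TRK or TCK file; points are returned in world (RAS) mm.

    nibabel applies the TRK header transform, so both formats yield the
    same coordinates for the same geometry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tf = nib.streamlines.load(str(path))  # raises on unknown magic / truncation
    streamlines = [np.asarray(s, dtype=float) for s in tf.streamlines]
    if not streamlines:
        raise ValueError(f"{path.name}: tractogram contains no streamlines")
    if control_id is None:
        control_id = path.name.split(".")[0]
    return Tractogram(streamlines, control_id=control_id)


def write_tractogram(
    t: Tractogram, path: str | Path, grid: ImageVolume | None = None
) -> None:
    """Write a tractogram to TCK, or to TRK when a reference grid is given.

    TRK headers need the grid geometry (shape, affine); TCK does not.
    """
    path = Path(path)
    nt = nib.streamlines.Tractogram(
        [s.astype(np.float64) for s in t.streamlines], affine_to_rasmm=np.eye(4)
    )
    suffix = path.name.lower()
    if suffix.endswith(".tck"):
        nib.streamlines.save(nt, str(path))
    elif suffix.endswith(".trk"):
        if grid is None:
            raise ValueError("writing TRK requires a reference grid for the header")
        header = {
            "voxel_to_rasmm": grid.affine.astype(np.float32),
            "dimensions": np.asarray(grid.shape, dtype=np.int16),
            "voxel_sizes": grid.voxel_sizes.astype(np.float32),
            "voxel_order": "".join(nib.aff2axcodes(grid.affine)),
        }
        nib.streamlines.save(nt, str(path), header=header)
    else:
        raise ValueError(f"unsupported tractogram format: {path.name}")


def resample_streamline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at even arc-length spacing <= ``step`` mm.

    Output points lie exactly on the original polyline and the endpoints are
    preserved. A step larger than the total length returns endpoints only.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline has non-finite coordinates")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg.sum())
    if total == 0.0:
        return np.vstack([pts[0], pts[-1]])
    # tiny slack so a length that is an exact multiple of step does not gain a segment
    n_seg = max(1, math.ceil(total / step - 1e-9))
    s = np.linspace(0.0, total, n_seg + 1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    out = np.empty((n_seg + 1, 3))
    for d in range(3):
        out[:, d] = np.interp(s, cum, pts[:, d])
    out[0], out[-1] = pts[0], pts[-1]
    return out


def streamline_voxels(
    sl: np.ndarray, grid: ImageVolume, step: float
) -> np.ndarray:
    """Flat indices of the in-grid voxels visited by one streamline."""
    pts = resample_streamline(sl, step)
    idx = voxel_indices(pts, grid.affine)
    shape = np.asarray(grid.shape)
    inb = np.all((idx >= 0) & (idx < shape), axis=1)
    if not inb.any():
        return np.empty(0, dtype=np.int64)
    flat = np.ravel_multi_index(idx[inb].T, grid.shape)
    return np.unique(flat)


def streamlines_through_mask(
    t: Tractogram, mask: LesionMask, step: float | None = None
) -> Tractogram:
    """Subset of streamlines with at least one resampled point in the mask."""
    if len(t) == 0:
        raise ValueError("empty tractogram")
    grid = mask.volume
    if step is None:
        step = default_step(grid)
    flat_mask = mask.data.ravel() > 0
    selected = [
        sl
        for sl in t.streamlines
        if (v := streamline_voxels(sl, grid, step)).size and flat_mask[v].any()
    ]
    # an empty subset is a legal result (lesion off every fiber of this control)
    return Tractogram(selected, control_id=t.control_id, space=t.space)


def visitation_map(
    streamlines, grid: ImageVolume, step: float | None = None
) -> ImageVolume:
    """Binary map of every voxel traversed by any of the streamlines."""
    if step is None:
        step = default_step(grid)
    if isinstance(streamlines, Tractogram):
        streamlines = streamlines.streamlines
    out = np.zeros(int(np.prod(grid.shape)), dtype=np.uint8)
    for sl in streamlines:
        out[streamline_voxels(sl, grid, step)] = 1
    return grid.like(out.reshape(grid.shape))
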