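"""Volume data model, NIfTI I/O and mask utilities.

Every analysis runs in a single common template grid (one shape, one
voxel-to-world affine); volumes on different grids never mix. World
coordinates are millimetres, voxel indices are 0-based.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

#: absolute tolerance when deciding two volumes share the same affine
GRID_ATOL = 1e-4

#: 26-connectivity structuring element shared with cluster extraction
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class GridMismatchError(ValueError):
    """Raised when volumes that must share a grid do not."""


@dataclasses.dataclass
class ImageVolume:
    """A 3D scalar volume with a voxel-index -> world-mm affine.

    Carrier for lesion masks, disconnection probability maps and
    voxel-wise statistic maps alike.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError(f"degenerate volume shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if not np.all(np.isfinite(self.affine)):
            raise ValueError("affine contains non-finite entries")
        if abs(np.linalg.det(self.affine[:3, :3])) <= 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge length of a voxel along each axis, in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=GRID_ATOL
        )

    def like(self, data: np.ndarray) -> "ImageVolume":
        """New volume with `data` on this volume's grid."""
        return ImageVolume(data, self.affine.copy())


@dataclasses.dataclass
class LesionMask:
    """Strictly binary lesion mask for one subject."""

    volume: ImageVolume
    subject_id: str = ""

    def __post_init__(self) -> None:
        vals = np.unique(self.volume.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(
                f"lesion mask for {self.subject_id!r} is not binary: values {vals[:5]}"
            )
        if not np.any(self.volume.data):
            log.warning("lesion mask for %r is empty", self.subject_id)

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


def check_same_grid(*volumes: ImageVolume) -> None:
    """Raise :class:`GridMismatchError` unless all volumes share one grid."""
    first = volumes[0]
    for v in volumes[1:]:
        if not first.same_grid(v):
            raise GridMismatchError(
                f"volumes on different grids: {first.shape}/{v.shape} or affines "
                f"differing beyond {GRID_ATOL}"
            )


def read_volume(path: str | Path) -> ImageVolume:
    """Read a single 3D NIfTI image.

    Integer-coded data (masks, labels) is returned with its stored dtype so
    round-trips are bit exact; 4D images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        data = np.asarray(img.dataobj)[..., 0]
    elif len(shape) != 3:
        raise ValueError(
            f"{path.name}: expected a single 3D image, got shape {shape} "
            "(4D inputs must be split into single volumes first)"
        )
    else:
        data = np.asarray(img.dataobj)
    vol = ImageVolume(data, np.asarray(img.affine, dtype=float))
    return vol


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI.

    Integer/boolean data is stored as unsigned 8-bit (masks, labels);
    floating data as 32-bit float (probability and statistic maps).
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = vol.data
    if data.dtype == bool or np.issubdtype(data.dtype, np.integer):
        out = data.astype(np.uint8)
    else:
        out = data.astype(np.float32)
    img = nib.Nifti1Image(out, vol.affine)
    nib.save(img, str(path))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero.

    Unlike banker's rounding this is reproducible voxel snapping: 0.5 -> 1,
    -0.5 -> -1, independent of parity.
    """
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def world_to_voxel(point, vol: ImageVolume) -> np.ndarray:
    """Map one world-mm point to the nearest voxel index (may be out of grid)."""
    return voxel_indices(np.asarray(point, dtype=float)[None, :], vol.affine)[0]


def voxel_indices(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Vectorized world->voxel mapping for an (N, 3) array of mm points."""
    inv = np.linalg.inv(affine)
    ijk = points @ inv[:3, :3].T + inv[:3, 3]
    return _round_half_away(ijk).astype(np.int64)


def apply_affine_to_mask(
    mask: LesionMask, transform: np.ndarray, target: ImageVolume
) -> LesionMask:
    """Resample a binary mask through a world-space affine onto a target grid.

    Nearest-neighbour only (pull-back of target voxel centres), so the
    output is strictly binary. An all-zero result is legal but logged.
    """
    transform = np.asarray(transform, dtype=float)
    if abs(np.linalg.det(transform[:3, :3])) <= 1e-12:
        raise ValueError("transform is not invertible")
    tinv = np.linalg.inv(transform)
    idx = np.indices(target.shape).reshape(3, -1).T.astype(float)
    world = idx @ target.affine[:3, :3].T + target.affine[:3, 3]
    src_world = world @ tinv[:3, :3].T + tinv[:3, 3]
    src_idx = voxel_indices(src_world, mask.volume.affine)
    shape = mask.volume.shape
    inb = np.all((src_idx >= 0) & (src_idx < np.array(shape)), axis=1)
    out = np.zeros(target.shape, dtype=np.uint8).ravel()
    flat_src = np.ravel_multi_index(src_idx[inb].T, shape)
    out[inb] = (mask.volume.data.ravel()[flat_src] > 0).astype(np.uint8)
    out = out.reshape(target.shape)
    if not out.any():
        log.warning(
            "resampled mask for %r is empty on the target grid", mask.subject_id
        )
    return LesionMask(ImageVolume(out, target.affine.copy()), mask.subject_id)


def lesion_summary(mask: LesionMask) -> dict:
    """Lesion size and count summary.

    Components are counted with 26-connectivity, the same convention used
    for statistical-map clusters; volume is voxel count x voxel volume.
    """
    n_vox = int(np.count_nonzero(mask.data))
    if n_vox == 0:
        return {"volume_mm3": 0.0, "n_voxels": 0, "n_components": 0}
    _, n_comp = ndimage.label(mask.data > 0, structure=STRUCT_26)
    return {
        "volume_mm3": n_vox * mask.volume.voxel_volume,
        "n_voxels": n_vox,
        "n_components": int(n_comp),
    }
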