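"""Per-subject voxel-wise disconnection probability maps.

For one lesion and N normative tractograms: a control "visits" a voxel if
any of its streamlines passing through the lesion traverses that voxel;
the disconnectome value at a voxel is the fraction of controls visiting
it, a percentage-overlap of lesion-filtered visitation maps. Values are
stored as proportions in [0, 1] (exact multiples of 1/N) and converted to
percent only at report time.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .tractography import Tractogram, default_step, streamline_voxels
from .volumes import ImageVolume, LesionMask, check_same_grid

log = logging.getLogger(__name__)

__all__ = [
    "DisconnectomeMap",
    "disconnectome_for_subject",
    "disconnectome_batch",
    "threshold_map",
    "control_voxel_cache",
]


@dataclasses.dataclass
class DisconnectomeMap:
    """Voxel-wise disconnection probability volume for one subject."""

    volume: ImageVolume
    subject_id: str = ""
    n_controls: int = 0

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


def control_voxel_cache(
    controls: list[Tractogram], grid: ImageVolume, step: float
) -> list[list[np.ndarray]]:
    """Per control, per streamline: flat indices of visited in-grid voxels.

    Resampling each streamline once and reusing the result across subjects
    is what makes cohort-sized batches cheap; the per-subject result is
    identical to recomputing from scratch because selection and visitation
    are pure functions of these voxel sets.
    """
    return [
        [streamline_voxels(sl, grid, step) for sl in tg.streamlines]
        for tg in controls
    ]


def _map_from_cache(
    lesion_flat: np.ndarray, cache: list[list[np.ndarray]], n_voxels: int
) -> np.ndarray:
    counts = np.zeros(n_voxels, dtype=np.int32)
    for control in cache:
        visited = np.zeros(n_voxels, dtype=bool)
        any_hit = False
        for vox in control:
            if vox.size and lesion_flat[vox].any():
                visited[vox] = True
                any_hit = True
        if any_hit:
            counts[visited] += 1
    return counts


def disconnectome_for_subject(
    lesion: LesionMask,
    controls: list[Tractogram],
    grid: ImageVolume | None = None,
    step: float | None = None,
    _cache: list[list[np.ndarray]] | None = None,
) -> DisconnectomeMap:
    """Disconnection probability map for one lesion against N controls."""
    if not controls and _cache is None:
        raise ValueError("need at least one normative tractogram")
    if grid is None:
        grid = lesion.volume
    check_same_grid(grid, lesion.volume)
    if step is None:
        step = default_step(grid)
    if not np.any(lesion.data):
        raise ValueError(f"lesion mask for {lesion.subject_id!r} is empty")
    cache = (
        _cache
        if _cache is not None
        else control_voxel_cache(controls, grid, step)
    )
    n = len(cache)
    counts = _map_from_cache(lesion.data.ravel() > 0, cache, int(np.prod(grid.shape)))
    if not counts.any():
        log.warning(
            "subject %r: lesion intersects no streamline in any control",
            lesion.subject_id,
        )
    data = counts.astype(np.float64).reshape(grid.shape) / n
    return DisconnectomeMap(grid.like(data), lesion.subject_id, n_controls=n)


def disconnectome_batch(
    lesions: list[LesionMask],
    controls: list[Tractogram],
    grid: ImageVolume | None = None,
    step: float | None = None,
) -> tuple[list[DisconnectomeMap | None], dict[str, str]]:
    """Maps for a cohort; order-preserving, per-subject failures recorded.

    Returns (maps, errors): failed subjects get ``None`` in place and an
    entry in ``errors`` keyed by subject id; the batch continues.
    """
    if not lesions:
        raise ValueError("empty subject list")
    if not controls:
        raise ValueError("need at least one normative tractogram")
    if grid is None:
        grid = lesions[0].volume
    if step is None:
        step = default_step(grid)
    cache = control_voxel_cache(controls, grid, step)
    maps: list[DisconnectomeMap | None] = []
    errors: dict[str, str] = {}
    for lesion in lesions:
        try:
            maps.append(
                disconnectome_for_subject(lesion, controls, grid, step, _cache=cache)
            )
        except Exception as exc:  # noqa: BLE001 - per-subject isolation is the contract
            errors[lesion.subject_id] = str(exc)
            maps.append(None)
    return maps, errors


def threshold_map(d: DisconnectomeMap, tau: float) -> ImageVolume:
    """Binary volume of voxels disconnected with probability >= tau (inclusive).

    Only voxels with nonzero disconnection ever survive, so tau=0 selects
    "any disconnection" rather than the whole grid.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    keep = (d.data >= tau) & (d.data > 0)
    return d.volume.like(keep.astype(np.uint8))
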