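"""Cluster extraction on statistic maps and cluster-level follow-up.

Suprathreshold voxels (strictly above threshold, matching a literal
"pseudo-z > 3") are partitioned into connected components under 6-, 18-
or 26-connectivity. The negative tail is handled explicitly: callers
extract clusters of strongly negative bootstrap ratios by passing
``tail="negative"``, which thresholds ``-map`` and reports the signed
peak value.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import ndimage

from .disconnectome import DisconnectomeMap
from .volumes import ImageVolume, check_same_grid

log = logging.getLogger(__name__)

__all__ = [
    "extract_clusters",
    "cluster_disconnectivity",
    "correlate_with_battery",
    "BatteryCorrelations",
    "connectivity_structure",
]

_CONN_RANK = {6: 1, 18: 2, 26: 3}


def connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONN_RANK:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    return ndimage.generate_binary_structure(3, _CONN_RANK[connectivity])


def extract_clusters(
    stat_map: ImageVolume,
    threshold: float = 3.0,
    connectivity: int = 26,
    min_size_vox: int = 1,
    tail: str = "positive",
) -> tuple[pd.DataFrame, ImageVolume]:
    """Connected suprathreshold clusters of a voxel-wise statistic map.

    Returns a table (one row per cluster, sorted by size descending) and a
    label volume (0 background, cluster_id elsewhere). ``max_bsr`` is the
    most extreme statistic in the cluster — signed, so negative-tail
    clusters report negative peaks. Peak position ties break toward the
    lowest flat (C-order) voxel index. An empty table is a legal result.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if min_size_vox < 1:
        raise ValueError("min_size_vox must be >= 1")
    if tail not in ("positive", "negative"):
        raise ValueError(f"tail must be 'positive' or 'negative', got {tail!r}")
    data = stat_map.data if tail == "positive" else -stat_map.data
    supra = data > threshold
    labels, n = ndimage.label(supra, structure=connectivity_structure(connectivity))
    rows = []
    out = np.zeros(stat_map.shape, dtype=np.int32)
    if n:
        sizes = ndimage.sum_labels(supra, labels, index=np.arange(1, n + 1))
        order = np.argsort(-sizes, kind="stable")
        cluster_id = 0
        for rank in order:
            size = int(sizes[rank])
            if size < min_size_vox:
                continue
            cluster_id += 1
            comp = labels == rank + 1
            out[comp] = cluster_id
            flat = np.flatnonzero(comp.ravel())
            peak_flat = flat[np.argmax(data.ravel()[flat])]
            ijk = np.unravel_index(peak_flat, stat_map.shape)
            world = stat_map.affine[:3, :3] @ np.asarray(ijk) + stat_map.affine[:3, 3]
            rows.append(
                {
                    "cluster_id": cluster_id,
                    "size_vox": size,
                    "size_mm3": size * stat_map.voxel_volume,
                    "max_bsr": float(stat_map.data[ijk]),
                    "peak_i": int(ijk[0]),
                    "peak_j": int(ijk[1]),
                    "peak_k": int(ijk[2]),
                    "peak_x": float(world[0]),
                    "peak_y": float(world[1]),
                    "peak_z": float(world[2]),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "size_vox", "size_mm3", "max_bsr",
            "peak_i", "peak_j", "peak_k", "peak_x", "peak_y", "peak_z",
        ],
    )
    return table, stat_map.like(out)


def cluster_disconnectivity(
    maps: list[DisconnectomeMap], labels: ImageVolume
) -> pd.DataFrame:
    """Mean disconnection proportion per subject within each cluster."""
    ids = np.unique(labels.data)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("label volume contains no clusters")
    for m in maps:
        check_same_grid(labels, m.volume)
    values = np.array(
        [
            ndimage.mean(m.data, labels=labels.data, index=ids)
            for m in maps
        ]
    )
    return pd.DataFrame(
        values,
        index=[m.subject_id for m in maps],
        columns=[f"cluster_{int(i)}" for i in ids],
    )


@dataclasses.dataclass
class BatteryCorrelations:
    r: pd.DataFrame          # measures x predictors, Pearson r
    n: pd.DataFrame          # complete-pair count per cell
    notes: dict              # (measure, predictor) -> reason a cell is missing


def correlate_with_battery(
    cluster_values: pd.DataFrame,
    cohort: pd.DataFrame,
    battery_columns: list[str],
    extra_columns: tuple[str, ...] = ("moca", "brain_score"),
    min_pairs: int = 3,
) -> BatteryCorrelations:
    """Pearson correlations between cluster disconnectivity (plus MoCA and
    PLS brain scores) and the cognitive battery, pairwise complete.

    The battery is typically available only in a subsample, so each cell
    carries its own n; cells with fewer than ``min_pairs`` complete pairs
    or a constant column are set missing with a recorded reason.
    """
    if len(cohort) != len(cluster_values):
        raise ValueError("cohort table and cluster values must align row-for-row")
    predictors = cluster_values.reset_index(drop=True)
    coh = cohort.reset_index(drop=True)
    for col in extra_columns:
        if col in coh.columns:
            predictors[col] = coh[col]
    battery = coh[battery_columns]
    r = pd.DataFrame(index=battery_columns, columns=predictors.columns, dtype=float)
    n = pd.DataFrame(0, index=battery_columns, columns=predictors.columns, dtype=int)
    notes: dict = {}
    for meas in battery_columns:
        for pred in predictors.columns:
            pair = pd.concat([battery[meas], predictors[pred]], axis=1).dropna()
            n.loc[meas, pred] = len(pair)
            if len(pair) < min_pairs:
                notes[(meas, pred)] = f"only {len(pair)} complete pairs"
                continue
            a, b = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
            if a.std() == 0 or b.std() == 0:
                notes[(meas, pred)] = "constant column"
                continue
            r.loc[meas, pred] = float(np.corrcoef(a, b)[0, 1])
    return BatteryCorrelations(r=r, n=n, notes=notes)
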