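"""Cluster extraction vs a recursive flood-fill oracle, cluster
disconnectivity, and battery correlations."""

import numpy as np
import pandas as pd
import pytest

from disconnectomics.clusters import (
    cluster_disconnectivity,
    correlate_with_battery,
    extract_clusters,
)
from disconnectomics.disconnectome import DisconnectomeMap


def flood_fill_labels(supra, connectivity):
    """Independent oracle: iterative flood fill over an explicit
    neighbour stencil."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    labels = np.zeros(supra.shape, dtype=int)
    next_label = 0
    for start in zip(*np.nonzero(supra)):
        if labels[start]:
            continue
        next_label += 1
        stack = [start]
        labels[start] = next_label
        while stack:
            i, j, k = stack.pop()
            for di, dj, dk in offsets:
                n = (i + di, j + dj, k + dk)
                if all(0 <= n[d] < supra.shape[d] for d in range(3)):
                    if supra[n] and not labels[n]:
                        labels[n] = next_label
                        stack.append(n)
    return labels


def _same_partition(a, b):
    """Two label volumes describe the same partition (up to renaming)."""
    if not np.array_equal(a > 0, b > 0):
        return False
    mapping = {}
    for la, lb in zip(a[a > 0].ravel(), b[a > 0].ravel()):
        if mapping.setdefault(la, lb) != lb:
            return False
    return len(set(mapping.values())) == len(mapping)


class TestExtractClusters:
    def test_two_separated_cubes(self, grid16):
        data = np.zeros(grid16.shape)
        data[2:5, 2:5, 2:5] = 5.0
        data[10:12, 10:12, 10:12] = 4.0
        table, labels = extract_clusters(grid16.like(data), threshold=3.0)
        assert len(table) == 2
        assert list(table.size_vox) == [27, 8]  # sorted by size descending
        assert list(table.size_mm3) == pytest.approx([27 * 8.0, 8 * 8.0])
        assert table.max_bsr.iloc[0] == 5.0

    def test_threshold_is_strict(self, grid16):
        data = np.zeros(grid16.shape)
        data[5, 5, 5] = 3.0
        table, _ = extract_clusters(grid16.like(data), threshold=3.0)
        assert len(table) == 0
        data[5, 5, 5] = 3.0000001
        table, _ = extract_clusters(grid16.like(data), threshold=3.0)
        assert len(table) == 1 and table.size_vox.iloc[0] == 1

    def test_min_size_filter(self, grid16):
        data = np.zeros(grid16.shape)
        data[2:4, 2, 2] = 4.0      # 2 voxels
        data[10, 10, 10] = 4.0     # 1 voxel
        table, labels = extract_clusters(
            grid16.like(data), threshold=3.0, min_size_vox=2
        )
        assert len(table) == 1
        assert (labels.data > 0).sum() == 2

    def test_negative_tail_reports_signed_peak(self, grid16):
        data = np.zeros(grid16.shape)
        data[4:6, 4, 4] = -4.5
        pos, _ = extract_clusters(grid16.like(data), threshold=3.0)
        neg, labels = extract_clusters(
            grid16.like(data), threshold=3.0, tail="negative"
        )
        assert len(pos) == 0
        assert len(neg) == 1
        assert neg.max_bsr.iloc[0] == -4.5
        assert (labels.data > 0).sum() == 2

    def test_peak_coordinates_voxel_and_world(self, grid16):
        data = np.zeros(grid16.shape)
        data[3, 7, 9] = 6.0
        data[3, 7, 10] = 4.0
        table, _ = extract_clusters(grid16.like(data), threshold=3.0)
        row = table.iloc[0]
        assert (row.peak_i, row.peak_j, row.peak_k) == (3, 7, 9)
        assert (row.peak_x, row.peak_y, row.peak_z) == (6.0, 14.0, 18.0)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng, grid16):
        for _ in range(10):
            data = np.where(
                rng.uniform(size=grid16.shape) < 0.25,
                rng.uniform(3.01, 6.0, size=grid16.shape),
                0.0,
            )
            table, labels = extract_clusters(
                grid16.like(data), threshold=3.0, connectivity=connectivity
            )
            oracle = flood_fill_labels(data > 3.0, connectivity)
            assert _same_partition(labels.data, oracle)
            sizes = sorted(
                np.bincount(oracle.ravel())[1:], reverse=True
            )
            assert list(table.size_vox) == [int(s) for s in sizes if s > 0]


class TestClusterDisconnectivity:
    def _labels(self, grid):
        lab = np.zeros(grid.shape, dtype=np.int32)
        lab[2, 2, 2] = 1
        lab[5, 5, 5] = 2
        lab[5, 5, 6] = 2
        return grid.like(lab)

    def test_mean_within_cluster(self, grid16):
        labels = self._labels(grid16)
        data = np.zeros(grid16.shape)
        data[5, 5, 5], data[5, 5, 6] = 0.2, 0.4
        maps = [DisconnectomeMap(grid16.like(data), "s1")]
        cv = cluster_disconnectivity(maps, labels)
        assert cv.loc["s1", "cluster_1"] == 0.0
        assert cv.loc["s1", "cluster_2"] == pytest.approx(0.3)

    def test_all_zero_map_gives_zero_row(self, grid16):
        labels = self._labels(grid16)
        maps = [DisconnectomeMap(grid16.like(np.zeros(grid16.shape)), "s1")]
        assert (cluster_disconnectivity(maps, labels).loc["s1"] == 0).all()

    def test_linearity_in_maps(self, grid16, rng):
        labels = self._labels(grid16)
        a = rng.uniform(size=grid16.shape)
        b = rng.uniform(size=grid16.shape)
        alpha = 0.3
        cv = cluster_disconnectivity(
            [
                DisconnectomeMap(grid16.like(a), "a"),
                DisconnectomeMap(grid16.like(b), "b"),
                DisconnectomeMap(grid16.like(alpha * a + (1 - alpha) * b), "mix"),
            ],
            labels,
        )
        assert np.allclose(
            cv.loc["mix"], alpha * cv.loc["a"] + (1 - alpha) * cv.loc["b"]
        )

    def test_empty_labels_rejected(self, grid16):
        with pytest.raises(ValueError, match="no clusters"):
            cluster_disconnectivity(
                [DisconnectomeMap(grid16.like(np.zeros(grid16.shape)), "s")],
                grid16.like(np.zeros(grid16.shape, dtype=np.int32)),
            )


class TestBatteryCorrelation:
    def test_self_correlation_is_one(self):
        cv = pd.DataFrame({"cluster_1": [0.1, 0.5, 0.3, 0.9]},
                          index=[f"s{i}" for i in range(4)])
        cohort = pd.DataFrame({"copy": [0.1, 0.5, 0.3, 0.9]})
        bc = correlate_with_battery(cv, cohort, ["copy"], extra_columns=())
        assert bc.r.loc["copy", "cluster_1"] == pytest.approx(1.0)
        assert bc.n.loc["copy", "cluster_1"] == 4

    def test_constant_column_flagged_missing(self):
        cv = pd.DataFrame({"cluster_1": [0.1, 0.5, 0.3]})
        cohort = pd.DataFrame({"flat": [2.0, 2.0, 2.0]})
        bc = correlate_with_battery(cv, cohort, ["flat"], extra_columns=())
        assert np.isnan(bc.r.loc["flat", "cluster_1"])
        assert bc.notes[("flat", "cluster_1")] == "constant column"

    def test_too_few_pairs_flagged(self):
        cv = pd.DataFrame({"cluster_1": [0.1, 0.5, 0.3, 0.2]})
        cohort = pd.DataFrame({"sparse": [1.0, 2.0, np.nan, np.nan]})
        bc = correlate_with_battery(cv, cohort, ["sparse"], extra_columns=())
        assert np.isnan(bc.r.loc["sparse", "cluster_1"])
        assert "2 complete pairs" in bc.notes[("sparse", "cluster_1")]

    def test_subsample_n_reflects_missingness(self):
        cv = pd.DataFrame({"cluster_1": np.linspace(0, 1, 10)})
        vals = np.linspace(1, 0, 10)
        vals[7:] = np.nan
        cohort = pd.DataFrame({"test_a": vals})
        bc = correlate_with_battery(cv, cohort, ["test_a"], extra_columns=())
        assert bc.n.loc["test_a", "cluster_1"] == 7
        assert bc.r.loc["test_a", "cluster_1"] == pytest.approx(-1.0)

    def test_planted_negative_coupling_recovered(self, small_cohort):
        # generator plants battery = loading * (-disconnection) + noise,
        # so every battery/cluster correlation should come out negative
        c = small_cohort
        footprint = c.truth.footprints["target"].data > 0
        labels = c.grid.like(footprint.astype(np.int32))
        cv = cluster_disconnectivity(c.maps, labels)
        battery = [col for col in c.effect.battery_loadings]
        bc = correlate_with_battery(cv, c.behavior, battery, extra_columns=())
        rs = bc.r["cluster_1"].astype(float)
        assert (rs.dropna() < 0).all()
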