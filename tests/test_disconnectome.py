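"""Disconnectome map construction, checked against an independent
brute-force oracle that loops voxel-by-voxel over resampled points."""

import math

import numpy as np
import pytest

from disconnectomics.disconnectome import (
    disconnectome_batch,
    disconnectome_for_subject,
    threshold_map,
)
from disconnectomics.tractography import Tractogram
from disconnectomics.volumes import ImageVolume, LesionMask


def brute_force_disconnectome(lesion, controls, grid, step):
    """Independent per-point oracle: resample on the arc-length grid by
    hand, snap each point to its voxel, and count controls."""
    inv = np.linalg.inv(grid.affine)
    shape = grid.shape

    def points_to_voxels(pts):
        ijk = pts @ inv[:3, :3].T + inv[:3, 3]
        snapped = np.copysign(np.floor(np.abs(ijk) + 0.5), ijk).astype(int)
        return [
            tuple(v)
            for v in snapped
            if all(0 <= v[d] < shape[d] for d in range(3))
        ]

    def dense_points(sl):
        seg = np.linalg.norm(np.diff(sl, axis=0), axis=1)
        total = seg.sum()
        if total == 0:
            return sl[:1]
        n_seg = max(1, math.ceil(total / step - 1e-9))
        s = np.linspace(0, total, n_seg + 1)
        cum = np.concatenate([[0], np.cumsum(seg)])
        return np.column_stack([np.interp(s, cum, sl[:, d]) for d in range(3)])

    lesion_voxels = {tuple(v) for v in np.argwhere(lesion.data > 0)}
    counts = np.zeros(shape)
    for tg in controls:
        visited = set()
        for sl in tg.streamlines:
            vox = points_to_voxels(dense_points(sl))
            if any(v in lesion_voxels for v in vox):
                visited.update(vox)
        for v in visited:
            counts[v] += 1
    return counts / len(controls)


def _lesion_at(grid, voxels, sid="s1"):
    data = np.zeros(grid.shape, dtype=np.uint8)
    for v in voxels:
        data[v] = 1
    return LesionMask(grid.like(data), sid)


def _line(p0, p1, n=2):
    return np.linspace(p0, p1, n).astype(float)


class TestSingleSubject:
    def test_one_control_full_probability(self, grid16):
        lesion = _lesion_at(grid16, [(5, 5, 5)])
        sl = _line((4, 10, 10), (12, 10, 10))  # visits voxels (2..6, 5, 5)
        d = disconnectome_for_subject(lesion, [Tractogram([sl], "c0")], step=1.0)
        assert d.n_controls == 1
        assert np.all(d.data[2:7, 5, 5] == 1.0)
        assert d.data.sum() == 5.0

    def test_two_controls_one_intersecting_gives_half(self, grid16):
        lesion = _lesion_at(grid16, [(5, 5, 5)])
        hit = Tractogram([_line((4, 10, 10), (12, 10, 10))], "c0")
        miss = Tractogram([_line((4, 26, 26), (12, 26, 26))], "c1")
        d = disconnectome_for_subject(lesion, [hit, miss], step=1.0)
        assert set(np.unique(d.data)) == {0.0, 0.5}
        assert np.all(d.data[2:7, 5, 5] == 0.5)

    def test_non_intersecting_lesion_gives_zero_map(self, grid16):
        lesion = _lesion_at(grid16, [(14, 14, 14)])
        controls = [Tractogram([_line((4, 10, 10), (12, 10, 10))], "c0")]
        d = disconnectome_for_subject(lesion, controls, step=1.0)
        assert not d.data.any()

    def test_empty_lesion_rejected(self, grid16):
        lesion = _lesion_at(grid16, [])
        with pytest.raises(ValueError, match="empty"):
            disconnectome_for_subject(
                lesion, [Tractogram([_line((0, 0, 0), (5, 5, 5))], "c0")]
            )

    def test_zero_controls_rejected(self, grid16):
        with pytest.raises(ValueError):
            disconnectome_for_subject(_lesion_at(grid16, [(1, 1, 1)]), [])


class TestOracleEquivalence:
    def test_random_phantom_matches_brute_force_exactly(self, grid16, rng):
        step = 1.0
        controls = [
            Tractogram(
                [np.cumsum(rng.uniform(-5, 5, size=(6, 3)), axis=0) + 15
                 for _ in range(8)],
                f"c{c}",
            )
            for c in range(5)
        ]
        for _ in range(5):
            center = rng.integers(3, 13, size=3)
            lesion = _lesion_at(
                grid16,
                [tuple(center + off) for off in
                 ((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1))],
            )
            d = disconnectome_for_subject(lesion, controls, step=step)
            oracle = brute_force_disconnectome(lesion, controls, grid16, step)
            assert np.array_equal(d.data, oracle)

    def test_values_are_exact_multiples_of_one_over_n(self, small_cohort):
        n = small_cohort.spec.n_controls
        for m in small_cohort.maps[:8]:
            assert np.array_equal(m.data * n, np.round(m.data * n))


class TestBatch:
    def test_batch_equals_independent_calls_bit_exact(self, grid16, rng):
        controls = [
            Tractogram(
                [np.cumsum(rng.uniform(-5, 5, size=(5, 3)), axis=0) + 15
                 for _ in range(6)],
                f"c{c}",
            )
            for c in range(3)
        ]
        lesions = [
            _lesion_at(grid16, [tuple(rng.integers(2, 14, size=3))], f"s{i}")
            for i in range(10)
        ]
        maps, errors = disconnectome_batch(lesions, controls, step=1.0)
        assert not errors
        for lesion, m in zip(lesions, maps):
            single = disconnectome_for_subject(lesion, controls, step=1.0)
            assert np.array_equal(m.data, single.data)

    def test_subject_order_is_preserved(self, grid16):
        controls = [Tractogram([_line((4, 10, 10), (12, 10, 10))], "c0")]
        lesions = [
            _lesion_at(grid16, [(5, 5, 5)], "first"),
            _lesion_at(grid16, [(14, 1, 1)], "second"),
        ]
        maps, _ = disconnectome_batch(lesions, controls, step=1.0)
        assert [m.subject_id for m in maps] == ["first", "second"]
        maps_rev, _ = disconnectome_batch(lesions[::-1], controls, step=1.0)
        assert [m.subject_id for m in maps_rev] == ["second", "first"]
        assert np.array_equal(maps[0].data, maps_rev[1].data)

    def test_failing_subject_recorded_batch_continues(self, grid16):
        controls = [Tractogram([_line((4, 10, 10), (12, 10, 10))], "c0")]
        good = _lesion_at(grid16, [(5, 5, 5)], "good")
        bad = _lesion_at(grid16, [], "bad")  # empty mask fails per-subject
        maps, errors = disconnectome_batch([good, bad], controls, step=1.0)
        assert maps[0] is not None and maps[1] is None
        assert list(errors) == ["bad"]


class TestMonotonicity:
    def test_nested_lesions_give_nested_maps(self, grid16, rng):
        controls = [
            Tractogram(
                [np.cumsum(rng.uniform(-5, 5, size=(5, 3)), axis=0) + 15
                 for _ in range(5)],
                f"c{c}",
            )
            for c in range(4)
        ]
        for _ in range(10):
            small = np.zeros(grid16.shape, dtype=np.uint8)
            c = rng.integers(4, 12, size=3)
            small[c[0], c[1], c[2]] = 1
            big = small.copy()
            big[c[0] - 2 : c[0] + 3, c[1] - 2 : c[1] + 3, c[2] - 2 : c[2] + 3] = 1
            d1 = disconnectome_for_subject(
                LesionMask(grid16.like(small), "s"), controls, step=1.0
            )
            d2 = disconnectome_for_subject(
                LesionMask(grid16.like(big), "s"), controls, step=1.0
            )
            assert np.all(d1.data <= d2.data)

    def test_removing_nonintersecting_controls_renormalizes(self, grid16):
        lesion = _lesion_at(grid16, [(5, 5, 5)])
        hit = Tractogram([_line((4, 10, 10), (12, 10, 10))], "c0")
        miss = Tractogram([_line((4, 26, 26), (12, 26, 26))], "c1")
        with_both = disconnectome_for_subject(lesion, [hit, miss], step=1.0)
        only_hit = disconnectome_for_subject(lesion, [hit], step=1.0)
        assert np.array_equal(with_both.data * 2, only_hit.data)


class TestThreshold:
    def test_tau_zero_selects_any_disconnection(self, grid16):
        lesion = _lesion_at(grid16, [(5, 5, 5)])
        hit = Tractogram([_line((4, 10, 10), (12, 10, 10))], "c0")
        miss = Tractogram([_line((4, 26, 26), (12, 26, 26))], "c1")
        d = disconnectome_for_subject(lesion, [hit, miss], step=1.0)
        t0 = threshold_map(d, 0.0)
        assert np.array_equal(t0.data > 0, d.data > 0)

    def test_tau_one_requires_all_controls(self, grid16):
        lesion = _lesion_at(grid16, [(5, 5, 5)])
        hit = Tractogram([_line((4, 10, 10), (12, 10, 10))], "c0")
        miss = Tractogram([_line((4, 26, 26), (12, 26, 26))], "c1")
        d = disconnectome_for_subject(lesion, [hit, miss], step=1.0)
        assert not threshold_map(d, 1.0).data.any()

    def test_boundary_is_inclusive(self, grid16):
        lesion = _lesion_at(grid16, [(5, 5, 5)])
        hit = Tractogram([_line((4, 10, 10), (12, 10, 10))], "c0")
        miss = Tractogram([_line((4, 26, 26), (12, 26, 26))], "c1")
        d = disconnectome_for_subject(lesion, [hit, miss], step=1.0)
        t = threshold_map(d, 0.5)
        assert t.data.any()  # voxels at exactly 0.5 are included
        assert np.array_equal(t.data > 0, d.data == 0.5)
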