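from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgan3d.cube_pipeline import (
    CubePair,
    extract_cubes,
    make_pairs,
    merge_cubes,
)
from emgan3d.density_io import DensityMap


def brute_offsets(n, cube, stride):
    """All covering offsets along one axis: 0, stride, ... >= n - cube."""
    offs = [0]
    while offs[-1] < n - cube:
        offs.append(offs[-1] + stride)
    return offs


def brute_extract(data, cube, stride):
    per_axis = [brute_offsets(n, cube, stride) for n in data.shape]
    padded_shape = [o[-1] + cube for o in per_axis]
    padded = np.zeros(padded_shape, dtype=data.dtype)
    padded[: data.shape[0], : data.shape[1], : data.shape[2]] = data
    out = {}
    for off in product(*per_axis):
        oz, oy, ox = off
        out[off] = padded[oz : oz + cube, oy : oy + cube, ox : ox + cube]
    return out


def brute_merge(offset_cubes, cube, padded_shape, original_shape):
    acc = np.zeros(padded_shape)
    cnt = np.zeros(padded_shape)
    for (oz, oy, ox), c in offset_cubes.items():
        acc[oz : oz + cube, oy : oy + cube, ox : ox + cube] += c
        cnt[oz : oz + cube, oy : oy + cube, ox : ox + cube] += 1
    out = acc / cnt
    return out[: original_shape[0], : original_shape[1], : original_shape[2]]


class TestExtract:
    def test_exact_fit_single_cube(self, rng):
        m = DensityMap(rng.random((25, 25, 25), dtype=np.float32))
        grid, cubes = extract_cubes(m)
        assert len(cubes) == 1
        assert grid.offsets == [(0, 0, 0)]
        np.testing.assert_array_equal(cubes[0], m.data)

    def test_33_cube_count(self, rng):
        m = DensityMap(rng.random((33, 33, 33), dtype=np.float32))
        grid, cubes = extract_cubes(m)
        assert len(cubes) == 27
        assert sorted({o[0] for o in grid.offsets}) == [0, 4, 8]

    def test_26_padding(self, rng):
        m = DensityMap(rng.random((26, 26, 26), dtype=np.float32))
        grid, cubes = extract_cubes(m)
        assert grid.padded_shape == (29, 29, 29)
        assert len(cubes) == 8
        # voxels beyond original index 25 are zero padding
        last = cubes[-1]  # offset (4,4,4)
        assert np.all(last[22:, :, :] == 0)

    def test_matches_brute_force(self, rng):
        data = rng.random((14, 9, 22), dtype=np.float32)
        m = DensityMap(data)
        grid, cubes = extract_cubes(m, cube_size=7, stride=3)
        oracle = brute_extract(data, 7, 3)
        assert set(grid.offsets) == set(oracle)
        for off, cube in zip(grid.offsets, cubes):
            np.testing.assert_array_equal(cube, oracle[off])

    def test_lexicographic_order(self, rng):
        m = DensityMap(rng.random((30, 30, 30), dtype=np.float32))
        grid, _ = extract_cubes(m)
        assert grid.offsets == sorted(grid.offsets)

    def test_every_voxel_covered(self, rng):
        m = DensityMap(rng.random((31, 27, 29), dtype=np.float32))
        grid, _ = extract_cubes(m, cube_size=25, stride=4)
        cover = np.zeros(grid.padded_shape, dtype=int)
        for oz, oy, ox in grid.offsets:
            cover[oz : oz + 25, oy : oy + 25, ox : ox + 25] += 1
        assert cover.min() >= 1

    def test_bad_stride(self, rng):
        m = DensityMap(rng.random((25, 25, 25), dtype=np.float32))
        with pytest.raises(ValueError):
            extract_cubes(m, stride=0)
        with pytest.raises(ValueError):
            extract_cubes(m, cube_size=4, stride=5)


class TestMakePairs:
    def test_pair_dropped_if_either_cube_all_zero(self):
        exp = np.zeros((25, 25, 25), dtype=np.float32)
        sim = np.full((25, 25, 25), 0.5, dtype=np.float32)
        pairs = make_pairs(DensityMap(exp), DensityMap(sim))
        assert pairs == []

    def test_all_positive_keeps_every_offset(self, rng):
        exp = DensityMap(rng.random((33, 33, 33), dtype=np.float32) + 0.1)
        sim = DensityMap(rng.random((33, 33, 33), dtype=np.float32) + 0.1)
        pairs = make_pairs(exp, sim)
        # padded border cubes contain zero voxels but are not all-zero
        assert len(pairs) == 27

    def test_sparse_maps_match_brute_filter(self, rng):
        shape = (30, 30, 30)
        exp_d = np.zeros(shape, dtype=np.float32)
        sim_d = np.zeros(shape, dtype=np.float32)
        exp_d[rng.random(shape) < 0.002] = 1.0
        sim_d[rng.random(shape) < 0.002] = 1.0
        exp, sim = DensityMap(exp_d), DensityMap(sim_d)
        pairs = make_pairs(exp, sim, cube_size=9, stride=6)
        kept = {p.offset for p in pairs}
        oracle_exp = brute_extract(exp_d, 9, 6)
        oracle_sim = brute_extract(sim_d, 9, 6)
        oracle_kept = {
            off
            for off in oracle_exp
            if oracle_exp[off].any() and oracle_sim[off].any()
        }
        assert kept == oracle_kept

    def test_shape_mismatch_raises(self, rng):
        a = DensityMap(rng.random((25, 25, 25), dtype=np.float32))
        b = DensityMap(rng.random((26, 25, 25), dtype=np.float32))
        with pytest.raises(ValueError, match="frame"):
            make_pairs(a, b)

    def test_cube_pair_shape_validation(self):
        with pytest.raises(ValueError):
            CubePair(np.zeros((3, 3, 3)), np.zeros((4, 4, 4)), (0, 0, 0))


class TestMerge:
    def test_round_trip_identity(self, rng):
        m = DensityMap(rng.random((31, 28, 26), dtype=np.float32))
        grid, cubes = extract_cubes(m)
        out = merge_cubes(grid, cubes)
        assert out.shape == m.shape
        np.testing.assert_allclose(out.data, m.data, atol=1e-9)

    def test_overlap_average_of_constants(self, rng):
        m = DensityMap(np.zeros((29, 25, 25), dtype=np.float32))
        grid, cubes = extract_cubes(m)  # offsets (0,0,0) and (4,0,0)
        assert len(cubes) == 2
        cubes = [np.zeros((25, 25, 25)), np.ones((25, 25, 25))]
        out = merge_cubes(grid, cubes)
        assert np.all(out.data[:4] == 0.0)  # only cube 0
        assert np.all(out.data[4:25] == 0.5)  # both cubes overlap
        assert np.all(out.data[25:29] == 1.0)  # only cube 1

    def test_random_cubes_match_brute_oracle(self, rng):
        m = DensityMap(rng.random((33, 33, 33), dtype=np.float32))
        grid, _ = extract_cubes(m)
        cubes = [rng.random((25, 25, 25)) for _ in grid.offsets]
        out = merge_cubes(grid, cubes)
        oracle = brute_merge(
            dict(zip(grid.offsets, cubes)), 25, grid.padded_shape, grid.original_shape
        )
        np.testing.assert_allclose(out.data, oracle, atol=1e-6)

    def test_cube_count_mismatch_raises(self, rng):
        m = DensityMap(rng.random((33, 33, 33), dtype=np.float32))
        grid, cubes = extract_cubes(m)
        with pytest.raises(ValueError, match="offsets"):
            merge_cubes(grid, cubes[:-1])

    @settings(max_examples=20, deadline=None)
    @given(
        nz=st.integers(25, 40), ny=st.integers(25, 40), nx=st.integers(25, 40),
        seed=st.integers(0, 2**31),
    )
    def test_round_trip_property(self, nz, ny, nx, seed):
        data = np.random.default_rng(seed).random((nz, ny, nx), dtype=np.float32)
        m = DensityMap(data)
        grid, cubes = extract_cubes(m)
        out = merge_cubes(grid, cubes)
        np.testing.assert_allclose(out.data, m.data, atol=1e-9)
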