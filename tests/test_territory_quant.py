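import numpy as np
import pytest

from oligofish.synthetic_data import SimNucleusParams, ellipsoid_mask, simulate_nucleus_image
from oligofish.territory_quant import (
    QuantParams,
    extract_objects,
    intermeans_threshold,
    measure_territories,
    territory_mask,
    threshold_stack,
)


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Independent oracle: BFS flood fill over explicit neighbor offsets."""
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [(dz, dy, dx)
                   for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                   if (dz, dy, dx) != (0, 0, 0)]
    todo = {tuple(p) for p in np.argwhere(mask)}
    components = []
    while todo:
        seed = todo.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            z, y, x = frontier.pop()
            for dz, dy, dx in offsets:
                nb = (z + dz, y + dy, x + dx)
                if nb in todo:
                    todo.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        components.append(comp)
    return components


def oracle_intermeans(values: np.ndarray) -> float:
    """Literal transcription of the iterative intermeans update loop."""
    v = np.asarray(values, dtype=np.float64).ravel()
    t = v.mean()
    while True:
        below, above = v[v <= t], v[v > t]
        new_t = (below.mean() + above.mean()) / 2.0
        if abs(new_t - t) < 0.5:
            return new_t
        t = new_t


class TestThreshold:
    def test_two_valued_stack_separates_exactly(self):
        rng = np.random.default_rng(30)
        stack = np.full((8, 16, 16), 10, dtype=np.uint16)
        signal = rng.random((8, 16, 16)) < 0.2
        stack[signal] = 200
        assert np.array_equal(threshold_stack(stack), signal)

    def test_idempotent_on_binary(self):
        rng = np.random.default_rng(31)
        mask = rng.random((6, 10, 10)) < 0.3
        assert np.array_equal(threshold_stack(mask.astype(np.uint8)), mask)

    def test_matches_literal_update_loop(self):
        rng = np.random.default_rng(32)
        for _ in range(50):
            lo = rng.integers(0, 50)
            hi = rng.integers(100, 250)
            stack = np.concatenate([
                rng.normal(lo, 8, size=500),
                rng.normal(hi, 15, size=rng.integers(50, 400)),
            ])
            stack = np.clip(np.rint(stack), 0, 255).astype(np.uint16)
            stack = stack.reshape(-1)
            ours = intermeans_threshold(stack)
            ref = oracle_intermeans(stack)
            assert ours == pytest.approx(ref, abs=1e-6)
            assert np.array_equal(stack > ours, stack > ref)

    def test_constant_image_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            intermeans_threshold(np.full((4, 4, 4), 7))

    def test_unknown_method_errors(self):
        with pytest.raises(ValueError):
            threshold_stack(np.zeros((2, 2, 2)), method="otsu")


class TestExtractObjects:
    def _cube(self, shape, corner, size):
        arr = np.zeros(shape, dtype=bool)
        z, y, x = corner
        arr[z : z + size, y : y + size, x : x + size] = True
        return arr

    def test_64_voxel_cube_kept(self):
        labels, sizes = extract_objects(self._cube((10, 10, 10), (2, 2, 2), 4))
        assert len(sizes) == 1
        assert list(sizes.values()) == [64]

    def test_27_voxel_cube_dropped(self):
        labels, sizes = extract_objects(self._cube((10, 10, 10), (2, 2, 2), 3))
        assert sizes == {}
        assert not labels.any()

    def test_strictly_greater_than_30(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, :, :] = True  # 25 voxels
        mask[1, 0, :] = True  # 30 voxels total, still dropped
        _, sizes = extract_objects(mask)
        assert sizes == {}
        mask[1, 1, 0] = True  # 31 > 30, kept
        _, sizes = extract_objects(mask)
        assert list(sizes.values()) == [31]

    def test_corner_touching_cubes_match_flood_fill(self):
        mask = self._cube((12, 12, 12), (1, 1, 1), 4) | \
            self._cube((12, 12, 12), (5, 5, 5), 4)
        for connectivity, expected in ((26, 1), (6, 2)):
            params = QuantParams(min_object_voxels=0, connectivity=connectivity)
            _, sizes = extract_objects(mask, params)
            oracle = flood_fill_components(mask, connectivity)
            assert len(sizes) == len(oracle) == expected
            assert sorted(sizes.values()) == sorted(len(c) for c in oracle)

    def test_random_blobs_match_flood_fill(self):
        rng = np.random.default_rng(33)
        for connectivity in (6, 26):
            mask = rng.random((8, 12, 12)) < 0.18
            params = QuantParams(min_object_voxels=0, connectivity=connectivity)
            _, sizes = extract_objects(mask, params)
            oracle = flood_fill_components(mask, connectivity)
            assert sorted(sizes.values()) == sorted(len(c) for c in oracle)


class TestMeasureTerritories:
    def _stack_pair(self, overlap: bool):
        shape = (24, 40, 40)
        m1 = ellipsoid_mask(shape, (12, 12, 12), (6, 7, 7))
        center2 = (12, 20, 24) if overlap else (12, 30, 30)
        m2 = ellipsoid_mask(shape, center2, (6, 7, 7))
        stacks = {}
        for name, m in (("a", m1), ("b", m2)):
            img = np.full(shape, 10, dtype=np.uint16)
            img[m] = 200
            stacks[name] = img
        return stacks, m1, m2

    def test_disjoint_overlap_zero(self):
        stacks, _, _ = self._stack_pair(overlap=False)
        stats = measure_territories(stacks)
        assert stats.overlap.loc["a", "b"] == 0
        assert stats.overlap_fraction.loc["a", "b"] == 0

    def test_identical_channels_full_overlap(self):
        stacks, m1, _ = self._stack_pair(overlap=False)
        stats = measure_territories({"a": stacks["a"], "b": stacks["a"].copy()})
        assert stats.overlap.loc["a", "b"] == stats.volumes["a"]
        assert stats.overlap_fraction.loc["a", "b"] == pytest.approx(1.0)

    def test_overlap_matrix_invariants(self):
        stacks, _, _ = self._stack_pair(overlap=True)
        stats = measure_territories(stacks)
        for i in stats.channels:
            assert stats.overlap.loc[i, i] == stats.volumes[i]
            for j in stats.channels:
                assert stats.overlap.loc[i, j] == stats.overlap.loc[j, i]
                assert stats.overlap.loc[i, j] <= min(stats.volumes[i], stats.volumes[j])

    def test_ellipsoid_volume_near_analytic(self):
        shape = (32, 40, 48)
        mask = ellipsoid_mask(shape, (16, 20, 24), (8, 10, 12))
        img = np.full(shape, 10, dtype=np.uint16)
        img[mask] = 200
        stats = measure_territories({"e": img})
        analytic = 4.0 / 3.0 * np.pi * 8 * 10 * 12  # ~4021
        assert stats.volumes["e"] == pytest.approx(analytic, rel=0.05)

    def test_union_bounded_by_sum(self):
        stacks, _, _ = self._stack_pair(overlap=True)
        stats = measure_territories(stacks)
        params = QuantParams()
        union = (territory_mask(stacks["a"], params)
                 | territory_mask(stacks["b"], params)).sum()
        assert union <= stats.volumes["a"] + stats.volumes["b"]
        assert union == (stats.volumes["a"] + stats.volumes["b"]
                         - stats.overlap.loc["a", "b"])

    def test_min_voxels_monotone(self):
        rng = np.random.default_rng(34)
        img = np.full((16, 24, 24), 10, dtype=np.uint16)
        img[rng.random(img.shape) < 0.1] = 200
        img[ellipsoid_mask(img.shape, (8, 12, 12), (4, 5, 5))] = 200
        volumes = []
        for mv in (0, 10, 30, 100):
            stats = measure_territories({"c": img}, QuantParams(min_object_voxels=mv))
            volumes.append(stats.volumes["c"])
        assert volumes == sorted(volumes, reverse=True)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError, match="dimensions differ"):
            measure_territories({"a": np.zeros((4, 4, 4)), "b": np.zeros((4, 4, 5))})

    def test_voxel_size_reporting(self):
        stacks, _, _ = self._stack_pair(overlap=False)
        stats = measure_territories(stacks, voxel_size=(0.2, 0.1, 0.1))
        for ch in stats.channels:
            assert stats.volumes_um3[ch] == pytest.approx(
                stats.volumes[ch] * 0.002)

    def test_csv_output(self, tmp_path):
        stacks, _, _ = self._stack_pair(overlap=True)
        stats = measure_territories(stacks)
        path = tmp_path / "out.csv"
        stats.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df["channel"]) == stats.channels
        assert df.loc[0, "volume_voxels"] == stats.volumes["a"]


class TestRecoveryFromSimulator:
    def test_volumes_within_10pct_overlaps_within_15pct(self):
        for seed in range(1, 11):
            params = SimNucleusParams(shape=(40, 72, 72), n_territories=2,
                                      placement="overlap", target_overlap=0.25,
                                      blur_sigma=0.8, seed=seed)
            stack, truth = simulate_nucleus_image(params)
            stats = measure_territories({f"ch{i}": stack[i] for i in range(2)})
            for ch, true_vol in truth.territory_volumes.items():
                assert stats.volumes[ch] == pytest.approx(true_vol, rel=0.10)
            true_ov = truth.territory_overlaps["ch0|ch1"]
            assert stats.overlap.loc["ch0", "ch1"] == pytest.approx(true_ov, rel=0.15)

    def test_inflated_radii_raise_measured_volume(self):
        # aging-style effect: +15% radii -> >= 40% measured volume increase
        young = SimNucleusParams(shape=(48, 80, 80), n_territories=3,
                                 blur_sigma=0.8, seed=3, radius_scale=1.0)
        aged = SimNucleusParams(shape=(48, 80, 80), n_territories=3,
                                blur_sigma=0.8, seed=3, radius_scale=1.15)
        vol = {}
        for label, p in (("young", young), ("aged", aged)):
            stack, _ = simulate_nucleus_image(p)
            stats = measure_territories({f"ch{i}": stack[i] for i in range(3)})
            vol[label] = sum(stats.volumes.values())
        assert vol["aged"] / vol["young"] >= 1.40
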