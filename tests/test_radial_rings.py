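import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autoquant.errors import ParameterError, ProfileError
from autoquant.radial_rings import (
    aggregate_profiles,
    compute_ring_partition,
    ring_intensity_profile,
    rolling_ball_subtract,
)
from autoquant.scene_sim import SceneParams, generate_lysosome_scene
from autoquant.segmentation import CellGeometry

from conftest import star_geometry


def opening_by_ball_oracle(image: np.ndarray, radius: int) -> np.ndarray:
    """Exhaustive grayscale opening by a ball structuring function."""
    r = int(radius)
    offsets = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= r * r
    ]
    H, W = image.shape
    padded = np.pad(image, r, constant_values=np.inf)
    eroded = np.full(image.shape, np.inf)
    for dy, dx in offsets:
        g = np.sqrt(r * r - dy * dy - dx * dx)
        eroded = np.minimum(eroded, padded[r + dy : r + dy + H, r + dx : r + dx + W] - g)
    padded = np.pad(eroded, r, constant_values=-np.inf)
    opened = np.full(image.shape, -np.inf)
    for dy, dx in offsets:
        g = np.sqrt(r * r - dy * dy - dx * dx)
        opened = np.maximum(opened, padded[r + dy : r + dy + H, r + dx : r + dx + W] + g)
    return opened


class TestRollingBall:
    def test_constant_image_goes_to_zero(self):
        out = rolling_ball_subtract(np.full((64, 64), 17.3), radius=30)
        assert np.allclose(out, 0.0)

    def test_spike_retained_background_removed(self):
        img = np.full((80, 80), 10.0)
        img[40:43, 40:43] += 100.0
        out = rolling_ball_subtract(img, radius=30)
        assert out[41, 41] == pytest.approx(100.0, abs=1.0)
        far = out.copy()
        far[30:53, 30:53] = 0.0
        assert np.allclose(far, 0.0, atol=1e-9)

    def test_matches_exhaustive_opening_oracle(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 40, (48, 48))
        for radius in (5, 9):
            background = img - rolling_ball_subtract(img, radius=radius)
            oracle_bg = opening_by_ball_oracle(img, radius)
            # subtraction clips at 0; compare where unclipped
            expect = np.clip(img - oracle_bg, 0, None)
            assert np.allclose(rolling_ball_subtract(img, radius=radius), expect)
            assert np.allclose(background[expect > 0], oracle_bg[expect > 0])

    def test_default_radius_is_30(self):
        import inspect

        sig = inspect.signature(rolling_ball_subtract)
        assert sig.parameters["radius"].default == 30

    def test_radius_too_large_errors(self):
        with pytest.raises(ParameterError):
            rolling_ball_subtract(np.zeros((20, 20)), radius=20)


class TestRingPartition:
    def test_centered_disk_boundary_radii(self, disk_geometry):
        partition = compute_ring_partition(disk_geometry)
        assert partition.n_rings == 4
        # boundary scale s implies radius 100*s; expect 100*sqrt(k/4)
        expected = [100 * np.sqrt(3 / 4), 100 * np.sqrt(2 / 4), 100 * np.sqrt(1 / 4)]
        for s, exp in zip(partition.scales, expected):
            assert 100 * s == pytest.approx(exp, abs=1.0)
        target = disk_geometry.cell_area / 4
        assert np.all(np.abs(partition.areas - target) / target <= 0.02)

    def test_default_is_four_rings(self, disk_geometry):
        partition = compute_ring_partition(disk_geometry)
        assert set(np.unique(partition.labels)) == {0, 1, 2, 3, 4}

    def test_offset_ellipse_equal_areas(self):
        rr, cc = np.mgrid[0:300, 0:300]
        cell = ((rr - 150) / 80) ** 2 + ((cc - 150) / 120) ** 2 <= 1.0
        nucleus = (rr - 150) ** 2 + (cc - 160) ** 2 <= 25**2
        geom = CellGeometry(cell, nucleus, (150.0, 160.0))
        partition = compute_ring_partition(geom)
        # oracle: pixel-count every labeled region
        areas = np.array([(partition.labels == k).sum() for k in range(1, 5)])
        target = cell.sum() / 4
        assert np.all(np.abs(areas - target) / target <= 0.02)

    def test_partition_covers_cell_exactly(self, disk_geometry):
        partition = compute_ring_partition(disk_geometry)
        assert ((partition.labels > 0) == disk_geometry.cell_mask).all()

    def test_too_few_rings_rejected(self, disk_geometry):
        with pytest.raises(ParameterError):
            compute_ring_partition(disk_geometry, n_rings=1)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_equal_area_property_on_star_masks(self, seed):
        geom = star_geometry(seed)
        partition = compute_ring_partition(geom)
        target = geom.cell_area / 4
        assert np.abs(partition.areas - target).max() / target <= 0.02
        partition.validate(geom.cell_mask)


class TestRingIntensityProfile:
    def test_uniform_image_flat_profile(self, disk_geometry):
        partition = compute_ring_partition(disk_geometry)
        img = disk_geometry.cell_mask * 5.0
        profile = ring_intensity_profile(img, partition)
        assert np.all(np.abs(profile.norm_density - 1.0) <= 3 * 0.02)
        assert np.all(np.abs(profile.fraction - 0.25) <= 3 * 0.02)

    def test_all_intensity_innermost(self, disk_geometry):
        partition = compute_ring_partition(disk_geometry)
        img = np.zeros(partition.labels.shape)
        img[partition.labels == 4] = 2.0
        profile = ring_intensity_profile(img, partition)
        assert profile.fraction == pytest.approx([0, 0, 0, 1], abs=1e-12)
        # n_4 = d_4 / d_cell = (I/A_4) / (I/A) = A / A_4 ~= 4
        assert profile.norm_density[3] == pytest.approx(4.0, rel=3 * 0.02)
        assert profile.norm_density[:3] == pytest.approx([0, 0, 0], abs=1e-12)

    def test_invariant_sums(self, disk_geometry):
        rng = np.random.default_rng(0)
        partition = compute_ring_partition(disk_geometry)
        img = rng.uniform(0, 9, partition.labels.shape)
        profile = ring_intensity_profile(img, partition)
        assert profile.fraction.sum() == pytest.approx(1.0, abs=1e-9)
        w = profile.area / profile.area.sum()
        assert (w * profile.norm_density).sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_equivariance(self, disk_geometry):
        partition = compute_ring_partition(disk_geometry)
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 9, partition.labels.shape)
        p1 = ring_intensity_profile(img, partition)
        p2 = ring_intensity_profile(img * 37.5, partition)
        assert np.allclose(p1.norm_density, p2.norm_density)
        assert np.allclose(p1.fraction, p2.fraction)

    def test_zero_intensity_errors(self, disk_geometry):
        partition = compute_ring_partition(disk_geometry)
        with pytest.raises(ProfileError):
            ring_intensity_profile(np.zeros(partition.labels.shape), partition)

    def test_scene_fraction_recovery(self):
        params = SceneParams(
            seed=21, n_puncta=400, ring_weights=(0.1, 0.2, 0.3, 0.4),
            background_level=0.0,
        )
        stack, gt = generate_lysosome_scene(params)
        partition = compute_ring_partition(gt.geometry)
        profile = ring_intensity_profile(stack.data[1, 0], partition)
        assert np.all(np.abs(profile.fraction - gt.ring_fractions) < 0.05)


class TestAggregateProfiles:
    @staticmethod
    def _profiles(values, condition="c"):
        from autoquant.radial_rings import RadialProfile

        out = []
        for i, v in enumerate(values):
            n = np.asarray(v, dtype=float)
            a = np.full(4, 100.0)
            out.append(
                RadialProfile(
                    intensity=n * 100,
                    area=a,
                    density=n,
                    cell_density=1.0,
                    norm_density=n,
                    fraction=n / n.sum(),
                    cell_id=f"cell{i}",
                    condition=condition,
                )
            )
        return out

    def test_identical_profiles_zero_sem(self):
        profiles = self._profiles([[1, 2, 3, 4], [1, 2, 3, 4]])
        table = aggregate_profiles(profiles)
        nd = table[table["metric"] == "norm_density"]
        assert np.allclose(nd["sem"], 0.0)
        assert np.allclose(nd.sort_values("ring")["mean"], [1, 2, 3, 4])

    def test_two_profile_closed_form(self):
        profiles = self._profiles([[1.0, 1, 1, 1], [2.0, 2, 2, 2]])
        table = aggregate_profiles(profiles)
        ring1 = table[(table["metric"] == "norm_density") & (table["ring"] == 1)]
        assert ring1["mean"].iloc[0] == pytest.approx(1.5)
        assert ring1["sem"].iloc[0] == pytest.approx(0.5)

    def test_perinuclear_vs_uniform_ordering(self):
        # 30 simulated cells per condition; generator ground truth orders means
        profiles = []
        for cond, weights in (
            ("perinuclear", (0.05, 0.15, 0.3, 0.5)),
            ("uniform", (0.25, 0.25, 0.25, 0.25)),
        ):
            for seed in range(30):
                params = SceneParams(
                    seed=seed, shape=(160, 160), cell_radius=60.0, n_puncta=120,
                    ring_weights=weights, background_level=0.0,
                )
                stack, gt = generate_lysosome_scene(params)
                partition = compute_ring_partition(gt.geometry)
                profiles.append(
                    ring_intensity_profile(
                        stack.data[1, 0], partition, cell_id=f"{cond}{seed}",
                        condition=cond,
                    )
                )
        table = aggregate_profiles(profiles)
        inner = table[(table["metric"] == "fraction") & (table["ring"] == 4)]
        peri = inner[inner["condition"] == "perinuclear"]["mean"].iloc[0]
        unif = inner[inner["condition"] == "uniform"]["mean"].iloc[0]
        assert peri > unif

    def test_low_n_warning(self, caplog):
        profiles = self._profiles([[1, 2, 3, 4]] * 3)
        with caplog.at_level("WARNING"):
            aggregate_profiles(profiles)
        assert any("cells" in r.message for r in caplog.records)

    def test_empty_input_errors(self):
        with pytest.raises(ParameterError):
            aggregate_profiles([])
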