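import numpy as np
import pytest
from skimage.measure import label

from sparus.acquisition import PlaneWaveSequence, ValidationError, make_linear_array, simulate_rf
from sparus.beamform import ImageGrid, beamform_bmode
from sparus.metrics import ssim
from sparus.phantoms import (
    ToothScene,
    dataset_phantom,
    make_paired_dataset,
    make_tooth_scene,
    measure_thickness,
    negative_control_phantom,
    points_in_polygon,
    tooth_phantom,
    train_val_split,
    wire_phantom,
)


class TestWirePhantom:
    def test_single_scatterer_at_10mm(self):
        ph = wire_phantom(10e-3)
        assert ph.n_scatterers == 1
        assert ph.scatterer_positions[0] == pytest.approx([0.0, 0.01])
        assert ph.reflectivities[0] == 1.0

    def test_deterministic(self):
        a, b = wire_phantom(10e-3), wire_phantom(10e-3)
        assert np.array_equal(a.scatterer_positions, b.scatterer_positions)

    def test_dense_bmode_single_connected_component(self, dense_array, clean_sequence):
        # oracle: connected-component count after -6 dB thresholding
        grid = ImageGrid(
            n_rows=64, n_cols=64,
            lateral_min=-1.5e-3, lateral_max=1.5e-3,
            depth_min=9e-3, depth_max=11e-3,
        )
        rf = simulate_rf(
            wire_phantom(10e-3), dense_array, clean_sequence,
            cover_depth=grid.depth_max, cover_lateral=1.5e-3,
        )
        img = beamform_bmode(rf, grid, dense_array, clean_sequence.sound_speed)
        half_max = img.pixels.max() * 10 ** (-6 / 20)
        mask = img.pixels >= half_max
        assert label(mask).max() == 1


class TestToothScene:
    def test_constructed_thickness_recovered_exactly(self):
        scene = make_tooth_scene(1.41)  # Table-1-scale representative input
        assert measure_thickness(scene, 2.0) == pytest.approx(1.41, abs=0.005)

    def test_gingiva_shallower_than_tooth(self):
        scene = make_tooth_scene(1.5)
        # compare at matched arc positions (offset construction)
        assert np.all(
            scene.gingiva_surface_curve[1:, 1] < scene.tooth_surface_curve[1:, 1]
        )
        assert scene.gingiva_surface_curve[0] == pytest.approx(
            scene.tooth_surface_curve[0]
        )

    def test_thickness_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            make_tooth_scene(0.2)
        with pytest.raises(ValidationError):
            make_tooth_scene(3.5)


class TestMeasureThickness:
    def test_parallel_flat_curves(self):
        tooth = np.column_stack([np.linspace(0, 5e-3, 50), np.full(50, 5e-3)])
        ging = tooth + np.array([0.0, -1.2e-3])
        scene = ToothScene(tooth, ging, (0.0, 5e-3))
        assert measure_thickness(scene, 2.0) == pytest.approx(1.2)
        assert measure_thickness(scene, 3.0) == pytest.approx(1.2)

    def test_recovery_over_random_scenes(self):
        rng = np.random.default_rng(42)
        errs = []
        for i in range(20):
            t = float(rng.uniform(0.6, 2.8))
            scene = make_tooth_scene(
                t,
                margin=(float(rng.uniform(-2.5e-3, -0.5e-3)), float(rng.uniform(2e-3, 3.2e-3))),
                tangent_angle_deg=float(rng.uniform(40, 70)),
                curvature=float(rng.uniform(10, 80)),
                seed=i,
            )
            errs.append(abs(measure_thickness(scene, 2.0) - t))
        assert np.mean(errs) < 0.02

    def test_rotation_invariance(self):
        scene = make_tooth_scene(1.37)
        before = measure_thickness(scene, 2.0)
        after = measure_thickness(scene.rotated(np.deg2rad(10.0)), 2.0)
        assert abs(after - before) <= 0.02

    def test_normal_missing_gingiva_rejected(self):
        # gingiva polyline too short: normal at 2 mm has nothing to hit
        tooth = np.column_stack([np.linspace(0, 5e-3, 50), np.full(50, 5e-3)])
        ging = tooth[:5] + np.array([0.0, -1e-3])
        scene = ToothScene(tooth, ging, (0.0, 5e-3))
        with pytest.raises(ValidationError, match="intersect"):
            measure_thickness(scene, 2.0)

    def test_beyond_surface_extent_rejected(self):
        scene = make_tooth_scene(1.5, curve_length=3e-3)
        with pytest.raises(ValidationError):
            measure_thickness(scene, 50.0)


class TestToothPhantom:
    def test_deterministic_under_seed(self):
        a = tooth_phantom(1.41, seed=5)
        b = tooth_phantom(1.41, seed=5)
        assert np.array_equal(a.scatterer_positions, b.scatterer_positions)
        assert np.array_equal(a.reflectivities, b.reflectivities)

    def test_speckle_count_poisson_consistent(self):
        # oracle: Poisson 3-sigma interval around density x area
        scene = make_tooth_scene(1.5, scatterer_density=40.0, seed=1)
        ph = tooth_phantom(1.5, scene=scene)
        poly = np.vstack([scene.tooth_surface_curve, scene.gingiva_surface_curve[::-1]])
        area_mm2 = 0.5 * abs(
            np.sum(
                poly[:, 0] * np.roll(poly[:, 1], -1)
                - np.roll(poly[:, 0], -1) * poly[:, 1]
            )
        ) / 1e-6
        lam = 40.0 * area_mm2
        assert abs(ph.metadata["n_speckle"] - lam) <= 3 * np.sqrt(lam)

    def test_gingiva_mask_emitted_with_grid(self):
        grid = ImageGrid(n_rows=64, n_cols=64, depth_max=9.5e-3)
        ph = tooth_phantom(1.41, grid=grid, seed=3)
        assert "gingiva" in ph.region_masks
        mask = ph.region_masks["gingiva"]
        assert mask.shape == (64, 64)
        assert 0 < mask.sum() < mask.size

    def test_speckle_lies_inside_gingiva_polygon(self):
        scene = make_tooth_scene(1.5, seed=2)
        ph = tooth_phantom(1.5, scene=scene)
        n_interface = ph.n_scatterers - ph.metadata["n_speckle"]
        speckle = ph.scatterer_positions[n_interface:]
        poly = np.vstack([scene.tooth_surface_curve, scene.gingiva_surface_curve[::-1]])
        assert points_in_polygon(speckle, poly).all()


class TestNegativeControls:
    def test_reproducible_noise_cloud(self):
        a = negative_control_phantom("noise", seed=9)
        b = negative_control_phantom("noise", seed=9)
        assert np.array_equal(a.scatterer_positions, b.scatterer_positions)
        assert np.array_equal(a.reflectivities, b.reflectivities)

    def test_no_gingiva_mask(self):
        for kind in ("vessel", "muscle", "noise"):
            ph = negative_control_phantom(kind, seed=0)
            assert "gingiva" not in ph.region_masks

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            negative_control_phantom("bone", seed=0)

    def test_vessel_scatterers_excluded_from_ellipse(self):
        ph = negative_control_phantom("vessel", seed=1)
        e = ph.metadata["ellipse"]
        pos = ph.scatterer_positions
        inside = ((pos[:, 0] - e["cx"]) / e["a"]) ** 2 + (
            (pos[:, 1] - e["cz"]) / e["b"]
        ) ** 2 < 1.0
        assert not inside.any()

    def test_vessel_lumen_darker_than_speckle(self, clean_sequence):
        # oracle: region statistics on the beamformed envelope
        arr = make_linear_array()
        ph = negative_control_phantom("vessel", seed=1)
        grid = ImageGrid(
            n_rows=64, n_cols=64,
            lateral_min=-3e-3, lateral_max=3e-3,
            depth_min=2e-3, depth_max=9e-3,
        )
        rf = simulate_rf(ph, arr, clean_sequence, cover_depth=9e-3, cover_lateral=3e-3)
        from sparus.beamform import beamform_all_angles, compound

        env = np.abs(compound(beamform_all_angles(rf, grid, arr, clean_sequence.sound_speed)))
        e = ph.metadata["ellipse"]
        xx, zz = np.meshgrid(grid.x, grid.z)
        lumen = ((xx - e["cx"]) / (0.6 * e["a"])) ** 2 + (
            (zz - e["cz"]) / (0.6 * e["b"])
        ) ** 2 < 1.0
        ring = (
            ((xx - e["cx"]) / (1.5 * e["a"])) ** 2 + ((zz - e["cz"]) / (1.5 * e["b"])) ** 2
            > 1.0
        )
        assert env[lumen].mean() < 0.25 * env[ring].mean()


class TestPairedDataset:
    def test_triplet_counts(self, tiny_dataset):
        assert tiny_dataset.n_pairs == 8
        assert set(tiny_dataset.sparse_images) == {2, 8}
        assert len(tiny_dataset.sparse_images[2]) == 8

    def test_factor1_member_equals_dense(self):
        data = make_paired_dataset(1, [1], seed=3, image_size=32)
        assert np.array_equal(
            data.sparse_images[1][0].pixels, data.dense_images[0].pixels
        )

    def test_sparse_member_degraded(self, tiny_dataset):
        for i in range(tiny_dataset.n_pairs):
            de = tiny_dataset.dense_images[i].pixels
            sp = tiny_dataset.sparse_images[8][i].pixels
            assert ssim(de, sp) < 1.0

    def test_eighty_twenty_split_counts(self):
        split = train_val_split(400, seed=0)
        assert len(split["train"]) == 320
        assert len(split["val"]) == 80
        assert sorted(split["train"] + split["val"]) == list(range(400))

    def test_split_counts_small(self, tiny_dataset):
        assert len(tiny_dataset.split["train"]) == 6
        assert len(tiny_dataset.split["val"]) == 2

    def test_deterministic_generation(self):
        d1 = make_paired_dataset(2, [8], seed=21, image_size=32)
        d2 = make_paired_dataset(2, [8], seed=21, image_size=32)
        for i in range(2):
            assert np.array_equal(d1.dense_images[i].pixels, d2.dense_images[i].pixels)
            assert np.array_equal(
                d1.sparse_images[8][i].pixels, d2.sparse_images[8][i].pixels
            )

    def test_dataset_phantom_stream_prefix_stable(self):
        a = dataset_phantom(5, 3)
        b = dataset_phantom(5, 3)
        assert np.array_equal(a.scatterer_positions, b.scatterer_positions)

    def test_invalid_n_pairs(self):
        with pytest.raises(ValidationError):
            make_paired_dataset(0, [8], seed=0)
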