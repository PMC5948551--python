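"""Parametric blade model, analytic ground truth and the virtual scan."""

import math

import numpy as np
import pytest

import lidarleaf as ll
from lidarleaf.virtual_scanner import (
    RoomBox,
    Scene,
    box_mesh,
    frustum_mesh,
    leaf_surface_point,
    scan_scene,
    true_leaf_angular_density,
)


def make_leaf(**kw):
    defaults = dict(attachment_height=300.0, azimuth=0.0, inclination=45.0,
                    blade_length=600.0, max_width=80.0)
    defaults.update(kw)
    return ll.LeafSpec(**defaults)


class TestBladeGeometry:
    def test_base_is_attachment_point(self):
        leaf = make_leaf(attachment_radius=12.0, azimuth=90.0)
        pt = leaf_surface_point(leaf, 0.0, 0.0)
        assert pt == pytest.approx([0.0, 12.0, 300.0], abs=1e-9)

    def test_horizontal_blade_tip(self):
        leaf = make_leaf(inclination=0.0)
        assert leaf_surface_point(leaf, 1.0, 0.0) == pytest.approx(
            [600.0, 0.0, 300.0], abs=1e-9)

    def test_vertical_blade_tip(self):
        leaf = make_leaf(inclination=90.0)
        assert leaf_surface_point(leaf, 1.0, 0.0) == pytest.approx(
            [0.0, 0.0, 900.0], abs=1e-9)

    def test_parameter_bounds(self):
        with pytest.raises(ll.ValidationError):
            leaf_surface_point(make_leaf(), 1.5, 0.0)
        with pytest.raises(ll.ValidationError):
            make_leaf(inclination=95.0)


class TestTrueLeafArea:
    def test_rectangular_closed_form(self):
        leaf = make_leaf(width_profile="rectangular", droop_coefficient=0.5)
        assert ll.true_leaf_area(leaf) == pytest.approx(600 * 80, rel=1e-6)

    def test_sine_arch_closed_form(self):
        leaf = make_leaf()
        assert ll.true_leaf_area(leaf) == pytest.approx(
            600 * 80 * 2 / math.pi, rel=1e-3)

    def test_grid_convergence(self):
        leaf = make_leaf(droop_coefficient=0.5)
        coarse = ll.true_leaf_area(leaf, n_s=600, n_t=50)
        fine = ll.true_leaf_area(leaf, n_s=1200, n_t=100)
        assert abs(fine - coarse) / fine < 1e-3

    def test_monte_carlo_oracle(self):
        """Independent check: Monte-Carlo surface integration with a
        finite-difference Jacobian of the parametric map."""
        leaf = make_leaf(droop_coefficient=0.5)
        rng = np.random.default_rng(0)
        n = 200_000
        s = rng.uniform(1e-4, 1 - 1e-4, n)
        t = rng.uniform(-0.5 + 1e-4, 0.5 - 1e-4, n)
        eps = 1e-5
        p0 = leaf_surface_point(leaf, s, t)
        ds = (leaf_surface_point(leaf, s + eps, t) - p0) / eps
        dt = (leaf_surface_point(leaf, s, t + eps) - p0) / eps
        jac = np.linalg.norm(np.cross(ds, dt), axis=1)
        mc_area = jac.mean()
        assert ll.true_leaf_area(leaf) == pytest.approx(mc_area, rel=0.01)


class TestGroundTruth:
    def test_flat_blade_mass_in_single_bin(self):
        mass = true_leaf_angular_density(make_leaf(inclination=75.0))
        assert mass.argmax() == 7
        assert mass[7] == pytest.approx(mass.sum())

    def test_invariants(self):
        rng = np.random.default_rng(3)
        truth = ll.compute_ground_truth(ll.random_plant("maize-like", rng))
        assert truth.total_area == pytest.approx(truth.per_leaf_area.sum())
        assert truth.angular_distribution.sum() == pytest.approx(1.0,
                                                                 abs=1e-9)
        assert np.all(truth.angular_distribution >= 0)

    def test_tilted_planar_plant_mass_in_tilt_bin(self):
        leaf = make_leaf(inclination=42.0)
        plant = ll.PlantSpec(leaves=(leaf,), stem_height=400.0)
        truth = ll.compute_ground_truth(plant)
        assert truth.angular_distribution[4] == pytest.approx(1.0)


class TestScan:
    CFG = ll.ScanConfig(lidar_distance_D=1000.0, lidar_height_h=400.0,
                        start_angle=-0.3, stop_angle=0.3)

    def test_vertical_rod_geometry(self):
        """Every return from a thin centered rod satisfies
        R cos(theta) ~= D (within the rod radius)."""
        v, f = frustum_mesh(0.5, 0.5, 0.0, 800.0, n_seg=16, n_z=4)
        scene = Scene(v, f, np.zeros(len(f), dtype=int))
        scan, _ = scan_scene(scene, self.CFG, noise_sigma=0.0, seed=1,
                             n_sweeps=100)
        assert len(scan) > 0
        radial = scan.range_R * np.cos(scan.beam_angle_theta)
        assert np.abs(radial - 1000.0).max() < 0.5 + 1e-6
        cloud = ll.convert_scan(scan, self.CFG)
        assert np.hypot(cloud.points[:, 0], cloud.points[:, 1]).max() < 0.51

    def test_horizontal_disk_reconstructs_at_height(self):
        ang = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        rim = np.column_stack([400 * np.cos(ang), 400 * np.sin(ang),
                               np.full(48, 600.0)])
        verts = np.vstack([rim, [0.0, 0.0, 600.0]])
        faces = np.array([[i, (i + 1) % 48, 48] for i in range(48)])
        scene = Scene(verts, faces, np.zeros(len(faces), dtype=int))
        scan, _ = scan_scene(scene, self.CFG, noise_sigma=0.0, seed=1,
                             n_sweeps=100)
        cloud = ll.convert_scan(scan, self.CFG)
        assert len(cloud) > 100
        assert np.abs(cloud.points[:, 2] - 600.0).max() < 1e-6

    def test_empty_scene_returns_hit_background_box(self):
        box = RoomBox(half_width=1800.0, z_min=-100.0, z_max=2000.0)
        v, f = box_mesh(box)
        scene = Scene(v, f, np.full(len(f), -2, dtype=int))
        scan, ids = scan_scene(scene, self.CFG, noise_sigma=0.0, seed=1,
                               n_sweeps=60)
        cloud = ll.convert_scan(scan, self.CFG)
        assert np.all(ids == -2)
        on_wall = (np.isclose(np.abs(cloud.points[:, :2]), 1800.0,
                              atol=1e-6).any(axis=1)
                   | np.isclose(cloud.points[:, 2], -100.0, atol=1e-6)
                   | np.isclose(cloud.points[:, 2], 2000.0, atol=1e-6))
        assert on_wall.all()

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        plant = ll.random_plant("maize-like", rng)
        a = ll.simulate_scan(plant, self.CFG, noise_sigma=2.0, seed=11)
        b = ll.simulate_scan(plant, self.CFG, noise_sigma=2.0, seed=11)
        assert len(a) == len(b)
        assert np.array_equal(a.range_R, b.range_R)
        assert np.array_equal(a.sweep_index, b.sweep_index)

    def test_point_count_bounded_by_ray_count(self):
        rng = np.random.default_rng(6)
        plant = ll.random_plant("sorghum-like", rng)
        n_sweeps = 50
        scan, _ = scan_scene(ll.build_scene(plant, ll.RoomBox()), self.CFG,
                             noise_sigma=0.0, seed=0, n_sweeps=n_sweeps)
        assert len(scan) <= n_sweeps * self.CFG.beam_angles().size

    def test_negative_noise_rejected(self):
        with pytest.raises(ll.ValidationError):
            scan_scene(Scene(np.empty((0, 3)),
                             np.empty((0, 3), dtype=int),
                             np.empty(0, dtype=int)),
                       self.CFG, noise_sigma=-1.0, seed=0)


class TestValidationSet:
    def test_reproducible(self):
        a = ll.make_validation_set(1, "maize-like", seed=9,
                                   rotation_speed=60.0, background=None)
        b = ll.make_validation_set(1, "maize-like", seed=9,
                                   rotation_speed=60.0, background=None)
        assert a[0].plant == b[0].plant
        assert np.array_equal(a[0].records.range_R, b[0].records.range_R)

    def test_maize_like_is_planar(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            plant = ll.random_plant("maize-like", rng)
            az = np.array([leaf.azimuth for leaf in plant.leaves])
            rel = np.mod(az - az[0], 360.0)
            assert np.all(np.isclose(rel, 0.0) | np.isclose(rel, 180.0))

    def test_leaf_counts_in_stage_range(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = len(ll.random_plant("maize-like", rng).leaves)
            assert 6 <= n <= 11

    def test_plant_invariants_enforced(self):
        leaf = make_leaf(attachment_height=900.0)
        with pytest.raises(ll.ValidationError):
            ll.PlantSpec(leaves=(leaf,), stem_height=500.0)
        with pytest.raises(ll.ValidationError):
            ll.PlantSpec(leaves=(), stem_radius_base=5.0,
                         stem_radius_top=9.0)
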