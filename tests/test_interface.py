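"""File formats, configuration, pipeline driver and CLI."""

import json
import math

import numpy as np
import pytest
from click.testing import CliRunner

import lidarleaf as ll
from lidarleaf import io as lio
from lidarleaf.cli import main as cli_main
from lidarleaf.reconstruction import mesh_from_arrays


@pytest.fixture()
def tiny_scan():
    """Coarse noiseless scan of a one-leaf plant (fast: 24 deg/s stage)."""
    leaf = ll.LeafSpec(attachment_height=300.0, azimuth=45.0,
                       inclination=40.0, blade_length=350.0,
                       max_width=60.0, attachment_radius=10.0)
    plant = ll.PlantSpec(leaves=(leaf,), stem_height=400.0,
                         stem_radius_base=6.0, stem_radius_top=6.0,
                         pot_radius=60.0, pot_height=100.0)
    cfg = ll.ScanConfig(lidar_distance_D=1200.0, lidar_height_h=400.0,
                        start_angle=-0.45, stop_angle=0.45,
                        rotation_speed=24.0)
    scan = ll.simulate_scan(plant, cfg, noise_sigma=0.0, seed=3)
    return plant, cfg, scan


class TestRawScanFormat:
    def test_round_trip(self, tmp_path):
        scan = ll.PolarScan([100.0, 250.5], [0.1, -0.2], [0.0, 1.5],
                            [0, 7], [3, 4])
        path = tmp_path / "scan.txt"
        lio.write_raw_scan(path, scan)
        back = lio.read_raw_scan(path)
        np.testing.assert_allclose(back.range_R, scan.range_R, atol=1e-6)
        np.testing.assert_allclose(back.stage_angle_phi,
                                   scan.stage_angle_phi, atol=1e-9)
        assert back.sweep_index.tolist() == [0, 7]

    def test_phi_derived_from_config(self, tmp_path):
        path = tmp_path / "scan.txt"
        path.write_text(lio.RAW_HEADER + "\n25 0 800.0 0.1\n")
        cfg = ll.ScanConfig()
        scan = lio.read_raw_scan(path, cfg)
        assert scan.stage_angle_phi[0] == pytest.approx(math.radians(3.0))

    def test_corrupted_header_names_line_one(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("not-a-header\n0 0 1.0 0.0\n")
        with pytest.raises(lio.ParseError, match=r":1:"):
            lio.read_raw_scan(path)

    def test_bad_record_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(lio.RAW_HEADER + "\n0 0 1.0 0.0\n0 0 oops 0.0\n")
        with pytest.raises(lio.ParseError, match=r":3:"):
            lio.read_raw_scan(path)


class TestPointCloudFormats:
    @pytest.mark.parametrize("suffix", [".csv", ".xyz", ".ply"])
    def test_round_trip(self, tmp_path, suffix):
        rng = np.random.default_rng(0)
        cloud = ll.PointCloud(rng.uniform(-500, 500, (40, 3)))
        path = tmp_path / f"cloud{suffix}"
        lio.write_point_cloud(path, cloud)
        back = lio.read_point_cloud(path)
        np.testing.assert_allclose(back.points, cloud.points, atol=1e-5)

    def test_csv_labels_round_trip(self, tmp_path):
        cloud = ll.PointCloud(np.zeros((3, 3)), labels=[1, 2, 2])
        path = tmp_path / "cloud.csv"
        lio.write_point_cloud(path, cloud)
        assert lio.read_point_cloud(path).labels.tolist() == [1, 2, 2]

    def test_empty_ply(self, tmp_path):
        path = tmp_path / "empty.ply"
        lio.write_point_cloud(path, ll.PointCloud.empty())
        assert len(lio.read_point_cloud(path)) == 0


class TestMeshFormats:
    @pytest.mark.parametrize("suffix", [".ply", ".obj"])
    def test_round_trip_area_and_counts(self, tmp_path, suffix):
        mesh = mesh_from_arrays(
            np.array([[0, 0, 0], [10, 0, 0], [10, 10, 3], [0, 10, 3]],
                     dtype=float),
            np.array([[0, 1, 2], [0, 2, 3]]))
        path = tmp_path / f"leaf{suffix}"
        lio.write_mesh(path, mesh)
        back = lio.read_mesh(path)
        assert back.triangles.shape == mesh.triangles.shape
        assert back.area == pytest.approx(mesh.area, rel=1e-6)


class TestConfig:
    def test_degree_suffix(self, tmp_path):
        path = tmp_path / "scan.toml"
        path.write_text("lidar_distance_D = 1000.0\n"
                        "start_angle_deg = -20\nstop_angle_deg = 30\n")
        cfg = lio.read_scan_config(path)
        assert cfg.start_angle == pytest.approx(math.radians(-20))
        assert cfg.stop_angle == pytest.approx(math.radians(30))

    def test_unknown_scan_key_rejected(self):
        with pytest.raises(ll.ValidationError):
            lio.scan_config_from_dict({"laser_power": 5})

    def test_unknown_pipeline_key_rejected(self):
        with pytest.raises(ll.ValidationError, match="unknown config"):
            ll.PipelineConfig.from_dict({"voxel_sizes": 10})

    def test_pipeline_ranges_enforced(self):
        with pytest.raises(ll.ValidationError):
            ll.PipelineConfig(voxel_size=-1.0)
        with pytest.raises(ll.ValidationError):
            ll.PipelineConfig(bandwidth_fraction=1.5)


class TestRunPipeline:
    def config_for(self, plant, cfg, out=None):
        return ll.PipelineConfig(scan=cfg, k=1, stem_radius=12.0,
                                 pot_top_z=plant.pot_height + 5.0,
                                 seed=4, output_dir=out)

    def test_one_leaf_plant_traits(self, tiny_scan, tmp_path):
        plant, cfg, scan = tiny_scan
        traits, meshes, manifest = ll.run_pipeline(
            scan, self.config_for(plant, cfg, str(tmp_path / "run")))
        assert len(meshes) == 1
        truth = ll.compute_ground_truth(plant)
        assert traits.total_area == pytest.approx(truth.total_area,
                                                  rel=0.08)
        assert (tmp_path / "run" / "traits.json").exists()
        assert (tmp_path / "run" / "manifest.json").exists()
        assert (tmp_path / "run" / "leaf_01.ply").exists()
        assert manifest.stage_counts["input"] == len(scan)

    def test_deterministic_trait_json(self, tiny_scan, tmp_path):
        plant, cfg, scan = tiny_scan
        docs = []
        for name in ("a", "b"):
            out = tmp_path / name
            ll.run_pipeline(scan, self.config_for(plant, cfg, str(out)))
            docs.append((out / "traits.json").read_bytes())
        assert docs[0] == docs[1]

    def test_raw_file_input_and_digest(self, tiny_scan, tmp_path):
        plant, cfg, scan = tiny_scan
        raw = tmp_path / "raw.txt"
        lio.write_raw_scan(raw, scan)
        traits, _, manifest = ll.run_pipeline(
            raw, self.config_for(plant, cfg))
        assert manifest.input_digest is not None
        assert traits.total_area > 0

    def test_failing_stage_is_named(self):
        # three lonely points cannot be split into five leaves
        cloud = ll.PointCloud(np.array([[200.0, 0, 400], [210.0, 0, 400],
                                        [205.0, 5, 401]]))
        cfg = ll.PipelineConfig(k=5, min_points=1)
        with pytest.raises(ll.PipelineError) as err:
            ll.run_pipeline(cloud, cfg)
        assert err.value.stage == "segmentation"


class TestCLI:
    def test_simulate_convert_run(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim"
        res = runner.invoke(cli_main, [
            "simulate", "--archetype", "maize", "--n-plants", "1",
            "--seed", "5", "--rotation-speed", "24", "--out", str(out)])
        assert res.exit_code == 0, res.output
        raw = out / "plant_00_raw.txt"
        truth_doc = json.loads((out / "plant_00_truth.json").read_text())
        assert raw.exists() and truth_doc["total_area_mm2"] > 0

        scan_doc = json.loads((out / "plant_00_scan.json").read_text())
        toml = tmp_path / "cfg.toml"
        toml.write_text("".join(
            f"{key} = {scan_doc[key]}\n"
            for key in ("lidar_distance_D", "lidar_height_h",
                        "scan_frequency", "beam_angular_interval",
                        "start_angle", "stop_angle", "rotation_speed"))
            + f"k = {scan_doc['n_leaves']}\n"
            + f"pot_top_z = {scan_doc['pot_top_z']}\n"
            + "stem_radius = 20.0\n")
        res = runner.invoke(cli_main, [
            "run", str(raw), "--config", str(toml),
            "--out", str(tmp_path / "run")])
        assert res.exit_code == 0, res.output
        doc = json.loads((tmp_path / "run" / "traits.json").read_text())
        est = doc["total_area_mm2"]
        assert est == pytest.approx(truth_doc["total_area_mm2"], rel=0.15)

    def test_validate_command(self, tmp_path):
        csv = tmp_path / "pairs.csv"
        csv.write_text("estimate,reference\n419.8,463\n506.2,463\n")
        runner = CliRunner()
        res = runner.invoke(cli_main, ["validate", str(csv)])
        assert res.exit_code == 0, res.output
        doc = json.loads(res.output)
        assert doc["mae_percent_of_mean"] == pytest.approx(9.33, abs=0.01)
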