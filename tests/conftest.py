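import numpy as np
import pytest

import lidarleaf as ll


def pipeline_config_for(sample, seed: int = 7) -> ll.PipelineConfig:
    """Standard processing configuration for a synthetic validation sample:
    stem filter sized for the synthetic stems (6-16 mm radius), pot cutoff
    just above the pot rim, k = true leaf count."""
    return ll.PipelineConfig(scan=sample.config,
                             k=len(sample.plant.leaves),
                             stem_radius=20.0,
                             pot_top_z=sample.plant.pot_height + 5.0,
                             seed=seed)


@pytest.fixture(scope="session")
def maize_run():
    """Ten maize-like plants scanned at the instrument's routine sampling
    geometry (0.0029 rad beams, 3 deg/s at 25 Hz, sigma = 2 mm) and pushed
    through the full pipeline.  Shared across the validation tests because
    the simulation plus processing takes a few minutes."""
    samples = ll.make_validation_set(10, "maize-like", seed=1)
    results = []
    for sample in samples:
        traits, meshes, manifest = ll.run_pipeline(
            sample.records, pipeline_config_for(sample))
        results.append(traits)
    return samples, results


@pytest.fixture(scope="session")
def single_flat_leaf_scan():
    """Noiseless full-rotation scan of one flat inclined blade on a thin
    stem; used by reconstruction-accuracy tests."""
    def build(width_profile: str):
        leaf = ll.LeafSpec(attachment_height=350.0, azimuth=30.0,
                           inclination=35.0, blade_length=500.0,
                           max_width=80.0, droop_coefficient=0.0,
                           width_profile=width_profile,
                           attachment_radius=15.0)
        plant = ll.PlantSpec(leaves=(leaf,), stem_height=400.0,
                             stem_radius_base=5.0, stem_radius_top=5.0,
                             pot_radius=60.0, pot_height=100.0)
        cfg = ll.ScanConfig(lidar_distance_D=1200.0, lidar_height_h=500.0,
                            start_angle=-0.5, stop_angle=0.6)
        scan, ids = ll.simulate_scan_labeled(plant, cfg, noise_sigma=0.0,
                                             seed=2)
        cloud = ll.convert_scan(scan, cfg)
        return cloud.points[ids == 1]
    return {p: build(p) for p in ("rectangular", "sine-arch")}
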