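"""Synthetic data generator: species mix, latent-health structure, gas
coupling, renderer behaviour, determinism, and the modality-split property."""

import hashlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from treefuse.synthetic import (
    GeneratorConfig,
    classify_latent,
    generate_dataset,
    load_dataset,
    oracle_image_estimate,
    oracle_sensor_estimate,
    render_tree,
    sample_population,
    _tree_render_seed,
)


@pytest.fixture(scope="module")
def population():
    return sample_population(GeneratorConfig(n_trees=1000, seed=5))


def test_species_proportions_match_study_mix(population):
    counts = population["species"].value_counts()
    # dominant species at 27/18/14/12 % of n=1000, multinomial tolerance 4 sd
    for name, expected in [("Platanus orientalis", 270), ("Acer negundo", 180),
                           ("Fraxinus pennsylvanica", 140), ("Morus alba", 120)]:
        sd = np.sqrt(expected * (1 - expected / 1000))
        assert abs(counts[name] - expected) < 4 * sd
    rare = counts.drop(["Platanus orientalis", "Acer negundo",
                        "Fraxinus pennsylvanica", "Morus alba"])
    assert len(rare) == 8
    assert (rare / 1000 < 0.08).all()


def test_labels_consistent_with_latent_threshold(population):
    cfg = GeneratorConfig(n_trees=1000, seed=5)
    np.testing.assert_array_equal(
        population["health_class"], classify_latent(population["u"], cfg))
    # modality decomposition reconstructs the latent exactly
    u = (cfg.visual_fraction * population["a"]
         + (1 - cfg.visual_fraction) * population["b"])
    np.testing.assert_allclose(u, population["u"], atol=1e-12)
    assert population["a"].between(0, 1).all()
    assert population["b"].between(0, 1).all()


def test_population_deterministic_for_seed():
    cfg = GeneratorConfig(n_trees=50, seed=13)
    pd.testing.assert_frame_equal(sample_population(cfg), sample_population(cfg))


def test_noise_free_limit_biometrics_are_exact_link_functions():
    from treefuse.synthetic import SPECIES_SIZE
    cfg = GeneratorConfig(n_trees=200, seed=2, sensor_noise_scale=0.0,
                          gas_sigma=0.0, gas_ratio_jitter=0.0)
    pop = sample_population(cfg)
    k = np.asarray(SPECIES_SIZE)[pop["species_idx"]]
    b = pop["b"].to_numpy()
    np.testing.assert_allclose(pop["height_m"], 3.0 + 7.0 * k + 2.0 * b, atol=1e-12)
    np.testing.assert_allclose(pop["crown_density"],
                               np.clip(0.25 + 0.6 * b, 0.05, 0.98), atol=1e-12)
    np.testing.assert_allclose(pop["Soil_Moisture_%"], 12.0 + 28.0 * b, atol=1e-12)


def test_gas_rule_noise_free_limits():
    cfg = GeneratorConfig(n_trees=300, seed=8, gas_sigma=0.0,
                          gas_ratio_jitter=0.0)
    pop = sample_population(cfg)
    # exact stoichiometric ratio 1.375 = 44/32
    np.testing.assert_allclose(pop["CO2_rate"] / pop["O2_rate"], 1.375,
                               rtol=1e-12)
    # square law: the deterministic part scales with canopy width squared
    expected = (cfg.gas_coefficient * pop["canopy_width_true"] ** 2
                * pop["crown_density_true"] * (0.5 + 0.5 * pop["u"]))
    np.testing.assert_allclose(pop["O2_rate"], expected, rtol=1e-12)
    # crown density 0 implies zero noise-free O2
    assert cfg.gas_coefficient * 4.0 * 0.0 * 0.75 == 0.0


def test_gas_coupling_correlation(population):
    r = np.corrcoef(population["O2_rate"], population["CO2_rate"])[0, 1]
    assert r >= 0.95


def test_renderer_deterministic_and_fill_monotone():
    cfg = GeneratorConfig(n_trees=4, seed=1)
    pop = sample_population(cfg)
    img1 = render_tree(pop.iloc[0], 96, seed=42)
    img2 = render_tree(pop.iloc[0], 96, seed=42)
    assert np.array_equal(img1, img2)
    # crown density drives the canopy fill fraction
    sparse = pop.iloc[0].copy()
    dense = pop.iloc[0].copy()
    sparse["crown_density_true"] = 0.2
    dense["crown_density_true"] = 0.9
    f_sparse = (render_tree(sparse, 96, seed=9).max(axis=2) > 12).mean()
    f_dense = (render_tree(dense, 96, seed=9).max(axis=2) > 12).mean()
    assert f_dense > f_sparse


def test_renderer_healthy_hue_at_green_reference():
    cfg = GeneratorConfig(n_trees=4, seed=1, render_jitter=0.0)
    pop = sample_population(cfg)
    tree = pop.iloc[0].copy()
    tree["leaf_color_dev_true"] = 0.0  # fully healthy visual state
    img = render_tree(tree, 96, seed=3, render_jitter=0.0)
    canopy = (img.max(axis=2) > 12) & (np.arange(96)[:, None] < 40)
    mean = img[canopy].mean(axis=0)
    from treefuse.synthetic import GREEN
    np.testing.assert_allclose(mean, GREEN, atol=2.0)


def test_generate_dataset_layout_and_checksums(tmp_path):
    cfg = GeneratorConfig(n_trees=12, seed=3)
    out1 = generate_dataset(cfg, tmp_path / "d1")
    out2 = generate_dataset(cfg, tmp_path / "d2")
    for name in ("sensors.csv", "truth.csv", "manifest.csv", "generator.json"):
        assert (out1 / name).exists()
        h1 = hashlib.sha256((out1 / name).read_bytes()).hexdigest()
        h2 = hashlib.sha256((out2 / name).read_bytes()).hexdigest()
        assert h1 == h2, name
    imgs1 = sorted((out1 / "images").glob("*.png"))
    assert len(imgs1) == 12
    for p in imgs1:
        q = out2 / "images" / p.name
        assert hashlib.sha256(p.read_bytes()).hexdigest() == \
            hashlib.sha256(q.read_bytes()).hexdigest()
    sensors, truth, images = load_dataset(out1)
    assert len(sensors) == len(truth) == len(images) == 12
    assert list(sensors["tree_id"]) == list(truth["tree_id"])
    with pytest.raises(FileExistsError):
        generate_dataset(cfg, tmp_path / "d1")
    generate_dataset(cfg, tmp_path / "d1", overwrite=True)


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(species_proportions=(0.5, 0.5))
    with pytest.raises(ValueError):
        GeneratorConfig(resolution=128)
    with pytest.raises(ValueError):
        GeneratorConfig(gas_sigma=-1.0)
    with pytest.raises(ValueError):
        sample_population(GeneratorConfig(n_trees=2))


def test_modality_split_fusion_beats_single_modalities():
    """Oracles that invert the generative rule: using both modalities
    recovers the health class strictly better than either alone, and the
    fused oracle clears the 0.95 recovery ceiling."""
    cfg = GeneratorConfig(n_trees=600, seed=17)
    pop = sample_population(cfg)
    labels = pop["health_class"].to_numpy()
    images = np.stack([
        render_tree(pop.iloc[i], cfg.resolution, _tree_render_seed(cfg.seed, i))
        for i in range(len(pop))
    ])
    u_sensor = oracle_sensor_estimate(pop, cfg)
    u_image = oracle_image_estimate(images, cfg)
    # fused: visual component read from pixels, sensor component from table
    w = cfg.visual_fraction
    a_from_image = (u_image - (1 - w) * np.clip(
        (np.minimum(pop["crown_density"], 1) * 0 + u_image * 0), 0, 1))
    # recombine at the component level
    from treefuse.synthetic import GREEN, BROWN, _canopy_pixels
    axis = GREEN - BROWN
    denom = float(axis @ axis)
    a_img = np.array([
        float(np.clip((img[_canopy_pixels(img)[0]].mean(axis=0) - BROWN)
                      @ axis / denom, 0, 1))
        for img in images
    ])
    a_sens = np.clip(1 - pop["leaf_color_deviation"].to_numpy() / 5.0, 0, 1)
    b_sens = (u_sensor - w * a_sens) / (1 - w)
    u_both = w * a_img + (1 - w) * b_sens
    acc = {
        "sensor": (classify_latent(u_sensor, cfg) == labels).mean(),
        "image": (classify_latent(u_image, cfg) == labels).mean(),
        "both": (classify_latent(u_both, cfg) == labels).mean(),
    }
    assert acc["both"] > acc["sensor"]
    assert acc["both"] > acc["image"]
    assert acc["both"] >= 0.95
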