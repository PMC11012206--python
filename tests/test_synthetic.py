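import numpy as np
import pytest
from dataclasses import replace

from spectrafuse.synthetic import (
    PeakSpec,
    SyntheticConfig,
    generate_block,
    generate_paired,
    informative_windows,
    split_signal_config,
    zero_effect_config,
)


def test_default_study_design_counts():
    cfg = SyntheticConfig()
    assert cfg.class_sizes == (45, 46, 48, 44, 42)
    assert cfg.n_samples == 225
    uv = generate_block(cfg, "uv")
    mir = generate_block(cfg, "mir")
    assert uv.values.shape == (225, 511) and uv.units == "nm"
    assert mir.values.shape == (225, 361) and mir.units == "cm-1"
    sizes = [int(np.sum(uv.labels == c)) for c in uv.class_order]
    assert sizes == [45, 46, 48, 44, 42]


def test_paired_blocks_share_ids_labels_order(tiny_config):
    uv, mir = generate_paired(tiny_config)
    np.testing.assert_array_equal(uv.sample_ids, mir.sample_ids)
    np.testing.assert_array_equal(uv.labels, mir.labels)
    assert uv.class_order == mir.class_order


def test_determinism_and_seed_sensitivity(tiny_config):
    a = generate_block(tiny_config, "uv")
    b = generate_block(tiny_config, "uv")
    c = generate_block(replace(tiny_config, seed=tiny_config.seed + 1), "uv")
    np.testing.assert_array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_block_noise_streams_independent(tiny_config):
    """UV and MIR noise must differ even on identical grids."""
    cfg = replace(tiny_config, mir_axis=tiny_config.uv_axis)
    uv, mir = generate_paired(cfg)
    assert not np.array_equal(uv.values, mir.values)


def test_noise_free_effect_free_spectra_identical(tiny_config):
    cfg = replace(
        zero_effect_config(seed=tiny_config.seed),
        class_sizes=tiny_config.class_sizes,
        uv_axis=tiny_config.uv_axis,
        mir_axis=tiny_config.mir_axis,
        scatter_sigma=0.0, offset_sigma=0.0, slope_sigma=0.0,
        amp_jitter_sigma=0.0, noise_sigma=0.0,
    )
    uv = generate_block(cfg, "uv")
    np.testing.assert_allclose(
        uv.values, np.tile(uv.values[0], (uv.n_samples, 1)), atol=1e-12
    )


def test_noise_free_class_differences_match_closed_form(tiny_config):
    """With all sigmas zero, between-class differences equal the
    offset-weighted Gaussian peak shapes exactly."""
    cfg = replace(
        tiny_config,
        scatter_sigma=0.0, offset_sigma=0.0, slope_sigma=0.0,
        amp_jitter_sigma=0.0, noise_sigma=0.0,
    )
    uv = generate_block(cfg, "uv")
    rows = {c: uv.values[uv.labels == c][0] for c in uv.class_order}
    expected = {}
    for ci, cls in enumerate(cfg.class_names):
        total = np.zeros_like(uv.axis)
        for pk in cfg.uv_peaks:
            total += (pk.base_amplitude + pk.class_offsets[ci]) * np.exp(
                -((uv.axis - pk.center) ** 2) / (2 * pk.width**2)
            )
        expected[cls] = total
    base_cls = cfg.class_names[0]
    for cls in cfg.class_names[1:]:
        np.testing.assert_allclose(
            rows[cls] - rows[base_cls],
            expected[cls] - expected[base_cls],
            atol=1e-12,
        )


def test_split_signal_informative_windows_declared():
    wins = informative_windows(split_signal_config())
    assert len(wins["uv"]) >= 1 and len(wins["mir"]) >= 1
    # informative signal must be split: neither block holds all of it
    total = len(wins["uv"]) + len(wins["mir"])
    assert len(wins["uv"]) < total and len(wins["mir"]) < total


def test_zero_effect_preset_has_no_informative_peak():
    cfg = zero_effect_config()
    assert all(not p.informative for p in cfg.uv_peaks + cfg.mir_peaks)
    wins = informative_windows(cfg)
    assert wins == {"uv": [], "mir": []}


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        PeakSpec(250.0, -1.0, 1.0, (0.0,) * 5)
    with pytest.raises(ValueError):
        PeakSpec(250.0, 10.0, 0.1, (-0.5, 0.0, 0.0, 0.0, 0.0))
    with pytest.raises(ValueError):
        SyntheticConfig(class_sizes=(10, 10))  # length != n_classes
    with pytest.raises(ValueError):
        replace(SyntheticConfig(), uv_peaks=(PeakSpec(250.0, 10.0, 1.0, (0.0,) * 3),))
    with pytest.raises(ValueError):
        generate_block(replace(SyntheticConfig(), uv_axis=(190.0, 190.0, 1.0)), "uv")


def test_noise_monotonicity_for_fixed_classifier(tiny_config):
    """More measurement noise must not help a fixed classifier, on average
    over seeds."""
    from spectrafuse.classify import ClassifierSpec
    from spectrafuse.ga import FeatureMask, GAConfig, fitness

    cfg_ga = GAConfig(
        parsimony_lambda=0.0, cv_folds=3,
        base_classifier=ClassifierSpec("rf", {"n_estimators": 30}, seed=0),
        seed=0,
    )
    accs = {0.01: [], 1.0: []}
    for seed in range(10):
        for noise in accs:
            cfg = replace(tiny_config, seed=seed, noise_sigma=noise)
            uv = generate_block(cfg, "uv")
            mask = FeatureMask(np.ones(uv.n_variables, dtype=bool))
            accs[noise].append(fitness(mask, uv, cfg_ga))
    assert np.mean(accs[1.0]) <= np.mean(accs[0.01]) + 0.05
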