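"""SNV / MSC / SG unit and property tests.

Expected numbers were computed independently: SNV values by direct
evaluation of (x - mean)/sd with sample sd; the MSC example by hand OLS
(reference [0,1,2], x=[1,3,6] -> b=2.5, a=0.8333); the SG window-3/order-1
example via the 3-point moving mean with mirror padding.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spectrafuse.preprocess import PreprocessSpec, Preprocessor, msc, sg_smooth, snv

spectra = st.lists(
    st.floats(-50, 50), min_size=4, max_size=20
).filter(lambda xs: np.std(xs) > 1e-3)


def test_snv_frozen_values():
    np.testing.assert_allclose(snv(np.array([[1.0, 2.0, 3.0]])), [[-1, 0, 1]])
    out = snv(np.array([[1.0, 2.0, 4.0]]))
    np.testing.assert_allclose(out, [[-0.8729, -0.2182, 1.0911]], atol=5e-5)


def test_snv_zero_variance_names_sample(toy_dataset):
    flat = toy_dataset.with_values(np.ones_like(toy_dataset.values))
    with pytest.raises(ValueError, match="'a'"):
        snv(flat)


@settings(max_examples=30, derandomize=True)
@given(x=spectra, a=st.floats(-10, 10), b=st.floats(0.1, 10))
def test_snv_affine_invariance(x, a, b):
    x = np.array([x])
    np.testing.assert_allclose(snv(a + b * x), snv(x), atol=1e-8)


@settings(max_examples=30, derandomize=True)
@given(x=spectra)
def test_snv_row_mean_zero_sd_one(x):
    out = snv(np.array([x]))
    assert abs(out.mean()) < 1e-9
    assert abs(out.std(ddof=1) - 1) < 1e-9


def test_msc_identity_and_affine_exactness():
    ref = np.array([0.5, 1.0, 2.0, 1.5, 0.7])
    np.testing.assert_allclose(msc(ref[None, :], ref), ref[None, :], atol=1e-12)
    distorted = 2.0 + 3.0 * ref
    np.testing.assert_allclose(msc(distorted[None, :], ref), ref[None, :], atol=1e-9)


def test_msc_frozen_ols_example():
    out = msc(np.array([[1.0, 3.0, 6.0]]), np.array([0.0, 1.0, 2.0]))
    np.testing.assert_allclose(out, [[0.0667, 0.8667, 2.0667]], atol=5e-5)


@settings(max_examples=30, derandomize=True)
@given(a=st.floats(-5, 5), b=st.floats(0.1, 5))
def test_msc_recovers_any_affine_distortion(a, b):
    rng = np.random.default_rng(0)
    ref = rng.normal(1, 0.3, 12)
    np.testing.assert_allclose(
        msc((a + b * ref)[None, :], ref), ref[None, :], atol=1e-9
    )


def test_msc_zero_slope_error():
    ref = np.array([0.0, 1.0, 2.0, 3.0])
    flat = np.array([[1.0, 1.0, 1.0, 1.0]])
    with pytest.raises(ValueError, match="row 0"):
        msc(flat, ref)


def test_sg_moving_average_equivalence():
    out = sg_smooth(np.array([[1.0, 10.0, 1.0, 10.0, 1.0]]), 3, 1)
    np.testing.assert_allclose(out, [[7, 4, 7, 4, 7]])


def test_sg_interpolating_fit_is_identity():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, (3, 15))
    np.testing.assert_allclose(sg_smooth(x, 5, 4), x, atol=1e-9)


def test_sg_preserves_polynomials_at_interior():
    t = np.arange(20.0)
    x = (t**2)[None, :]
    out = sg_smooth(x, 5, 2)
    np.testing.assert_allclose(out[:, 2:-2], x[:, 2:-2], atol=1e-8)


def test_sg_linearity():
    rng = np.random.default_rng(2)
    x, y = rng.normal(0, 1, (2, 30))
    lhs = sg_smooth((2.0 * x + 3.0 * y)[None, :], 7, 2)
    rhs = 2.0 * sg_smooth(x[None, :], 7, 2) + 3.0 * sg_smooth(y[None, :], 7, 2)
    np.testing.assert_allclose(lhs, rhs, atol=1e-9)


@pytest.mark.parametrize(
    "window,polyorder", [(4, 2), (2, 1), (5, 5), (5, 7), (31, 2)]
)
def test_sg_invalid_parameters(window, polyorder):
    with pytest.raises(ValueError):
        sg_smooth(np.ones((1, 20)), window, polyorder)


def test_preprocess_spec_validation():
    with pytest.raises(ValueError):
        PreprocessSpec(method="wavelet")
    with pytest.raises(ValueError):
        PreprocessSpec(method="sg", sg_window=4)
    assert PreprocessSpec(method="snv").label == "SNV"


def test_msc_preprocessor_reference_frozen_from_training(toy_dataset):
    prep = Preprocessor(PreprocessSpec(method="msc"))
    prep.fit(toy_dataset)
    ref = prep.reference_.copy()
    np.testing.assert_allclose(ref, toy_dataset.values.mean(axis=0))
    # transforming other data must not update the reference
    other = toy_dataset.with_values(toy_dataset.values * 3.0 + 1.0)
    prep.transform(other)
    np.testing.assert_allclose(prep.reference_, ref)


def test_snv_and_msc_beat_raw_when_scatter_dominates():
    """When multiplicative scatter dwarfs noise, scatter-correcting
    preprocessing must not hurt CV accuracy relative to raw spectra
    (averaged over generator seeds)."""
    from dataclasses import replace

    from spectrafuse.classify import ClassifierSpec
    from spectrafuse.ga import FeatureMask, GAConfig, fitness
    from spectrafuse.synthetic import generate_block, split_signal_config

    import numpy as np

    accs = {"raw": [], "snv": [], "msc": []}
    for seed in range(10):
        cfg = replace(
            split_signal_config(seed=seed),
            class_sizes=(12, 12, 12, 12, 12),
            uv_axis=(190.0, 700.0, 5.0),
            scatter_sigma=0.8, offset_sigma=0.5, noise_sigma=0.005,
        )
        uv = generate_block(cfg, "uv")
        ga_cfg = GAConfig(
            parsimony_lambda=0.0, cv_folds=3,
            base_classifier=ClassifierSpec("rf", {"n_estimators": 30}, seed=0),
            seed=seed,
        )
        mask = FeatureMask(np.ones(uv.n_variables, dtype=bool))
        accs["raw"].append(fitness(mask, uv, ga_cfg))
        accs["snv"].append(fitness(mask, snv(uv), ga_cfg))
        accs["msc"].append(fitness(mask, msc(uv), ga_cfg))
    assert np.mean(accs["snv"]) >= np.mean(accs["raw"])
    assert np.mean(accs["msc"]) >= np.mean(accs["raw"])
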