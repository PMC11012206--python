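"""GA wavelength-selection tests.

The exhaustive-search oracle for small deterministic fitness functions
lives here as ``exhaustive_optimum``: it enumerates all 2^p - 1 non-empty
masks and returns the best under the GA's own tie-break rule, providing an
independent optimum the GA must match.
"""

import itertools

import numpy as np
import pytest

from spectrafuse.classify import ClassifierSpec
from spectrafuse.datasets import SpectralDataset
from spectrafuse.ga import FeatureMask, GAConfig, _repair, fitness, ga_select
from tests.conftest import make_separable_dataset


def exhaustive_optimum(p, fitness_fn):
    """Brute-force best (fitness, bits) over all non-empty masks."""
    best = None
    for combo in itertools.product([False, True], repeat=p):
        bits = np.array(combo)
        if not bits.any():
            continue
        f = fitness_fn(FeatureMask(bits))
        key = (-f, bits.sum(), tuple(np.flatnonzero(bits)))
        if best is None or key < best[0]:
            best = (key, f, bits)
    return best[1], best[2]


def quadratic_fitness(weights, interaction):
    """Deterministic toy fitness with pairwise interactions."""
    def fn(mask: FeatureMask) -> float:
        sel = np.flatnonzero(mask.bits)
        val = weights[sel].sum()
        for i, j in itertools.combinations(sel, 2):
            val += interaction[i, j]
        return float(val)

    return fn


class _Dummy:
    """Stand-in 'training data' carrying only the variable count."""

    def __init__(self, p):
        self.n_variables = p


def test_feature_mask_invariants():
    with pytest.raises(ValueError):
        FeatureMask(np.zeros(5, dtype=bool))
    m = FeatureMask(np.array([True, False, True]))
    assert m.selected_count == 2 and len(m) == 3


def test_ga_config_validation():
    with pytest.raises(ValueError):
        GAConfig(population_size=1)
    with pytest.raises(ValueError):
        GAConfig(elitism_count=10, population_size=10)
    with pytest.raises(ValueError):
        GAConfig(cv_folds=1)


def test_fitness_separable_toy_is_one():
    ds = make_separable_dataset(n_per_class=15, seed=0)
    bits = np.zeros(ds.n_variables, dtype=bool)
    bits[0] = True
    cfg = GAConfig(
        parsimony_lambda=0.0, cv_folds=3,
        base_classifier=ClassifierSpec("rf", {"n_estimators": 30}, seed=0),
        seed=0,
    )
    assert fitness(FeatureMask(bits), ds, cfg) == 1.0


def test_fitness_pure_noise_near_chance():
    """Balanced 2-class labels with pure-noise features: CV accuracy should
    sit near 0.5."""
    rng = np.random.default_rng(8)
    n = 60
    ds = SpectralDataset(
        values=rng.normal(0, 1, (n, 10)),
        axis=np.arange(10.0),
        units="nm",
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        labels=np.array(["A", "B"] * (n // 2), dtype=object),
    )
    cfg = GAConfig(
        parsimony_lambda=0.0, cv_folds=5,
        base_classifier=ClassifierSpec("rf", {"n_estimators": 50}, seed=0),
        seed=0,
    )
    vals = []
    for seed in range(5):
        vals.append(fitness(FeatureMask(np.ones(10, bool)), ds, GAConfig(
            parsimony_lambda=0.0, cv_folds=5,
            base_classifier=ClassifierSpec("rf", {"n_estimators": 50}, seed=seed),
            seed=seed,
        )))
    assert abs(np.mean(vals) - 0.5) < 0.15


def test_fitness_class_smaller_than_folds_rejected():
    ds = make_separable_dataset(n_per_class=3, seed=0)
    cfg = GAConfig(cv_folds=5, seed=0)
    with pytest.raises(ValueError, match="cv_folds"):
        fitness(FeatureMask(np.ones(ds.n_variables, bool)), ds, cfg)


def test_repair_sets_exactly_one_bit():
    rng = np.random.default_rng(0)
    repaired = _repair(np.zeros(12, dtype=bool), rng)
    assert repaired.sum() == 1


def test_ga_matches_exhaustive_optimum_single_instance():
    p = 8
    rng = np.random.default_rng(42)
    fn = quadratic_fitness(
        rng.normal(0, 1, p), np.triu(rng.normal(0, 0.5, (p, p)), 1)
    )
    best_f, _ = exhaustive_optimum(p, fn)
    cfg = GAConfig(population_size=30, generations=60, seed=3, patience=60)
    mask, history = ga_select(_Dummy(p), cfg, fitness_fn=fn)
    assert fn(mask) == pytest.approx(best_f, abs=1e-12)
    assert history.best_fitness_per_generation[-1] == pytest.approx(best_f)


def test_ga_reproducible_from_seed():
    p = 10
    rng = np.random.default_rng(1)
    fn = quadratic_fitness(
        rng.normal(0, 1, p), np.triu(rng.normal(0, 0.3, (p, p)), 1)
    )
    cfg = GAConfig(population_size=20, generations=25, seed=9, patience=25)
    m1, h1 = ga_select(_Dummy(p), cfg, fitness_fn=fn)
    m2, h2 = ga_select(_Dummy(p), cfg, fitness_fn=fn)
    np.testing.assert_array_equal(m1.bits, m2.bits)
    assert h1.best_fitness_per_generation == h2.best_fitness_per_generation
    np.testing.assert_array_equal(h1.selection_frequency, h2.selection_frequency)


def test_elitism_makes_best_fitness_non_decreasing():
    p = 12
    rng = np.random.default_rng(2)
    fn = quadratic_fitness(
        rng.normal(0, 1, p), np.triu(rng.normal(0, 0.4, (p, p)), 1)
    )
    cfg = GAConfig(
        population_size=16, generations=30, elitism_count=1, seed=4, patience=30
    )
    _, history = ga_select(_Dummy(p), cfg, fitness_fn=fn)
    best = history.best_fitness_per_generation
    assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))


def test_parsimony_breaks_ties_toward_smaller_masks():
    """With a plateau fitness (any mask containing bit 0 scores 1.0), the
    parsimony penalty must drive the GA to the singleton mask."""
    p = 8

    def fn(mask: FeatureMask) -> float:
        base = 1.0 if mask.bits[0] else 0.0
        return base - 0.05 * mask.selected_count / p

    cfg = GAConfig(population_size=30, generations=60, seed=0, patience=60)
    mask, _ = ga_select(_Dummy(p), cfg, fitness_fn=fn)
    assert mask.bits[0] and mask.selected_count == 1


def test_unlabelled_data_rejected():
    with pytest.raises(ValueError):
        ga_select(_Dummy(6), GAConfig(seed=0))
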