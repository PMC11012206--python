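"""Genetic-algorithm selection of characteristic wavelengths.

Individuals are binary masks over spectral variables. Fitness is the mean
stratified k-fold cross-validated accuracy of a base classifier restricted
to the masked columns, minus a parsimony penalty proportional to the
fraction of variables selected — computed on TRAINING data only, so the
held-out test set never influences which wavelengths are kept.

The generational loop is standard: tournament selection, uniform crossover,
per-bit flip mutation, repair of all-zero masks (one uniformly random bit is
set), and elitism. Ties in fitness are broken toward smaller masks, then
lexicographic bit order, so runs are exactly reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class FeatureMask:
    """Boolean mask over spectral variables; at least one bit must be set."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=bool)
        object.__setattr__(self, "bits", bits)
        if bits.ndim != 1:
            raise ValueError("mask bits must be a 1-D vector")
        if not bits.any():
            raise ValueError("feature mask must select at least one variable")

    @property
    def selected_count(self) -> int:
        return int(self.bits.sum())

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class GAConfig:
    """GA parameters. None of these is dictated by the study, so every one
    is configurable; the defaults are common wavelength-selection practice.

    ``mutation_prob_per_bit`` of None resolves to 1/p at run time.
    ``base_classifier`` of None resolves to a 100-tree random-forest spec —
    cheap enough to sit inside the CV fitness loop.
    """

    population_size: int = 50
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob_per_bit: Optional[float] = None
    tournament_size: int = 3
    elitism_count: int = 1
    init_density: float = 0.3
    parsimony_lambda: float = 0.01
    cv_folds: int = 5
    base_classifier: Optional[object] = None
    patience: int = 20
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1 or self.patience < 1:
            raise ValueError("generations and patience must be >= 1")
        if not 0 <= self.crossover_prob <= 1:
            raise ValueError("crossover_prob must be in [0, 1]")
        if self.mutation_prob_per_bit is not None and not (
            0 <= self.mutation_prob_per_bit <= 1
        ):
            raise ValueError("mutation_prob_per_bit must be in [0, 1]")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")
        if not 0 < self.init_density <= 1:
            raise ValueError("init_density must be in (0, 1]")
        if self.parsimony_lambda < 0:
            raise ValueError("parsimony_lambda must be nonnegative")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def resolved_base_classifier(self):
        if self.base_classifier is not None:
            return self.base_classifier
        from .classify import ClassifierSpec

        return ClassifierSpec(
            "rf", {"n_estimators": 100},
            seed=int(self.seed or 0) % (2**31 - 1),
        )


@dataclass
class GAHistory:
    """Per-generation best fitness/mask and the final population's
    per-variable selection frequency."""

    best_fitness_per_generation: list = field(default_factory=list)
    best_mask_per_generation: list = field(default_factory=list)
    selection_frequency: Optional[np.ndarray] = None


def fitness(mask: FeatureMask, train, config: GAConfig) -> float:
    """Cross-validated-accuracy fitness of one mask on training data.

    Mean stratified ``cv_folds``-fold CV accuracy of the base classifier on
    the masked columns, minus ``parsimony_lambda * selected_count / p``.
    Fold assignment and classifier seeds derive from ``config.seed``, so the
    value is deterministic.
    """
    from .classify import predict, train_classifier

    if mask.selected_count == 0:  # unreachable via FeatureMask, kept for rawbits
        raise ValueError("empty feature mask")
    y = np.asarray(train.labels, dtype=object)
    _, counts = np.unique(y.astype(str), return_counts=True)
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"every class needs >= cv_folds={config.cv_folds} samples"
        )
    seed = int(config.seed or 0) % (2**31 - 1)
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    spec = config.resolved_base_classifier()
    x = train.values[:, mask.bits]
    accs = []
    for tr, te in skf.split(x, y.astype(str)):
        fold_train = train.take_rows(tr)
        model = train_classifier(spec, fold_train, mask=mask)
        pred = predict(model, train.values[te])
        accs.append(float(np.mean(pred == y[te])))
    penalty = config.parsimony_lambda * mask.selected_count / len(mask.bits)
    return float(np.mean(accs)) - penalty


def _sort_key(fit: float, bits: np.ndarray):
    # higher fitness first; ties -> fewer bits, then lexicographic bit order
    return (-fit, int(bits.sum()), tuple(np.flatnonzero(bits)))


def _repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not bits.any():
        bits = bits.copy()
        bits[rng.integers(len(bits))] = True
    return bits


def ga_select(train, config: GAConfig,
              fitness_fn: Optional[Callable[[FeatureMask], float]] = None):
    """Run the GA and return ``(best FeatureMask, GAHistory)``.

    Parameters
    ----------
    train
        Labelled training dataset (SpectralDataset or FusedDataset). The
        test partition must not be passed here.
    config
        GA parameters; the whole run is reproducible from ``config.seed``.
    fitness_fn
        Optional replacement fitness ``FeatureMask -> float`` (used e.g. for
        deterministic benchmark functions); defaults to the CV fitness
        above.
    """
    if fitness_fn is None:
        labels = getattr(train, "labels", None)
        if labels is None or len(set(labels)) < 2:
            raise ValueError("training data must be labelled with >= 2 classes")
        fitness_fn = lambda m: fitness(m, train, config)
    p = train.n_variables if hasattr(train, "n_variables") else len(train)
    mut_p = (1.0 / p if config.mutation_prob_per_bit is None
             else config.mutation_prob_per_bit)
    rng = np.random.default_rng(int(config.seed or 0) % (2**31 - 1))

    pop = [
        _repair(rng.random(p) < config.init_density, rng)
        for _ in range(config.population_size)
    ]
    cache: dict = {}

    def evaluate(bits: np.ndarray) -> float:
        key = bits.tobytes()
        if key not in cache:
            cache[key] = float(fitness_fn(FeatureMask(bits)))
        return cache[key]

    history = GAHistory()
    best_bits, best_fit = None, -np.inf
    stale = 0
    for _gen in range(config.generations):
        fits = [evaluate(b) for b in pop]
        order = sorted(range(len(pop)), key=lambda i: _sort_key(fits[i], pop[i]))
        gen_best = order[0]
        improved = fits[gen_best] > best_fit
        if best_bits is None or _sort_key(fits[gen_best], pop[gen_best]) < _sort_key(
            best_fit, best_bits
        ):
            best_bits, best_fit = pop[gen_best].copy(), fits[gen_best]
        stale = 0 if improved else stale + 1
        history.best_fitness_per_generation.append(best_fit)
        history.best_mask_per_generation.append(FeatureMask(best_bits.copy()))
        if stale >= config.patience:
            break

        def tournament() -> np.ndarray:
            idx = rng.integers(len(pop), size=config.tournament_size)
            win = min(idx, key=lambda i: _sort_key(fits[i], pop[i]))
            return pop[win]

        next_pop = [pop[i].copy() for i in order[: config.elitism_count]]
        while len(next_pop) < config.population_size:
            mother, father = tournament(), tournament()
            if rng.random() < config.crossover_prob:
                swap = rng.random(p) < 0.5
                child = np.where(swap, father, mother)
            else:
                child = mother.copy()
            flip = rng.random(p) < mut_p
            child = np.logical_xor(child, flip)
            next_pop.append(_repair(child, rng))
        pop = next_pop

    final = np.stack(pop)
    history.selection_frequency = final.mean(axis=0)
    return FeatureMask(best_bits), history
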