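"""Train/test splitting and the four classifier families compared in the
study: support-vector (svc), random-forest (rf), feedforward-network (ann)
and gradient-boosted trees (gbt, an XGBoost-style engine).

The split reproduces the 70/30 random division: the training set has exactly
floor(train_fraction * n) samples; under stratification each class
contributes floor(train_fraction * n_c), with the remaining slots assigned
to the classes with the largest fractional parts. All stochastic elements
(split, forests, network initialisation, boosting) are seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .datasets import FusedDataset, SpectralDataset
from .ga import FeatureMask

FAMILIES = ("svc", "rf", "ann", "gbt")

# Accepted hyperparameter names per family; unknown names are rejected at
# spec construction so typos fail fast rather than silently using defaults.
_ALLOWED_HYPERPARAMS = {
    "svc": {"C", "gamma", "kernel"},
    "rf": {"n_estimators", "max_features", "max_depth", "min_samples_leaf"},
    "ann": {"hidden_layer_sizes", "activation", "max_iter", "early_stopping",
            "alpha", "learning_rate_init"},
    "gbt": {"n_estimators", "max_depth", "learning_rate", "subsample",
            "colsample_bytree", "reg_lambda"},
}

_DEFAULT_HYPERPARAMS = {
    "svc": {"kernel": "rbf", "C": 10.0, "gamma": "scale"},
    "rf": {"n_estimators": 500, "max_features": "sqrt"},
    "ann": {"hidden_layer_sizes": (100,), "activation": "relu",
            "max_iter": 1000, "early_stopping": False},
    # stochastic boosting (row/column subsampling) decorrelates trees and is
    # markedly more robust than deterministic boosting on row-normalised
    # spectra, where the whole row shares any residual scale distortion
    "gbt": {"n_estimators": 300, "max_depth": 6, "learning_rate": 0.1,
            "subsample": 0.8, "colsample_bytree": 0.5},
}


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split: 70/30 by default, stratified by default.

    A seed of None means "derive from the pipeline's global seed" (treated
    as 0 in standalone use).
    """

    train_fraction: float = 0.7
    stratified: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def split_train_test(dataset, spec: SplitSpec):
    """Partition a dataset's rows into (train, test).

    The train size is exactly floor(train_fraction * n). Stratified mode
    allocates floor(train_fraction * n_c) per class and hands the remaining
    slots to the classes with the largest fractional parts (ties broken by
    class order). Reproducible from ``spec.seed``.
    """
    n = dataset.n_samples
    rng = np.random.default_rng(0 if spec.seed is None else int(spec.seed))
    n_train = int(np.floor(spec.train_fraction * n))
    if spec.stratified:
        class_rows = {
            c: np.flatnonzero(dataset.labels == c) for c in dataset.class_order
        }
        singletons = [c for c, rows in class_rows.items() if len(rows) < 2]
        if singletons:
            raise ValueError(
                f"stratified split needs >= 2 samples per class; "
                f"class {singletons[0]!r} has fewer"
            )
        exact = {c: spec.train_fraction * len(r) for c, r in class_rows.items()}
        take = {c: int(np.floor(v)) for c, v in exact.items()}
        remainder = n_train - sum(take.values())
        by_frac = sorted(
            dataset.class_order,
            key=lambda c: (-(exact[c] - take[c]), dataset.class_order.index(c)),
        )
        for c in by_frac[:remainder]:
            take[c] += 1
        train_idx = []
        for c in dataset.class_order:
            rows = rng.permutation(class_rows[c])
            train_idx.extend(rows[: take[c]])
        train_idx = np.sort(np.array(train_idx, dtype=int))
    else:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    test_idx = np.flatnonzero(~mask)
    return dataset.take_rows(train_idx), dataset.take_rows(test_idx)


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family plus hyperparameters and a seed.

    family in {"svc", "rf", "ann", "gbt"}; hyperparameters not listed fall
    back to the package defaults (rbf-C10 SVC, 500-tree forest, one
    100-unit hidden layer, 300 boosting rounds at depth 6 / eta 0.1).
    """

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        unknown = set(self.hyperparameters) - _ALLOWED_HYPERPARAMS[self.family]
        if unknown:
            raise ValueError(
                f"unknown hyperparameters for {self.family}: {sorted(unknown)}"
            )

    def resolved_hyperparameters(self) -> dict:
        params = dict(_DEFAULT_HYPERPARAMS[self.family])
        params.update(self.hyperparameters)
        return params

    def build(self):
        """Instantiate the underlying estimator, seeded and single-threaded."""
        p = self.resolved_hyperparameters()
        seed = 0 if self.seed is None else int(self.seed)
        if self.family == "svc":
            return SVC(random_state=seed, **p)
        if self.family == "rf":
            return RandomForestClassifier(random_state=seed, n_jobs=1, **p)
        if self.family == "ann":
            return MLPClassifier(random_state=seed, **p)
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0, **p)


@dataclass
class TrainedModel:
    """A fitted classifier with its spec, class order and input contract."""

    spec: ClassifierSpec
    estimator: object
    class_order: list
    feature_count: int
    mask: Optional[FeatureMask] = None
    _encode: dict = field(default_factory=dict, repr=False)
    _decode: dict = field(default_factory=dict, repr=False)


def _design_matrix(data) -> np.ndarray:
    if isinstance(data, (SpectralDataset, FusedDataset)):
        return data.values
    return np.asarray(data, dtype=float)


def train_classifier(spec: ClassifierSpec, train,
                     mask: Optional[FeatureMask] = None) -> TrainedModel:
    """Fit one classifier on the (optionally masked) training columns.

    Raises
    ------
    ValueError
        On single-class training data, non-finite features, or an empty
        mask.
    """
    x = _design_matrix(train)
    y = np.asarray(train.labels, dtype=object)
    if mask is not None:
        x = x[:, mask.bits]
    if x.shape[1] == 0:
        raise ValueError("empty feature mask")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite training features")
    present = [c for c in train.class_order if c in set(y)]
    if len(present) < 2:
        raise ValueError("training data must contain at least 2 classes")
    encode = {c: i for i, c in enumerate(present)}
    decode = {i: c for c, i in encode.items()}
    y_enc = np.array([encode[l] for l in y])
    est = spec.build()
    est.fit(x, y_enc)
    return TrainedModel(
        spec=spec, estimator=est, class_order=list(train.class_order),
        feature_count=x.shape[1], mask=mask, _encode=encode, _decode=decode,
    )


def predict(model: TrainedModel, data) -> np.ndarray:
    """Predict one label per row; applies the model's mask if it has one.

    Raises
    ------
    ValueError
        If the (masked) input width differs from the fitted feature count.
    """
    x = _design_matrix(data)
    if model.mask is not None and x.shape[1] == len(model.mask.bits):
        x = x[:, model.mask.bits]
    if x.shape[1] != model.feature_count:
        raise ValueError(
            f"input width {x.shape[1]} != fitted feature count "
            f"{model.feature_count}"
        )
    y_enc = np.asarray(model.estimator.predict(x), dtype=int)
    return np.array([model._decode[i] for i in y_enc], dtype=object)
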