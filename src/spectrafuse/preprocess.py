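"""Per-spectrum preprocessing: SNV, MSC and Savitzky-Golay smoothing.

All three operate row-wise on the absorbance matrix. SNV and SG are
stateless; MSC carries a reference spectrum which, in pipeline use, is
estimated from the training partition only and then frozen (see
:class:`Preprocessor`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from .datasets import SpectralDataset

_MSC_SLOPE_TOL = 1e-12


def _as_matrix(data):
    """Accept a SpectralDataset or a raw matrix; return (matrix, ids, wrap)."""
    if isinstance(data, SpectralDataset):
        return data.values, data.sample_ids, data.with_values
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    ids = np.array([f"row {i}" for i in range(x.shape[0])], dtype=object)
    return x, ids, lambda v: v


def snv(data, ddof: int = 1):
    """Standard normal variate: per spectrum, subtract the mean and divide
    by the standard deviation (sample sd, divisor p-1, by default).

    Removes additive offset and multiplicative scatter; every output row has
    mean 0 and (with ``ddof=1``) sample sd 1.

    Raises
    ------
    ValueError
        If a spectrum has fewer than 2 variables or zero variance (the
        offending sample ID is named).
    """
    x, ids, wrap = _as_matrix(data)
    if x.shape[1] < 2:
        raise ValueError("SNV requires at least 2 variables per spectrum")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    zero = np.flatnonzero(sd[:, 0] == 0)
    if zero.size:
        raise ValueError(f"zero-variance spectrum: sample {ids[zero[0]]!r}")
    return wrap((x - mean) / sd)


def msc(data, reference: Optional[np.ndarray] = None):
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference r by ordinary least
    squares, x_j ~ a + b r_j, and corrected to (x - a) / b. When
    ``reference`` is omitted it is the column-wise mean of ``data`` itself;
    in train/test use pass a reference estimated from training data only.

    Raises
    ------
    ValueError
        If the reference has the wrong length or zero variance, or a
        spectrum's fitted slope is ~0 (uncorrelated with the reference).
    """
    x, ids, wrap = _as_matrix(data)
    if reference is None:
        reference = x.mean(axis=0)
    r = np.asarray(reference, dtype=float)
    if r.shape != (x.shape[1],):
        raise ValueError("reference length must equal the number of variables")
    r_centered = r - r.mean()
    denom = np.dot(r_centered, r_centered)
    if denom == 0:
        raise ValueError("MSC reference has zero variance")
    b = (x - x.mean(axis=1, keepdims=True)) @ r_centered / denom
    a = x.mean(axis=1) - b * r.mean()
    bad = np.flatnonzero(np.abs(b) < _MSC_SLOPE_TOL)
    if bad.size:
        raise ValueError(
            f"MSC slope ~ 0 for sample {ids[bad[0]]!r}: "
            "spectrum uncorrelated with reference"
        )
    return wrap((x - a[:, None]) / b[:, None])


def sg_smooth(data, window: int = 11, polyorder: int = 2):
    """Savitzky-Golay smoothing (derivative order 0).

    Each point is replaced by the value of the least-squares polynomial of
    degree ``polyorder`` fitted over the centred ``window``; edges are
    handled by mirror padding (reflection without repeating the edge point).

    Raises
    ------
    ValueError
        If the window is even, smaller than 3, larger than the number of
        variables, or ``polyorder >= window``.
    """
    x, _, wrap = _as_matrix(data)
    if window % 2 == 0 or window < 3:
        raise ValueError("SG window must be an odd integer >= 3")
    if window > x.shape[1]:
        raise ValueError("SG window exceeds the number of variables")
    if not 0 <= polyorder < window:
        raise ValueError("SG polyorder must satisfy 0 <= polyorder < window")
    return wrap(savgol_filter(x, window, polyorder, axis=1, mode="mirror"))


@dataclass
class PreprocessSpec:
    """Choice of preprocessing method and its parameters.

    method one of {"none", "snv", "msc", "sg"}. ``sg_window``/``sg_polyorder``
    apply only to SG; ``msc_reference``, when None, is computed from the
    training partition at fit time.
    """

    method: str = "snv"
    sg_window: int = 11
    sg_polyorder: int = 2
    msc_reference: Optional[np.ndarray] = None

    _METHODS = ("none", "snv", "msc", "sg")

    def __post_init__(self) -> None:
        if self.method not in self._METHODS:
            raise ValueError(f"method must be one of {self._METHODS}")
        if self.method == "sg":
            if self.sg_window % 2 == 0 or self.sg_window < 3:
                raise ValueError("sg_window must be an odd integer >= 3")
            if not 0 <= self.sg_polyorder < self.sg_window:
                raise ValueError("sg_polyorder must be in [0, sg_window)")

    @property
    def label(self) -> str:
        """Short name used in comparison tables ('SNV', 'MSC', 'SG', 'Raw')."""
        return {"none": "Raw", "snv": "SNV", "msc": "MSC", "sg": "SG"}[self.method]


class Preprocessor:
    """Fit/transform wrapper around the three methods.

    ``fit`` estimates any state (only MSC has state: its reference spectrum,
    the training column mean) from training data; ``transform`` applies the
    frozen transform to any partition. SNV/SG/none are stateless, so for
    them fit is a no-op.
    """

    def __init__(self, spec: PreprocessSpec):
        self.spec = spec
        self.reference_: Optional[np.ndarray] = (
            None if spec.msc_reference is None
            else np.asarray(spec.msc_reference, dtype=float)
        )

    def fit(self, train) -> "Preprocessor":
        if self.spec.method == "msc" and self.reference_ is None:
            x, _, _ = _as_matrix(train)
            self.reference_ = x.mean(axis=0)
        return self

    def transform(self, data):
        m = self.spec.method
        if m == "none":
            return data
        if m == "snv":
            return snv(data)
        if m == "msc":
            if self.reference_ is None:
                raise RuntimeError("MSC preprocessor must be fitted first")
            return msc(data, self.reference_)
        return sg_smooth(data, self.spec.sg_window, self.spec.sg_polyorder)

    def fit_transform(self, train):
        return self.fit(train).transform(train)
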