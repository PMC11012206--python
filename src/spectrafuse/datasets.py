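"""In-memory containers for sample-aligned spectral data.

A :class:`SpectralDataset` is a samples x variables absorbance matrix with a
strictly increasing spectral axis (wavelength in nm or wavenumber in cm^-1),
unique per-sample identifiers and a categorical origin label per sample. The
ordered class set is fixed at construction so downstream confusion matrices
have a reproducible row/column order.

A :class:`FusedDataset` is the column-wise concatenation of several blocks
(low-level data fusion) and remembers which column range came from which
block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_UNITS = ("nm", "cm-1")


def _ordered_unique(seq) -> list:
    """Unique elements in order of first appearance."""
    seen: dict = {}
    for x in seq:
        seen.setdefault(x, None)
    return list(seen)


@dataclass
class SpectralDataset:
    """Absorbance matrix with axis, sample IDs and origin labels.

    Parameters
    ----------
    values
        Real matrix, shape (n_samples, n_variables). No missing values.
    axis
        Spectral axis, shape (n_variables,), strictly increasing.
    units
        ``"nm"`` for UV-Vis wavelength or ``"cm-1"`` for mid-IR wavenumber.
    sample_ids
        Unique sample identifiers, length n_samples.
    labels
        Origin label per sample, length n_samples.
    class_order
        Ordered class set. Defaults to order of first appearance in
        ``labels``; fixed thereafter for confusion-matrix reproducibility.
    """

    values: np.ndarray
    axis: np.ndarray
    units: str
    sample_ids: np.ndarray
    labels: np.ndarray
    class_order: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n == 0 or p == 0:
            raise ValueError("dataset must have at least one sample and one variable")
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}, got {self.units!r}")
        if self.axis.shape != (p,):
            raise ValueError(
                f"axis length {self.axis.shape[0]} != number of variables {p}"
            )
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if self.sample_ids.shape != (n,) or self.labels.shape != (n,):
            raise ValueError("sample_ids and labels must each have one entry per row")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        ids, counts = np.unique(self.sample_ids.astype(str), return_counts=True)
        if np.any(counts > 1):
            dup = ids[counts > 1][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        observed = _ordered_unique(self.labels)
        if self.class_order is None:
            self.class_order = observed
        else:
            self.class_order = list(self.class_order)
            missing = [c for c in observed if c not in self.class_order]
            if missing:
                raise ValueError(f"labels outside class_order: {missing}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def take_rows(self, idx) -> "SpectralDataset":
        """Row subset (or reordering) preserving axis and class order."""
        idx = np.asarray(idx)
        return SpectralDataset(
            values=self.values[idx],
            axis=self.axis.copy(),
            units=self.units,
            sample_ids=self.sample_ids[idx],
            labels=self.labels[idx],
            class_order=list(self.class_order),
        )

    def with_values(self, values: np.ndarray) -> "SpectralDataset":
        """Same metadata, new absorbance matrix of identical shape."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("replacement values must keep the matrix shape")
        return SpectralDataset(
            values=values,
            axis=self.axis.copy(),
            units=self.units,
            sample_ids=self.sample_ids.copy(),
            labels=self.labels.copy(),
            class_order=list(self.class_order),
        )

    def copy(self) -> "SpectralDataset":
        return self.with_values(self.values.copy())


@dataclass
class FusedDataset:
    """Column-wise concatenation of spectral blocks with provenance.

    ``block_slices`` is an ordered list of ``(name, start, stop)`` half-open
    column ranges tiling ``[0, n_variables)`` without gaps or overlaps.
    """

    values: np.ndarray
    block_slices: list
    sample_ids: np.ndarray
    labels: np.ndarray
    class_order: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        n, p = self.values.shape
        pos = 0
        for name, start, stop in self.block_slices:
            if start != pos or stop <= start:
                raise ValueError("block_slices must tile columns without gaps")
            pos = stop
        if pos != p:
            raise ValueError("block_slices do not cover all columns")
        if self.sample_ids.shape != (n,) or self.labels.shape != (n,):
            raise ValueError("sample_ids and labels must each have one entry per row")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def block_names(self) -> list:
        return [name for name, _, _ in self.block_slices]

    def block(self, name: str) -> np.ndarray:
        """Columns of one source block, as stored."""
        for bname, start, stop in self.block_slices:
            if bname == name:
                return self.values[:, start:stop]
        raise KeyError(f"no block named {name!r}")

    def take_rows(self, idx) -> "FusedDataset":
        idx = np.asarray(idx)
        return FusedDataset(
            values=self.values[idx],
            block_slices=list(self.block_slices),
            sample_ids=self.sample_ids[idx],
            labels=self.labels[idx],
            class_order=list(self.class_order),
        )
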