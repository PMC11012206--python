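"""Delimited-text reading and writing of spectral matrices.

Dialect: UTF-8 CSV, one header row ``sample_id,label,<axis 1>,...,<axis p>``
and one row per sample. Descending axes (the usual export order for
wavenumber spectra) are reversed on load together with their columns so that
storage is always ascending.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import SpectralDataset

_META_COLS = ("sample_id", "label")


def load_spectra(path, units: str) -> SpectralDataset:
    """Load a spectral matrix from the package CSV dialect.

    Parameters
    ----------
    path
        CSV file with header ``sample_id,label,<axis values...>``.
    units
        Axis units, ``"nm"`` or ``"cm-1"``.

    Raises
    ------
    ValueError
        On duplicate sample IDs, non-numeric cells, ragged rows, or an axis
        that is not strictly monotonic after sorting.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "label": str})
    for col in _META_COLS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    axis_cols = [c for c in df.columns if c not in _META_COLS]
    if not axis_cols:
        raise ValueError("file has no spectral columns")
    try:
        axis = np.array([float(c) for c in axis_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric axis value in header: {exc}") from None
    values = df[axis_cols].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df[axis_cols].map(lambda v: isinstance(v, str)).any()
        raise ValueError(f"non-numeric cells in columns: {list(bad[bad].index)}")
    diffs = np.diff(axis)
    if np.all(diffs < 0):  # descending export: reverse axis and columns together
        axis = axis[::-1]
        values = values[:, ::-1]
    return SpectralDataset(
        values=values,
        axis=axis,
        units=units,
        sample_ids=df["sample_id"].to_numpy(),
        labels=df["label"].to_numpy(),
    )


def save_spectra(dataset: SpectralDataset, path) -> None:
    """Write a dataset in the CSV dialect; ``load(save(D)) == D`` to ~1e-12.

    Axis values and absorbances are written with 12 significant digits.
    """
    df = pd.DataFrame(dataset.values, columns=[f"{v:.12g}" for v in dataset.axis])
    df.insert(0, "label", dataset.labels)
    df.insert(0, "sample_id", dataset.sample_ids)
    df.to_csv(path, index=False, float_format="%.12g")
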