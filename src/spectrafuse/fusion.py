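"""Low-level data fusion: end-to-end column-wise concatenation of blocks.

Rows are aligned by sample ID (to the first block's order), so the input
blocks may list their samples in different orders. No rescaling happens at
fusion time — scale handling is a preprocessing concern (SNV already puts
every spectrum of every block on a common per-row scale). An optional
per-block autoscale is available for non-SNV workflows.
"""

from __future__ import annotations

import numpy as np

from .datasets import FusedDataset, SpectralDataset


def llfuse(blocks, names=None, autoscale: bool = False) -> FusedDataset:
    """Concatenate spectral blocks column-wise into one fused matrix.

    Parameters
    ----------
    blocks
        Ordered list of :class:`SpectralDataset`. All must contain the same
        sample IDs (order may differ) with identical labels per ID.
    names
        Block names for provenance; defaults to the axis units, made unique.
    autoscale
        If True, standardise each block's columns (mean 0, sd 1 over
        samples) before concatenation.

    Raises
    ------
    ValueError
        If the blocks' ID sets differ or a sample's label disagrees between
        blocks (the offending ID is named).
    """
    blocks = list(blocks)
    if not blocks:
        raise ValueError("at least one block is required")
    if names is None:
        names = []
        for blk in blocks:
            base = {"nm": "uv", "cm-1": "mir"}.get(blk.units, blk.units)
            name, k = base, 1
            while name in names:
                k += 1
                name = f"{base}{k}"
            names.append(name)
    if len(names) != len(blocks):
        raise ValueError("one name per block required")

    first = blocks[0]
    ref_ids = list(first.sample_ids)
    ref_labels = dict(zip(first.sample_ids, first.labels))
    parts, slices, pos = [], [], 0
    for name, blk in zip(names, blocks):
        id_to_row = {sid: i for i, sid in enumerate(blk.sample_ids)}
        missing = set(ref_ids) ^ set(id_to_row)
        if missing:
            raise ValueError(f"sample ID mismatch between blocks: {sorted(missing)[0]!r}")
        order = [id_to_row[sid] for sid in ref_ids]
        for sid in ref_ids:
            if blk.labels[id_to_row[sid]] != ref_labels[sid]:
                raise ValueError(f"label disagreement for sample {sid!r}")
        vals = blk.values[order]
        if autoscale:
            sd = vals.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            vals = (vals - vals.mean(axis=0)) / sd
        parts.append(vals)
        slices.append((name, pos, pos + vals.shape[1]))
        pos += vals.shape[1]

    return FusedDataset(
        values=np.hstack(parts),
        block_slices=slices,
        sample_ids=first.sample_ids.copy(),
        labels=first.labels.copy(),
        class_order=list(first.class_order),
    )
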