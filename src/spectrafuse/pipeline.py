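"""End-to-end origin-traceability experiment, statsmodels-style.

:class:`TraceabilityPipeline` is the model object: it is built from one or
more sample-aligned spectral blocks (loaded from files or generated
synthetically) plus a :class:`PipelineConfig`, and its :meth:`fit` runs the
full experiment — per-block preprocessing, a single shared stratified
train/test split, optional GA wavelength selection on training data only,
low-level fusion, training of every configured classifier family, and
confusion-matrix evaluation on the held-out test set.

:meth:`fit` returns a :class:`PipelineResult` carrying one cell per
(block set x classifier): train/test accuracy, the full evaluation report
and the selected wavelength mask. ``summary()`` renders the comparison
table (rows = model x preprocessing, train/test accuracy columns per block
set); ``to_json()`` gives a deterministic machine-readable dump with a full
provenance echo of the resolved configuration.

Leakage discipline: the split is computed first; MSC references, GA fitness
and classifier fitting see training rows only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .classify import ClassifierSpec, SplitSpec, predict, split_train_test, train_classifier
from .datasets import SpectralDataset
from .evaluate import EvaluationReport, evaluate, report_to_text
from .fusion import llfuse
from .ga import FeatureMask, GAConfig, ga_select
from .preprocess import PreprocessSpec, Preprocessor
from .synthetic import SyntheticConfig, generate_block

logger = logging.getLogger("spectrafuse")

GA_PLACEMENTS = ("per_block", "post_fusion", "off")
_DEFAULT_CLASSIFIERS = tuple(ClassifierSpec(f) for f in ("svc", "rf", "ann", "gbt"))


def derive_seed(global_seed: int, *tags) -> int:
    """Stable sub-seed (< 2^31) from a global seed and string tags."""
    words = [int(global_seed)] + [zlib.crc32(str(t).encode()) for t in tags]
    return int(np.random.SeedSequence(words).generate_state(1)[0] % (2**31 - 1))


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run (and re-run, bit-for-bit) one experiment.

    ``block_sets`` lists the block combinations to compare, e.g.
    ``[("uv",), ("mir",), ("mir", "uv")]`` for the single-block vs fused
    comparison; the default is the fused MIR-then-UV arm. One split, derived
    from ``global_seed``, is shared by every cell so models are compared on
    common footing. Sub-seeds (split, GA, classifiers) are derived from
    ``global_seed`` unless a spec carries its own explicit seed.
    """

    synthetic: Optional[SyntheticConfig] = None
    block_paths: dict = field(default_factory=dict)  # name -> (path, units)
    block_sets: tuple = (("mir", "uv"),)
    # one spec applied to every block, or a {block name: spec} mapping
    preprocess: object = field(default_factory=PreprocessSpec)
    split: SplitSpec = field(default_factory=SplitSpec)
    ga: Optional[GAConfig] = None
    ga_placement: str = "post_fusion"
    classifiers: tuple = _DEFAULT_CLASSIFIERS
    output_dir: Optional[str] = None
    global_seed: int = 0

    def __post_init__(self) -> None:
        if self.ga_placement not in GA_PLACEMENTS:
            raise ValueError(f"ga_placement must be one of {GA_PLACEMENTS}")
        if not self.block_sets or any(len(bs) == 0 for bs in self.block_sets):
            raise ValueError("block_sets must contain at least one non-empty set")
        if not self.classifiers:
            raise ValueError("at least one classifier is required")

    @property
    def ga_active(self) -> bool:
        return self.ga_placement != "off" and self.ga is not None

    def preprocess_for(self, block: str) -> PreprocessSpec:
        if isinstance(self.preprocess, dict):
            return self.preprocess[block]
        return self.preprocess

    @property
    def preprocessing_label(self) -> str:
        if isinstance(self.preprocess, dict):
            labels = sorted({spec.label for spec in self.preprocess.values()})
            base = "/".join(labels)
        else:
            base = self.preprocess.label
        return base + ("-GA" if self.ga_active else "")


@dataclass
class CellResult:
    """One (block set, classifier) cell of the comparison."""

    block_set: str
    family: str
    train_accuracy: float
    test_accuracy: float
    report: EvaluationReport
    train_report: EvaluationReport
    mask: Optional[FeatureMask] = None


class PipelineResult:
    """Fitted-experiment results: per-cell accuracies, reports and masks."""

    def __init__(self, cells, config: PipelineConfig, class_order, timings):
        self.cells = cells  # dict[(block_set_name, family)] -> CellResult
        self.config = config
        self.class_order = list(class_order)
        self.timings = timings

    def cell(self, block_set: str, family: str) -> CellResult:
        return self.cells[(block_set, family)]

    @property
    def block_set_names(self) -> list:
        names = []
        for bs, _ in self.cells:
            if bs not in names:
                names.append(bs)
        return names

    def test_accuracies(self, block_set: Optional[str] = None) -> dict:
        """family -> test accuracy (%) for one block set (default: first)."""
        bs = block_set or self.block_set_names[0]
        return {
            fam: c.test_accuracy for (b, fam), c in self.cells.items() if b == bs
        }

    def summary(self) -> str:
        """Comparison table in the study's layout: one row per model, train
        and test accuracy (percent, 2 decimals) per block set."""
        label = self.config.preprocessing_label
        sets = self.block_set_names
        head = f"{'Model':<8}{'Preprocessing':<16}"
        for bs in sets:
            head += f"{bs + ' Train(%)':>16}{bs + ' Test(%)':>15}"
        lines = [head, "-" * len(head)]
        for spec in self.config.classifiers:
            row = f"{spec.family.upper():<8}{label:<16}"
            for bs in sets:
                c = self.cell(bs, spec.family)
                row += f"{c.train_accuracy:>16.2f}{c.test_accuracy:>15.2f}"
            lines.append(row)
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        cells = {}
        for (bs, fam), c in sorted(self.cells.items()):
            cells[f"{bs}/{fam}"] = {
                "train_accuracy": round(c.train_accuracy, 10),
                "test_accuracy": round(c.test_accuracy, 10),
                "confusion": c.report.confusion.tolist(),
                "n_test": c.report.n_test,
                "selected_variables": (
                    None if c.mask is None
                    else np.flatnonzero(c.mask.bits).tolist()
                ),
            }
        return {
            "class_order": [str(c) for c in self.class_order],
            "config": _echo(self.config),
            "cells": cells,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def save(self, out_dir) -> None:
        """Write summary table, per-cell reports and the JSON echo."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.txt").write_text(self.summary())
        (out / "result.json").write_text(self.to_json() + "\n")
        for (bs, fam), c in sorted(self.cells.items()):
            (out / f"report_{bs.replace('+', '_')}_{fam}.txt").write_text(
                report_to_text(c.report)
            )

    def plot_confusion(self, block_set: Optional[str] = None,
                       family: str = "svc", ax=None):
        """Heatmap of one cell's confusion matrix (rows = predicted)."""
        from .plotting import plot_confusion

        bs = block_set or self.block_set_names[0]
        return plot_confusion(self.cell(bs, family).report, ax=ax)


def _echo(obj):
    """Deterministic, JSON-safe echo of a (possibly nested) config."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _echo(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
            if not f.name.startswith("_")
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _echo(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_echo(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


class TraceabilityPipeline:
    """The experiment as a model object: blocks + config, ``fit()`` runs it."""

    def __init__(self, blocks: dict, config: PipelineConfig):
        self.config = config
        self.blocks = self._align(blocks)

    @staticmethod
    def _align(blocks: dict) -> dict:
        """Align all blocks to the first block's sample order; validate."""
        if not blocks:
            raise ValueError("at least one block is required")
        names = list(blocks)
        first = blocks[names[0]]
        ref = list(first.sample_ids)
        aligned = {names[0]: first}
        for name in names[1:]:
            blk = blocks[name]
            pos = {sid: i for i, sid in enumerate(blk.sample_ids)}
            diff = set(ref) ^ set(pos)
            if diff:
                raise ValueError(f"block {name!r}: sample ID mismatch {sorted(diff)[0]!r}")
            order = [pos[sid] for sid in ref]
            blk = blk.take_rows(order)
            if not np.array_equal(blk.labels, first.labels):
                raise ValueError(f"block {name!r}: labels disagree with first block")
            aligned[name] = blk
        return aligned

    @classmethod
    def from_synthetic(cls, config: PipelineConfig) -> "TraceabilityPipeline":
        if config.synthetic is None:
            raise ValueError("config.synthetic is not set")
        needed = sorted({b for bs in config.block_sets for b in bs})
        blocks = {name: generate_block(config.synthetic, name) for name in needed}
        return cls(blocks, config)

    @classmethod
    def from_files(cls, config: PipelineConfig) -> "TraceabilityPipeline":
        from .io import load_spectra

        if not config.block_paths:
            raise ValueError("config.block_paths is empty")
        blocks = {
            name: load_spectra(path, units)
            for name, (path, units) in config.block_paths.items()
        }
        return cls(blocks, config)

    # ------------------------------------------------------------------ fit

    def fit(self) -> PipelineResult:
        cfg = self.config
        timings: dict = {}
        t0 = time.perf_counter()

        first = next(iter(self.blocks.values()))
        split_spec = cfg.split
        if split_spec.seed is None:
            split_spec = replace(split_spec, seed=derive_seed(cfg.global_seed, "split"))
        train_first, _ = split_train_test(first, split_spec)
        train_ids = set(train_first.sample_ids)
        train_idx = np.array(
            [i for i, sid in enumerate(first.sample_ids) if sid in train_ids]
        )
        test_idx = np.array(
            [i for i, sid in enumerate(first.sample_ids) if sid not in train_ids]
        )
        timings["split"] = time.perf_counter() - t0
        logger.info("split: %d train / %d test (seed %s)",
                    len(train_idx), len(test_idx), split_spec.seed)

        cells = {}
        for block_set in cfg.block_sets:
            bs_name = "+".join(block_set)
            t0 = time.perf_counter()

            # per-block preprocessing, fitted on training rows only
            processed = []
            for name in block_set:
                blk = self.blocks[name]
                prep = Preprocessor(cfg.preprocess_for(name))
                prep.fit(blk.take_rows(train_idx))
                processed.append(prep.transform(blk))

            ga_seed = (cfg.ga.seed if cfg.ga is not None and cfg.ga.seed is not None
                       else derive_seed(cfg.global_seed, "ga", bs_name))

            mask = None
            if cfg.ga_active and cfg.ga_placement == "per_block":
                parts = []
                for name, blk in zip(block_set, processed):
                    ga_cfg = replace(cfg.ga, seed=derive_seed(ga_seed, name))
                    m, _ = ga_select(blk.take_rows(train_idx), ga_cfg)
                    parts.append(m.bits)
                mask = FeatureMask(np.concatenate(parts))

            fused = processed[0] if len(processed) == 1 else llfuse(
                processed, names=list(block_set)
            )
            train_set = fused.take_rows(train_idx)
            test_set = fused.take_rows(test_idx)

            if cfg.ga_active and cfg.ga_placement == "post_fusion":
                ga_cfg = replace(cfg.ga, seed=ga_seed)
                mask, _ = ga_select(train_set, ga_cfg)
            timings[f"{bs_name}/prepare"] = time.perf_counter() - t0
            if mask is not None:
                logger.info("%s: GA selected %d/%d variables",
                            bs_name, mask.selected_count, len(mask.bits))

            for spec in cfg.classifiers:
                t0 = time.perf_counter()
                if spec.seed is None:
                    spec_run = replace(
                        spec, seed=derive_seed(cfg.global_seed, "clf", spec.family)
                    )
                else:
                    spec_run = spec
                model = train_classifier(spec_run, train_set, mask=mask)
                train_report = evaluate(
                    train_set.labels, predict(model, train_set), first.class_order
                )
                test_report = evaluate(
                    test_set.labels, predict(model, test_set), first.class_order
                )
                cells[(bs_name, spec.family)] = CellResult(
                    block_set=bs_name,
                    family=spec.family,
                    train_accuracy=train_report.accuracy,
                    test_accuracy=test_report.accuracy,
                    report=test_report,
                    train_report=train_report,
                    mask=mask,
                )
                timings[f"{bs_name}/{spec.family}"] = time.perf_counter() - t0
                logger.info("%s/%s: train %.2f%% test %.2f%%",
                            bs_name, spec.family,
                            train_report.accuracy, test_report.accuracy)

        result = PipelineResult(cells, cfg, first.class_order, timings)
        if cfg.output_dir:
            result.save(cfg.output_dir)
        return result


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Build the pipeline from its configured data source and fit it."""
    if config.synthetic is not None:
        pipe = TraceabilityPipeline.from_synthetic(config)
    else:
        pipe = TraceabilityPipeline.from_files(config)
    return pipe.fit()


def compare_table(result: PipelineResult) -> str:
    """The comparison table of a fitted run (same as ``result.summary()``)."""
    return result.summary()
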