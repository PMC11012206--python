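"""Plotting helpers: mean spectra by class and confusion-matrix heatmaps."""

from __future__ import annotations

import numpy as np

from .datasets import SpectralDataset
from .evaluate import EvaluationReport


def plot_mean_spectra(dataset: SpectralDataset, ax=None):
    """Mean spectrum per origin class over the block's axis.

    Wavenumber (cm^-1) axes are displayed descending, as conventional for
    mid-IR, although storage is ascending.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for cls in dataset.class_order:
        rows = dataset.values[dataset.labels == cls]
        ax.plot(dataset.axis, rows.mean(axis=0), label=str(cls))
    xlabel = "Wavelength (nm)" if dataset.units == "nm" else "Wavenumber (cm$^{-1}$)"
    if dataset.units == "cm-1":
        ax.invert_xaxis()
    ax.set_xlabel(xlabel)
    ax.set_ylabel("Absorbance")
    ax.legend(fontsize="small")
    return ax


def plot_confusion(report: EvaluationReport, ax=None):
    """Heatmap of the confusion matrix (rows = predicted, columns = true)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    cm = report.confusion
    im = ax.imshow(cm, cmap="Blues")
    classes = [str(c) for c in report.class_order]
    ax.set_xticks(range(len(classes)), classes, rotation=45, ha="right")
    ax.set_yticks(range(len(classes)), classes)
    ax.set_xlabel("True class")
    ax.set_ylabel("Predicted class")
    thresh = cm.max() / 2 if cm.max() else 0.5
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(int(cm[i, j])), ha="center", va="center",
                    color="white" if cm[i, j] > thresh else "black")
    ax.figure.colorbar(im, ax=ax)
    ax.set_title(f"Accuracy {report.accuracy:.2f}%")
    return ax


def plot_ga_history(history, ax=None):
    """Best fitness per generation of a GA run."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    y = history.best_fitness_per_generation
    ax.plot(np.arange(1, len(y) + 1), y)
    ax.set_xlabel("Generation")
    ax.set_ylabel("Best fitness")
    return ax
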