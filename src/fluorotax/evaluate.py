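"""Evaluation: confusion matrices, Cohen's kappa, stratified k-fold CV,
and the covariance-RMSE audit of smoothing distortion.

Fold-averaged confusion matrices carry fractional entries (elementwise
mean over folds); Cohen's kappa accepts them unchanged. Two kappa
summaries are reported for a cross-validation: the kappa of the averaged
matrix (the default headline number) and the mean of the per-fold
kappas — on balanced data they differ only in the third decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .spectra import SpectraSet

__all__ = [
    "ConfusionMatrix",
    "UndefinedKappaError",
    "CVResult",
    "confusion_matrix",
    "cohens_kappa",
    "cross_validate",
    "covariance_rmse",
]


class UndefinedKappaError(ValueError):
    """Chance agreement is 1: kappa is undefined (degenerate single class)."""


@dataclass
class ConfusionMatrix:
    """Square class x class matrix; rows = true, columns = predicted.

    Entries are nonnegative reals — fractional when fold-averaged.
    """

    classes: list[str]
    matrix: np.ndarray
    n_folds: int = 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.classes)
        if self.matrix.shape != (k, k):
            raise ValueError("matrix must be square over the class list")
        if np.any(self.matrix < 0):
            raise ValueError("confusion counts must be nonnegative")
        if self.matrix.sum() <= 0:
            raise ValueError("confusion matrix must have a positive total")

    @property
    def total(self) -> float:
        return float(self.matrix.sum())

    def to_dict(self) -> dict:
        return {"classes": self.classes, "matrix": self.matrix.tolist(),
                "n_folds": self.n_folds}


def confusion_matrix(true_labels: Sequence[str], pred_labels: Sequence[str],
                     classes: Sequence[str]) -> ConfusionMatrix:
    """Count predictions into a class x class matrix in the given order."""
    if len(true_labels) != len(pred_labels):
        raise ValueError("true and predicted label lists differ in length")
    pos = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)))
    for t, p in zip(true_labels, pred_labels):
        if t not in pos or p not in pos:
            raise ValueError(f"label {t if t not in pos else p!r} not in "
                             "the class list")
        cm[pos[t], pos[p]] += 1.0
    return ConfusionMatrix(list(classes), cm)


def cohens_kappa(cm: ConfusionMatrix | np.ndarray) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement (trace / total) and p_e the agreement
    expected by chance from the marginals. Fractional (fold-averaged)
    matrices are accepted.
    """
    m = cm.matrix if isinstance(cm, ConfusionMatrix) else np.asarray(cm, float)
    n = m.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    po = float(np.trace(m)) / n
    pe = float(m.sum(axis=1) @ m.sum(axis=0)) / n ** 2
    if pe >= 1.0 - 1e-15:
        raise UndefinedKappaError("chance agreement is 1; kappa undefined")
    return float((po - pe) / (1.0 - pe))


@dataclass
class CVResult:
    """Per-fold and aggregated cross-validation outcome."""

    classes: list[str]
    fold_matrices: list[ConfusionMatrix]
    averaged: ConfusionMatrix
    fold_kappas: list[float]
    kappa_averaged: float     # kappa of the fold-averaged matrix (headline)
    kappa_mean: float         # mean of per-fold kappas

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "averaged_confusion": self.averaged.to_dict(),
            "fold_kappas": self.fold_kappas,
            "kappa_averaged": self.kappa_averaged,
            "kappa_mean": self.kappa_mean,
        }


FitPredict = Callable[[SpectraSet, SpectraSet], Sequence[str]]


def cross_validate(fit_predict: FitPredict, sset: SpectraSet,
                   folds: int = 5, seed: int | None = None) -> CVResult:
    """Stratified k-fold cross-validation of a fit-and-predict procedure.

    ``fit_predict(train_set, test_set)`` must fit every stateful stage on
    the training fold only and return predicted labels for the held-out
    fold. Fold assignment is stratified and seeded; the averaged matrix
    is the elementwise mean of the per-fold matrices.
    """
    if sset.labels is None:
        raise ValueError("labelled data required for cross-validation")
    classes = sorted(set(sset.labels))
    counts = {c: sset.labels.count(c) for c in classes}
    lacking = [c for c, n in counts.items() if n < folds]
    if lacking:
        raise ValueError(f"classes with fewer members than folds: {lacking}")

    y = np.asarray(sset.labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_matrices: list[ConfusionMatrix] = []
    fold_kappas: list[float] = []
    for train_idx, test_idx in skf.split(sset.values, y):
        train, test = sset.subset(train_idx), sset.subset(test_idx)
        pred = list(fit_predict(train, test))
        cm = confusion_matrix(list(y[test_idx]), pred, classes)
        fold_matrices.append(cm)
        fold_kappas.append(cohens_kappa(cm))

    avg = ConfusionMatrix(
        classes,
        np.mean([cm.matrix for cm in fold_matrices], axis=0),
        n_folds=folds,
    )
    return CVResult(classes, fold_matrices, avg, fold_kappas,
                    cohens_kappa(avg), float(np.mean(fold_kappas)))


def covariance_rmse(original: SpectraSet, smoothed: SpectraSet,
                    at: float = 684.0) -> float:
    """RMS difference between covariance-matrix rows at one wavelength.

    Computes the wavelength x wavelength population covariance matrix of
    each set (over measurements) and returns the root-mean-square
    difference of the two rows at wavelength ``at`` (default 684 nm, just
    red of the chlorophyll-a peak). Larger values mean the smoother has
    distorted the second-order statistics more.
    """
    if original.grid.shape != smoothed.grid.shape or not np.allclose(
            original.grid, smoothed.grid):
        raise ValueError("grids do not match")
    if original.n_measurements != smoothed.n_measurements:
        raise ValueError("measurement counts do not match")
    idx = np.flatnonzero(np.isclose(original.grid, at))
    if idx.size == 0:
        raise ValueError(f"wavelength {at} nm is not on the grid")
    i = int(idx[0])

    def cov(sset: SpectraSet) -> np.ndarray:
        xc = sset.values - sset.values.mean(axis=0)
        return xc.T @ xc / sset.n_measurements

    row_a = cov(original)[i]
    row_b = cov(smoothed)[i]
    return float(np.sqrt(np.mean((row_a - row_b) ** 2)))
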