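"""Confusion-matrix metrics for imbalanced classes and Cohen's kappa.

With 8 Silver, 12 Aged and 5 Extra-aged samples the class sizes are
unbalanced, so raw accuracy can flatter a classifier that favours the
majority class.  This module computes one-vs-rest per-class metrics
(classification rate, accuracy, precision, sensitivity, specificity) with
unweighted (macro) averages, and the chance-corrected agreement

    kappa = (N * sum_i m_ii - sum_i G_i * C_i) / (N^2 - sum_i G_i * C_i)

where ``m_ii`` are the confusion-matrix diagonal counts, ``G_i`` the truth
(row) totals and ``C_i`` the prediction (column) totals.  This is
algebraically identical to ``(p_o - p_e) / (1 - p_e)`` with observed
agreement ``p_o = sum m_ii / N`` and chance agreement
``p_e = sum G_i C_i / N^2``.  Note kappa can be negative for worse-than-
chance agreement even though the customary interpretation bands start at 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .categories import CATEGORY_ORDER
from .errors import DataError

__all__ = [
    "ConfusionMatrix",
    "KappaResult",
    "confusion",
    "class_metrics",
    "macro_average",
    "cohens_kappa",
    "interpret_kappa",
    "per_fold_rates",
    "fold_kappas",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = truth class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise DataError("confusion matrix must be square")
        if counts.shape[0] != len(self.labels):
            raise DataError("label count must match matrix size")
        if (counts < 0).any():
            raise DataError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def truth_totals(self) -> np.ndarray:
        """Row totals G_i."""
        return self.counts.sum(axis=1)

    @property
    def predicted_totals(self) -> np.ndarray:
        """Column totals C_i."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its observed and chance agreement components."""

    kappa: float
    observed_agreement: float
    chance_agreement: float


def _true_pred(cv_or_true, predicted=None) -> tuple[np.ndarray, np.ndarray]:
    if predicted is None:
        frame = cv_or_true.frame  # a chemometrics.CVResult
        return frame["true"].to_numpy(), frame["predicted"].to_numpy()
    return np.asarray(cv_or_true), np.asarray(predicted)


def confusion(cv_or_true, predicted=None, labels: Sequence[str] | None = None) -> ConfusionMatrix:
    """Tally (truth, prediction) pairs into a confusion matrix.

    Accepts either a :class:`~eeye.chemometrics.CVResult` or two label
    sequences.  ``labels`` fixes the class order (default: the tequila
    category order, or first appearance for other label sets).
    """
    true, pred = _true_pred(cv_or_true, predicted)
    if true.shape[0] == 0:
        raise DataError("no predictions to tabulate")
    if labels is None:
        seen = set(true) | set(pred)
        if seen <= set(CATEGORY_ORDER):
            labels = tuple(c for c in CATEGORY_ORDER if c in seen)
        else:
            labels = tuple(dict.fromkeys(list(true) + list(pred)))
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(true, pred):
        if t not in index or p not in index:
            raise DataError(f"label outside the class set: true={t!r}, predicted={p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


def class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest metrics per class plus the macro (unweighted) Average row.

    Per class i: sensitivity = m_ii / G_i, specificity = TN / (N - G_i),
    precision = m_ii / C_i (0 with a warning if the class is never
    predicted), accuracy = (TP + TN) / N, classification rate (%) =
    100 * sensitivity.
    """
    counts = cm.counts
    N = cm.N
    G = cm.truth_totals
    C = cm.predicted_totals
    if (G < 1).any():
        empty = [cm.labels[i] for i in np.flatnonzero(G < 1)]
        raise DataError(f"class(es) with no truth observations: {empty}")
    rows = []
    for i, label in enumerate(cm.labels):
        tp = counts[i, i]
        fn = G[i] - tp
        fp = C[i] - tp
        tn = N - tp - fn - fp
        sensitivity = tp / G[i]
        specificity = tn / (N - G[i]) if N > G[i] else 1.0
        if C[i] == 0:
            warnings.warn(f"class {label!r} never predicted; precision set to 0", stacklevel=2)
            precision = 0.0
        else:
            precision = tp / C[i]
        rows.append({
            "class": label,
            "rate_pct": 100.0 * sensitivity,
            "accuracy": (tp + tn) / N,
            "precision": precision,
            "sensitivity": sensitivity,
            "specificity": specificity,
        })
    frame = pd.DataFrame(rows).set_index("class")
    frame.loc["Average"] = frame.mean(axis=0)
    return frame


def macro_average(values: Sequence[float]) -> float:
    """Unweighted mean over per-class values (the Average row convention)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DataError("macro average of an empty sequence")
    return float(values.mean())


def cohens_kappa(cm: ConfusionMatrix) -> KappaResult:
    """Chance-corrected agreement of the confusion matrix (see module docs).

    If the denominator ``N^2 - sum G_i C_i`` vanishes (all truth and
    prediction mass in a single-cell pattern), kappa is defined as 1 when
    agreement is perfect and is an error otherwise.
    """
    N = cm.N
    if N < 1:
        raise DataError("empty confusion matrix")
    diag = int(np.trace(cm.counts))
    gc = int(cm.truth_totals @ cm.predicted_totals)
    p_o = diag / N
    p_e = gc / N ** 2
    denominator = N ** 2 - gc
    if denominator == 0:
        if diag == N:
            return KappaResult(kappa=1.0, observed_agreement=1.0, chance_agreement=1.0)
        raise DataError("kappa undefined: chance agreement is 1 but agreement is imperfect")
    kappa = (N * diag - gc) / denominator
    return KappaResult(kappa=float(kappa), observed_agreement=p_o, chance_agreement=p_e)


_KAPPA_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def interpret_kappa(kappa: float) -> str:
    """Customary verbal band for a kappa value (upper bounds inclusive)."""
    if kappa > 1:
        raise DataError(f"kappa cannot exceed 1, got {kappa}")
    if kappa < 0:
        return "no agreement"
    for upper, label in _KAPPA_BANDS:
        if kappa <= upper:
            return label
    return "almost perfect"


def per_fold_rates(cv) -> pd.DataFrame:
    """Secondary aggregation: per-fold correct fraction, averaged per class.

    Each fold's rate is the fraction of its held-out replicates predicted
    correctly; rates are then averaged over the folds whose truth class is
    the same, giving a per-class fold-averaged rate in percent.
    """
    frame = cv.frame.assign(correct=cv.frame["true"] == cv.frame["predicted"])
    fold_stats = (
        frame.groupby(["fold", "true"], sort=False)["correct"].mean().reset_index(name="fold_rate")
    )
    out = fold_stats.groupby("true", sort=False)["fold_rate"].mean().mul(100.0)
    out.index.name = "class"
    return out.to_frame("rate_pct")


def fold_kappas(cv) -> list[float]:
    """Kappa per fold where defined (single-class folds are usually degenerate)."""
    values = []
    for _, sub in cv.frame.groupby("fold", sort=False):
        cm = confusion(sub["true"].to_numpy(), sub["predicted"].to_numpy(),
                       labels=CATEGORY_ORDER)
        try:
            values.append(cohens_kappa(cm).kappa)
        except DataError:
            continue
    return values
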