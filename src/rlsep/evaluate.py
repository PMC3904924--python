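"""Classifier quality: apparent error, leave-one-out cross-validation
error, confusion matrices, and feature/CRP Pearson correlation reports."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CplSpec, FeatureSubspace, LabeledDataset, LinearClassifier

__all__ = [
    "ConfusionMatrix",
    "apparent_error",
    "loo_cve",
    "feature_outcome_correlations",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion counts with rows = true class (G+ then G-) and
    columns = predicted class (G+ then G-)."""

    pos_pos: int  # G+ predicted G+
    pos_neg: int  # G+ predicted G-
    neg_pos: int  # G- predicted G+
    neg_neg: int  # G- predicted G-

    def __post_init__(self):
        if min(self.pos_pos, self.pos_neg, self.neg_pos, self.neg_neg) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def m_pos(self) -> int:
        return self.pos_pos + self.pos_neg

    @property
    def m_neg(self) -> int:
        return self.neg_pos + self.neg_neg

    @property
    def m(self) -> int:
        return self.m_pos + self.m_neg

    @property
    def error(self) -> float:
        return (self.pos_neg + self.neg_pos) / self.m

    @staticmethod
    def from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return ConfusionMatrix(
            pos_pos=int(((y_true == 1) & (y_pred == 1)).sum()),
            pos_neg=int(((y_true == 1) & (y_pred == -1)).sum()),
            neg_pos=int(((y_true == -1) & (y_pred == 1)).sum()),
            neg_neg=int(((y_true == -1) & (y_pred == -1)).sum()),
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.pos_pos, self.pos_neg], [self.neg_pos, self.neg_neg]],
            index=["true G+", "true G-"], columns=["pred G+", "pred G-"],
        )


def apparent_error(classifier: LinearClassifier, dataset: LabeledDataset) -> float:
    """Fraction of the training patients misclassified by the decision rule
    (w.x - theta > 0 -> G+; ties -> G-)."""
    pred = classifier.predict(dataset.X)
    return float((pred != dataset.y).mean())


def loo_cve(
    dataset: LabeledDataset,
    subspace: FeatureSubspace | None = None,
    spec: CplSpec = CplSpec(),
) -> tuple[float, ConfusionMatrix, np.ndarray]:
    """Leave-one-out cross-validation error on a fixed feature subspace.

    For each patient j the perceptron criterion (lambda = 0) is re-minimized
    on the other m-1 patients restricted to the subspace and patient j is
    classified by the refit hyperplane. Returns the error fraction, the
    confusion matrix assembled from the m held-out decisions, and the
    per-patient predictions in cohort order.

    Feature selection is *not* re-run inside the folds: the subspace is
    fixed, which replicates the usual protocol of evaluating a chosen
    subset and carries its known optimistic bias.
    """
    from .cpl import minimize_cpl  # local import to avoid cycle at module load

    m = dataset.m
    if m < 3:
        raise ValueError("leave-one-out needs at least 3 patients")
    if dataset.m_pos < 2 or dataset.m_neg < 2:
        raise ValueError("each class needs >= 2 members for leave-one-out")
    if subspace is None:
        subspace = FeatureSubspace.full(dataset.n)

    fit_spec = spec.with_lam(0.0)
    if fit_spec.alpha is not None:
        # per-object weights cannot be sliced unambiguously across folds
        fit_spec = CplSpec(delta=fit_spec.delta, gamma=fit_spec.gamma, lam=0.0)

    preds = np.empty(m, dtype=int)
    rows = np.arange(m)
    for j in range(m):
        train = dataset.subset_patients(rows[rows != j])
        sol = minimize_cpl(train, fit_spec, subspace)
        preds[j] = sol.classifier.predict(dataset.X[j:j + 1])[0]

    cm = ConfusionMatrix.from_predictions(dataset.y, preds)
    return cm.error, cm, preds


def feature_outcome_correlations(
    dataset: LabeledDataset, crp: np.ndarray | None = None
) -> pd.DataFrame:
    """Pearson correlation of each feature with raw CRP concentration.

    Returns a table (feature, block, r, p_value, undefined) with two-sided
    p-values from the t transform on m-2 degrees of freedom. Constant
    features get r = NaN and undefined = True instead of an error. The
    p-values are descriptive only; no multiple-testing correction.
    """
    if crp is None:
        crp = dataset.crp
    if crp is None:
        raise ValueError("CRP concentrations are required")
    crp = np.asarray(crp, dtype=float)
    if dataset.m < 3:
        raise ValueError("correlation report needs at least 3 patients")

    rows = []
    for i, f in enumerate(dataset.features):
        x = dataset.X[:, i]
        if np.nanstd(x) == 0 or np.nanstd(crp) == 0:
            rows.append((f.name, f.block, np.nan, np.nan, True))
            continue
        r, p = stats.pearsonr(x, crp)
        rows.append((f.name, f.block, float(r), float(p), False))
    return pd.DataFrame(rows, columns=["feature", "block", "r", "p_value", "undefined"])
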