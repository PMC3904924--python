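"""The two-axis diagnostic map.

A linear classifier fitted on a combined phenotypic + genetic subspace
induces an affine projection of each patient onto two coordinates: the
*phenotypic fraction* (the partial sum of w_i x_i over retained phenotypic
features) and the *genetic fraction* (the same over retained genetic
features). Because the two partial sums add up to the full decision score
plus theta, the classifier's boundary is the straight line
phen + gen = theta on the map, and map-side classification is lossless with
respect to the original decision rule. New patients placed on the map can
be classified by majority vote of their K nearest mapped neighbours
(a case-based-reasoning style rule)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GENETIC, PHENOTYPIC, LabeledDataset, LinearClassifier

__all__ = ["MapPoint", "project", "project_row", "map_predict", "knn_decide"]


@dataclass(frozen=True)
class MapPoint:
    """One patient on the diagnostic map."""

    patient_id: str
    phenotypic: float
    genetic: float
    label: int  # +1 / -1; 0 for an unlabeled query

    @property
    def coords(self) -> tuple[float, float]:
        return (self.phenotypic, self.genetic)


def _block_weights(classifier: LinearClassifier, dataset: LabeledDataset):
    idx = list(classifier.subspace.indices)
    blocks = [dataset.features[i].block for i in idx]
    if not all(b in (PHENOTYPIC, GENETIC) for b in blocks):
        raise ValueError("classifier subspace lacks block tags")
    phen = np.array([b == PHENOTYPIC for b in blocks])
    return idx, phen


def project(classifier: LinearClassifier, dataset: LabeledDataset) -> list[MapPoint]:
    """Project every patient onto (phenotypic fraction, genetic fraction).

    The sum of a patient's two fractions minus theta equals the full
    decision score exactly, so the boundary line phen + gen = theta
    reproduces the classifier's predictions on the map.
    """
    idx, phen_mask = _block_weights(classifier, dataset)
    sub = dataset.X[:, idx]
    contrib = sub * classifier.weights
    phen = contrib[:, phen_mask].sum(axis=1)
    gen = contrib[:, ~phen_mask].sum(axis=1)
    return [
        MapPoint(patient_id=dataset.patient_ids[j], phenotypic=float(phen[j]),
                 genetic=float(gen[j]), label=int(dataset.y[j]))
        for j in range(dataset.m)
    ]


def project_row(classifier: LinearClassifier, dataset: LabeledDataset,
                x: np.ndarray, patient_id: str = "query") -> MapPoint:
    """Place a single (new) patient's full feature row on the map; the row
    must already be expressed in the training coordinate frame (use the
    fitted Standardizer on raw measurements)."""
    idx, phen_mask = _block_weights(classifier, dataset)
    x = np.asarray(x, dtype=float)[idx]
    contrib = x * classifier.weights
    return MapPoint(patient_id=patient_id,
                    phenotypic=float(contrib[phen_mask].sum()),
                    genetic=float(contrib[~phen_mask].sum()), label=0)


def map_predict(points: list[MapPoint], threshold: float) -> np.ndarray:
    """Classify map points by the boundary line phen + gen = theta
    (strictly above -> G+, ties -> G-), mirroring the full decision rule."""
    scores = np.array([p.phenotypic + p.genetic for p in points]) - threshold
    return np.where(scores > 0.0, 1, -1)


def knn_decide(points: list[MapPoint], query: MapPoint, k: int = 5) -> int:
    """Majority label among the K nearest map points (Euclidean distance).

    K must be odd so the majority is strict; K = 5 is the conventional
    default. Distance ties break toward the lower patient index (stable
    order of ``points``).
    """
    if k % 2 == 0:
        raise ValueError("K must be odd so the majority vote is strict")
    if k > len(points):
        raise ValueError("K exceeds the number of map points")
    q = np.array(query.coords)
    coords = np.array([p.coords for p in points])
    d = np.sqrt(((coords - q) ** 2).sum(axis=1))
    nearest = np.argsort(d, kind="stable")[:k]
    vote = sum(points[i].label for i in nearest)
    return 1 if vote > 0 else -1


def map_frame(points: list[MapPoint], threshold: float) -> pd.DataFrame:
    """Map coordinates as a table (patient, fractions, label, side)."""
    side = map_predict(points, threshold)
    return pd.DataFrame({
        "patient": [p.patient_id for p in points],
        "phenotypic_fraction": [p.phenotypic for p in points],
        "genetic_fraction": [p.genetic for p in points],
        "label": [p.label for p in points],
        "side": side,
    })
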