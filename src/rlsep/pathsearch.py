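"""Relaxed linear separability: the descending feature-subspace path.

Raising the cost level lambda in the modified criterion Psi_lambda drives
weight components to exact zero; dropping the zeroed features and repeating
yields a nested, strictly shrinking sequence of feature subspaces
F_n ⊃ F_k ⊃ F_k' ⊃ ... Each recorded subspace is re-fit with the pure
perceptron criterion (lambda = 0) and scored by apparent error and
leave-one-out cross-validation error; the subspace with minimal CVE is the
selected model. Feature removal is permanent: once eliminated at some
lambda a feature never re-enters at a larger one, which is what makes the
recorded sequence nested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cpl import SEP_TOL, minimize_cpl
from .datamodel import CplSpec, FeatureSubspace, LabeledDataset, LinearClassifier
from .evaluate import ConfusionMatrix, apparent_error, loo_cve

__all__ = [
    "LambdaSchedule",
    "PathRecord",
    "RlsPath",
    "run_rls",
    "select_optimal_subspace",
    "rank_features",
]


@dataclass(frozen=True)
class LambdaSchedule:
    """Geometric cost-level grid with optional bisection refinement.

    lam0/ratio/lam_max define the grid lam0 * ratio**k up to lam_max. When
    one grid step would eliminate more than ``max_drop`` features, the
    interval is bisected (geometrically) until steps remove at most
    ``max_drop`` features or the interval is relatively tighter than
    ``refine_rtol`` — giving a near-unit-step dimension ladder at the
    default max_drop = 1. ``compute_cve`` can be switched off when only the
    subspace chain is needed.
    """

    lam0: float = 1e-4
    ratio: float = 1.2
    lam_max: float = 1e3
    max_drop: int = 1
    refine_rtol: float = 1e-3
    compute_cve: bool = True

    def __post_init__(self):
        if self.lam0 <= 0 or self.ratio <= 1 or self.lam_max <= self.lam0:
            raise ValueError("schedule requires lam0 > 0, ratio > 1, lam_max > lam0")
        if self.max_drop < 1:
            raise ValueError("max_drop must be >= 1")


@dataclass(frozen=True)
class PathRecord:
    """One subspace of the descending sequence with its quality measures."""

    lam: float
    subspace: FeatureSubspace
    classifier: LinearClassifier  # lambda = 0 refit on the subspace
    apparent_error: float
    separable: bool
    cve: float | None = None
    confusion: ConfusionMatrix | None = None

    @property
    def dimension(self) -> int:
        return self.subspace.dimension


@dataclass
class RlsPath:
    """The recorded descending sequence of feature subspaces."""

    records: list[PathRecord] = field(default_factory=list)

    def __post_init__(self):
        dims = [r.dimension for r in self.records]
        if any(d2 >= d1 for d1, d2 in zip(dims, dims[1:])):
            raise ValueError("recorded dimensions must strictly decrease")
        for r1, r2 in zip(self.records, self.records[1:]):
            if not r2.subspace.issubset(r1.subspace):
                raise ValueError("recorded subspaces must be nested")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def as_frame(self) -> pd.DataFrame:
        """Path table: the data behind an error-vs-dimension plot."""
        return pd.DataFrame(
            {
                "dimension": [r.dimension for r in self.records],
                "lambda": [r.lam for r in self.records],
                "AE": [r.apparent_error for r in self.records],
                "CVE": [r.cve for r in self.records],
                "separable": [r.separable for r in self.records],
            }
        )


def _make_record(dataset: LabeledDataset, spec: CplSpec, subspace: FeatureSubspace,
                 lam: float, compute_cve: bool) -> PathRecord:
    refit = minimize_cpl(dataset, spec.with_lam(0.0), subspace)
    ae = apparent_error(refit.classifier, dataset)
    separable = refit.objective <= SEP_TOL
    cve = conf = None
    if compute_cve:
        cve, conf, _ = loo_cve(dataset, subspace, spec)
    return PathRecord(
        lam=lam, subspace=subspace, classifier=refit.classifier,
        apparent_error=ae, separable=separable, cve=cve, confusion=conf,
    )


def run_rls(
    dataset: LabeledDataset,
    spec: CplSpec = CplSpec(),
    schedule: LambdaSchedule = LambdaSchedule(),
) -> RlsPath:
    """Generate the descending subspace sequence by raising the cost level.

    Starts from the full feature set (recorded at lambda = 0), walks the
    geometric lambda grid, drops the features whose optimal weights are
    exactly zero after each minimization, and records every distinct
    retained set with its lambda, a lambda = 0 refit classifier, apparent
    error, separability flag and (optionally) leave-one-out CVE. Terminates
    when one feature remains, the solution collapses to w = 0, or lambda
    exceeds the grid maximum. The procedure is deterministic: no randomness
    anywhere in the pipeline.
    """
    if not np.isfinite(dataset.X).all():
        raise ValueError("dataset contains missing or non-finite values")

    current = FeatureSubspace.full(dataset.n)
    records = [_make_record(dataset, spec, current, 0.0, schedule.compute_cve)]

    grid = []
    lam = schedule.lam0
    while lam <= schedule.lam_max:
        grid.append(lam)
        lam *= schedule.ratio

    pending = list(grid)
    prev_lam = 0.0
    i = 0
    while i < len(pending) and current.dimension > 1:
        lam = pending[i]
        sol = minimize_cpl(dataset, spec.with_lam(lam), current)
        retained = sol.nonzero_subspace
        if retained.dimension == current.dimension:
            prev_lam = lam
            i += 1
            continue
        ndrop = current.dimension - retained.dimension
        can_refine = (lam - prev_lam) > schedule.refine_rtol * lam and prev_lam > 0
        if ndrop > schedule.max_drop and can_refine:
            pending.insert(i, float(np.sqrt(prev_lam * lam)))
            continue
        if retained.dimension == 0:
            break  # cost term wiped every weight; no smaller subspace to record
        current = retained
        records.append(_make_record(dataset, spec, current, lam, schedule.compute_cve))
        prev_lam = lam
        i += 1

    return RlsPath(records)


def select_optimal_subspace(path: RlsPath) -> PathRecord:
    """The record with minimal cross-validation error; ties break toward
    the smaller dimension (records are stored in decreasing dimension)."""
    if len(path) == 0:
        raise ValueError("path has no records")
    scored = [r for r in path if r.cve is not None]
    if not scored:
        raise ValueError("path records carry no CVE; rerun with compute_cve=True")
    best = min(scored, key=lambda r: (r.cve, r.dimension))
    return best


def rank_features(classifier: LinearClassifier,
                  feature_names: list[str] | None = None) -> pd.DataFrame:
    """Order retained features by the absolute value of their optimal
    weight (the "factor"); the signed weight is kept alongside. Equal
    magnitudes preserve input order (stable sort)."""
    w = classifier.weights
    idx = list(classifier.subspace.indices)
    names = ([feature_names[i] for i in idx] if feature_names is not None
             else [f"feature_{i}" for i in idx])
    df = pd.DataFrame({
        "feature": names,
        "index": idx,
        "weight": w,
        "factor": np.abs(w),
        "sign": np.sign(w).astype(int),
    })
    return df.sort_values("factor", ascending=False, kind="stable").reset_index(drop=True)
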