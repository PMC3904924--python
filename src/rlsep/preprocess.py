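"""Cohort preparation: missingness filtering, genotype one-hot encoding,
class-wise nearest-neighbour imputation, the CRP median split, the
phenotypic/genetic/combined space partition, and continuous-feature
standardization.

The preparation order mirrors a typical clinical-genetics workflow: first
drop patients observed on too few features, then features observed on too
few of the surviving patients, encode genotype calls as indicators, and
finally fill the remaining holes from the most similar patient *of the same
learning set* — phenotype similarity for phenotypic holes, genotype
similarity for genetic holes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    GENETIC,
    PHENOTYPIC,
    FeatureInfo,
    LabeledDataset,
)

__all__ = [
    "GenotypeSite",
    "median_split",
    "filter_missingness",
    "encode_genotypes",
    "impute_nearest_neighbour",
    "partition_spaces",
    "SpacePartition",
    "Standardizer",
]


# ---------------------------------------------------------------------------
# Median split
# ---------------------------------------------------------------------------


def median_split(crp: np.ndarray) -> np.ndarray:
    """Split a cohort on the sample median of CRP concentration.

    Label +1 (G+, "inflamed") iff CRP is strictly above the median; values
    at or below the median get -1. The at-the-median tie goes to the
    low-CRP class so the rule is deterministic.
    """
    crp = np.asarray(crp, dtype=float)
    finite = np.isfinite(crp)
    if finite.sum() < 2:
        raise ValueError("median split needs at least 2 finite CRP values")
    med = np.median(crp[finite])
    y = np.where(crp > med, 1, -1)
    if (y == 1).sum() == 0 or (y == -1).sum() == 0:
        raise ValueError("median split produced an empty class (all CRP values equal?)")
    return y


# ---------------------------------------------------------------------------
# Missingness filtering
# ---------------------------------------------------------------------------


def filter_missingness(
    table: pd.DataFrame,
    patient_min_frac: float = 0.75,
    feature_min_frac: float = 0.75,
) -> pd.DataFrame:
    """Two-pass missingness filter on a raw cohort table.

    First drops patients (rows) whose observed fraction across features is
    below ``patient_min_frac``; then drops features (columns) whose observed
    fraction *among surviving patients* is below ``feature_min_frac``.
    """
    for frac, name in ((patient_min_frac, "patient_min_frac"),
                       (feature_min_frac, "feature_min_frac")):
        if not 0 < frac <= 1:
            raise ValueError(f"{name} must lie in (0, 1], got {frac}")
    obs = table.notna()
    keep_rows = obs.mean(axis=1) >= patient_min_frac
    reduced = table.loc[keep_rows]
    if reduced.shape[0] == 0:
        raise ValueError("missingness filter removed every patient")
    keep_cols = reduced.notna().mean(axis=0) >= feature_min_frac
    reduced = reduced.loc[:, keep_cols]
    if reduced.shape[1] == 0:
        raise ValueError("missingness filter removed every feature")
    return reduced


# ---------------------------------------------------------------------------
# Genotype encoding
# ---------------------------------------------------------------------------


@dataclass
class GenotypeSite:
    """One polymorphic site: its observed genotype categories and the
    indices of the binary indicator columns they produced."""

    site: str
    categories: list[str]
    column_indices: list[int] = field(default_factory=list)
    degenerate: bool = False  # single observed category -> one constant column


def encode_genotypes(calls: pd.DataFrame) -> tuple[pd.DataFrame, list[GenotypeSite]]:
    """One-hot encode genotype calls, one indicator per observed category.

    ``calls`` holds one column per polymorphic site with string genotype
    categories (e.g. AA/AG/GG); NaN means a missing call. A missing call
    yields NaN in *all* of that site's indicators (resolved by imputation).
    A site with a single observed category produces one constant column and
    is flagged degenerate rather than dropped, so that column counts match
    the coding convention (a usually-triple coding that shrinks when
    polymorphism is reduced, and grows to five for a tri-allelic site with
    five observed genotypes).
    """
    cols: dict[str, np.ndarray] = {}
    sites: list[GenotypeSite] = []
    j = 0
    for site in calls.columns:
        col = calls[site]
        observed = sorted(col.dropna().astype(str).unique())
        if not observed:
            raise ValueError(f"site {site!r} has no observed genotype calls")
        rec = GenotypeSite(site=str(site), categories=observed,
                           degenerate=len(observed) == 1)
        miss = col.isna().to_numpy()
        for cat in observed:
            ind = (col.astype(str) == cat).astype(float).to_numpy()
            ind[miss] = np.nan
            cols[f"{site}={cat}"] = ind
            rec.column_indices.append(j)
            j += 1
        sites.append(rec)
    return pd.DataFrame(cols, index=calls.index), sites


# ---------------------------------------------------------------------------
# Class-wise nearest-neighbour imputation
# ---------------------------------------------------------------------------


def _zscore_columns(X: np.ndarray) -> np.ndarray:
    """z-score each column on full-cohort statistics, ignoring NaN;
    zero-variance columns map to 0 so they never dominate a distance."""
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def _nearest_donors(
    scaled_block: np.ndarray, j: int, candidates: np.ndarray, hamming: bool
) -> np.ndarray:
    """Candidate donor rows ordered by distance to patient j over mutually
    observed columns (ties and empty overlaps -> lowest patient index)."""
    row = scaled_block[j]
    dists = np.full(len(candidates), np.inf)
    for k, c in enumerate(candidates):
        other = scaled_block[c]
        shared = ~np.isnan(row) & ~np.isnan(other)
        if not shared.any():
            continue
        diff = row[shared] - other[shared]
        if hamming:
            dists[k] = float(np.count_nonzero(diff))
        else:
            dists[k] = float(np.sqrt(np.sum(diff**2)))
    order = np.argsort(dists, kind="stable")  # stable: index breaks ties
    return candidates[order], dists[order]


def impute_nearest_neighbour(dataset: LabeledDataset) -> LabeledDataset:
    """Fill missing cells from the nearest same-class patient.

    Phenotypic holes use Euclidean distance over mutually observed
    phenotypic columns (z-scored on full-cohort statistics so scale does
    not dominate); genetic holes use Hamming distance over mutually
    observed genetic indicators. The donor must itself have the cell
    observed; among equally distant donors the lowest patient index wins.
    Observed cells are never altered.
    """
    X = dataset.X.copy()
    if not np.isnan(X).any():
        return dataset

    y = dataset.y
    block_specs = []
    pi = dataset.phenotypic_indices
    gi = dataset.genetic_indices
    if pi.size:
        block_specs.append((pi, _zscore_columns(X[:, pi]), False, PHENOTYPIC))
    if gi.size:
        block_specs.append((gi, X[:, gi].copy(), True, GENETIC))

    for cols, scaled, hamming, block_name in block_specs:
        missing_rows = np.flatnonzero(np.isnan(X[:, cols]).any(axis=1))
        for j in missing_rows:
            same_class = np.flatnonzero((y == y[j]) & (np.arange(len(y)) != j))
            donors, _ = _nearest_donors(scaled, j, same_class, hamming)
            for local_i, col in enumerate(cols):
                if not np.isnan(X[j, col]):
                    continue
                donor_vals = X[donors, col]
                ok = np.flatnonzero(~np.isnan(donor_vals))
                if ok.size == 0:
                    cls = "G+" if y[j] == 1 else "G-"
                    raise ValueError(
                        f"no donor for feature {dataset.features[col].name!r} "
                        f"in class {cls}: missing in every same-class patient"
                    )
                X[j, col] = donor_vals[ok[0]]

    out = LabeledDataset(
        X=X, y=y.copy(), features=list(dataset.features),
        patient_ids=list(dataset.patient_ids),
        crp=None if dataset.crp is None else dataset.crp.copy(),
    )
    return out


# ---------------------------------------------------------------------------
# Feature-space partition
# ---------------------------------------------------------------------------

SPACE_NAMES = ("phenotypic", "genetic", "combined")


@dataclass
class SpacePartition:
    """The three basic feature spaces: phenotypic, genetic, and their
    concatenation (phenotypic columns first, then genetic)."""

    _spaces: dict

    def __getitem__(self, name: str) -> LabeledDataset:
        if name not in SPACE_NAMES:
            raise KeyError(f"unknown space {name!r}; choose from {SPACE_NAMES}")
        ds = self._spaces.get(name)
        if ds is None:
            raise ValueError(f"the {name} space is empty for this cohort")
        return ds

    def available(self) -> list[str]:
        return [s for s in SPACE_NAMES if s in self._spaces]


def partition_spaces(dataset: LabeledDataset) -> SpacePartition:
    """Split a cohort into its phenotypic, genetic and combined spaces.

    The patient set is identical in all three; the combined space orders
    columns phenotypic-then-genetic. Requesting a space whose block is
    empty raises for that space only.
    """
    spaces: dict[str, LabeledDataset] = {}
    pi = dataset.phenotypic_indices
    gi = dataset.genetic_indices
    if pi.size:
        spaces["phenotypic"] = dataset.subset_features(pi)
    if gi.size:
        spaces["genetic"] = dataset.subset_features(gi)
    combined_order = np.concatenate([pi, gi]).astype(int)
    spaces["combined"] = dataset.subset_features(combined_order)
    return SpacePartition(spaces)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclass
class Standardizer:
    """z-scores continuous (phenotypic) columns once, before any fitting;
    binary genetic indicators pass through untouched. The fitted location
    and scale are kept so new patients can be mapped in the training
    coordinate frame."""

    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def fit(self, dataset: LabeledDataset) -> "Standardizer":
        mu = np.zeros(dataset.n)
        sd = np.ones(dataset.n)
        pi = dataset.phenotypic_indices
        if pi.size:
            mu[pi] = np.nanmean(dataset.X[:, pi], axis=0)
            s = np.nanstd(dataset.X[:, pi], axis=0)
            sd[pi] = np.where(s > 0, s, 1.0)
        self.mean_, self.scale_ = mu, sd
        return self

    def transform(self, dataset: LabeledDataset) -> LabeledDataset:
        if self.mean_ is None:
            raise RuntimeError("Standardizer must be fitted before transform")
        X = (dataset.X - self.mean_) / self.scale_
        return LabeledDataset(
            X=X, y=dataset.y.copy(), features=list(dataset.features),
            patient_ids=list(dataset.patient_ids),
            crp=None if dataset.crp is None else dataset.crp.copy(),
        )

    def fit_transform(self, dataset: LabeledDataset) -> LabeledDataset:
        return self.fit(dataset).transform(dataset)

    def transform_rows(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer must be fitted before transform")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_
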