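"""Core data types: labeled two-group cohorts, feature subspaces, linear
classifiers and CPL criterion parameters, plus cohort table readers/writers.

A cohort is a patients x features matrix split into two learning sets: G+
(label +1, high CRP / "inflamed") and G- (label -1, low CRP). Every feature
belongs to one of two blocks, ``phenotypic`` (continuous or ordinal clinical
measurements) or ``genetic`` (0/1 genotype indicators derived from
polymorphic sites). Missing values are carried as NaN until the imputation
stage; after preprocessing a dataset must be complete.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

PHENOTYPIC = "phenotypic"
GENETIC = "genetic"
BLOCKS = (PHENOTYPIC, GENETIC)

#: strings treated as a missing cell in cohort tables
MISSING_MARKERS = ("", "NA", "NaN", "nan", "N/A", "na", "NULL", "null", "?")


@dataclass(frozen=True)
class FeatureInfo:
    """Per-column metadata: display name, block, and (for genetic columns)
    the identifier of the polymorphic site the indicator came from."""

    name: str
    block: str
    site: str | None = None

    def __post_init__(self):
        if self.block not in BLOCKS:
            raise ValueError(
                f"feature {self.name!r}: block must be one of {BLOCKS}, got {self.block!r}"
            )
        if self.block == GENETIC and not self.site:
            raise ValueError(f"genetic feature {self.name!r} must carry a site identifier")


@dataclass(frozen=True)
class FeatureSubspace:
    """An ordered subset of feature indices of a parent dataset."""

    indices: tuple[int, ...]

    def __post_init__(self):
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("subspace indices must be unique")
        if any(i < 0 for i in self.indices):
            raise ValueError("subspace indices must be non-negative")

    @property
    def dimension(self) -> int:
        return len(self.indices)

    def issubset(self, other: "FeatureSubspace") -> bool:
        return set(self.indices) <= set(other.indices)

    @staticmethod
    def full(n: int) -> "FeatureSubspace":
        return FeatureSubspace(tuple(range(n)))


@dataclass
class LabeledDataset:
    """Two-group cohort: matrix X (m patients x n features), labels y in
    {+1, -1}, per-feature metadata, and optionally the raw CRP values the
    labels were derived from. NaN entries mean "missing"."""

    X: np.ndarray
    y: np.ndarray
    features: list[FeatureInfo]
    patient_ids: list[str] = field(default_factory=list)
    crp: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (patients x features)")
        m, n = self.X.shape
        if m == 0:
            raise ValueError("dataset has zero patients")
        if len(self.y) != m:
            raise ValueError("labels length does not match number of patients")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be +1 or -1")
        if (self.y == 1).sum() == 0 or (self.y == -1).sum() == 0:
            raise ValueError("both learning sets G+ and G- must be non-empty")
        if len(self.features) != n:
            raise ValueError("feature metadata length does not match number of columns")
        if not self.patient_ids:
            self.patient_ids = [f"P{j+1:04d}" for j in range(m)]
        if len(self.patient_ids) != m:
            raise ValueError("patient_ids length does not match number of patients")
        if self.crp is not None:
            self.crp = np.asarray(self.crp, dtype=float)
            if len(self.crp) != m:
                raise ValueError("crp length does not match number of patients")
        gi = self.genetic_indices
        if gi.size:
            g = self.X[:, gi]
            ok = np.isnan(g) | (g == 0.0) | (g == 1.0)
            if not ok.all():
                raise ValueError("genetic columns must take values in {0, 1} (or NaN)")

    # -- basic geometry -------------------------------------------------
    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    @property
    def m_pos(self) -> int:
        return int((self.y == 1).sum())

    @property
    def m_neg(self) -> int:
        return int((self.y == -1).sum())

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def blocks(self) -> np.ndarray:
        return np.array([f.block for f in self.features])

    @property
    def phenotypic_indices(self) -> np.ndarray:
        return np.flatnonzero(self.blocks == PHENOTYPIC)

    @property
    def genetic_indices(self) -> np.ndarray:
        return np.flatnonzero(self.blocks == GENETIC)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.X).any()

    # -- subsetting ------------------------------------------------------
    def subset_features(self, indices: Iterable[int]) -> "LabeledDataset":
        idx = np.asarray(list(indices), dtype=int)
        return LabeledDataset(
            X=self.X[:, idx].copy(),
            y=self.y.copy(),
            features=[self.features[i] for i in idx],
            patient_ids=list(self.patient_ids),
            crp=None if self.crp is None else self.crp.copy(),
        )

    def subset_patients(self, rows: Iterable[int]) -> "LabeledDataset":
        rows = np.asarray(list(rows), dtype=int)
        return LabeledDataset(
            X=self.X[rows].copy(),
            y=self.y[rows].copy(),
            features=list(self.features),
            patient_ids=[self.patient_ids[j] for j in rows],
            crp=None if self.crp is None else self.crp[rows].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.feature_names, index=self.patient_ids)


@dataclass(frozen=True)
class LinearClassifier:
    """Hyperplane H(w, theta) on a feature subspace.

    Decision rule: predict G+ (label +1) iff w.x - theta > 0; a score of
    exactly zero is assigned to G- (the tie policy is global and used
    identically by apparent error, leave-one-out and the diagnostic map).
    """

    weights: np.ndarray
    threshold: float
    subspace: FeatureSubspace

    def __post_init__(self):
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if len(self.weights) != self.subspace.dimension:
            raise ValueError("weight vector length must equal subspace dimension")

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        sub = X[:, list(self.subspace.indices)]
        return sub @ self.weights - self.threshold

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_scores(X) > 0.0, 1, -1)


@dataclass(frozen=True)
class CplSpec:
    """Parameters of the CPL criterion functions.

    delta   margin constant (unit margin by convention; any delta > 0 only
            rescales the optimal weights).
    alpha   per-object weights; None selects the class-balanced default
            alpha_j = 1/(2 m+) on G+ and 1/(2 m-) on G-, which sums to 1/2
            per class and makes the lambda -> infinity objective equal 1.
    gamma   per-feature costs (> 0); None means unit costs.
    lam     cost level lambda >= 0 of the modified criterion.
    """

    delta: float = 1.0
    alpha: np.ndarray | None = None
    gamma: np.ndarray | None = None
    lam: float = 0.0

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("margin constant delta must be positive")
        if self.lam < 0:
            raise ValueError("cost level lambda must be non-negative")
        if self.alpha is not None:
            a = np.asarray(self.alpha, dtype=float)
            if (a < 0).any():
                raise ValueError("object weights alpha must be non-negative")
            object.__setattr__(self, "alpha", a)
        if self.gamma is not None:
            g = np.asarray(self.gamma, dtype=float)
            if (g <= 0).any():
                raise ValueError("feature costs gamma must be strictly positive")
            object.__setattr__(self, "gamma", g)

    def resolve_alpha(self, y: np.ndarray) -> np.ndarray:
        if self.alpha is not None:
            if len(self.alpha) != len(y):
                raise ValueError("alpha length must equal number of patients")
            return self.alpha
        y = np.asarray(y)
        mp = (y == 1).sum()
        mn = (y == -1).sum()
        return np.where(y == 1, 0.5 / mp, 0.5 / mn)

    def resolve_gamma(self, k: int) -> np.ndarray:
        if self.gamma is not None:
            if len(self.gamma) != k:
                raise ValueError("gamma length must equal subspace dimension")
            return self.gamma
        return np.ones(k)

    def with_lam(self, lam: float) -> "CplSpec":
        return replace(self, lam=lam)


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------


def _load_metadata(metadata_path: str | Path) -> dict:
    p = Path(metadata_path)
    text = p.read_text()
    if p.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_cohort(table_path: str | Path, metadata_path: str | Path) -> LabeledDataset:
    """Read a cohort table (CSV/TSV, header row) with its metadata sidecar.

    The sidecar (YAML or JSON) declares every feature column::

        id_column: patient          # optional
        label_column: group         # optional; +1/-1, or high/low
        crp_column: crp             # optional; used for the median split
        decimal: "."                # "," for decimal-comma exports
        features:
          - {name: age, block: phenotypic}
          - {name: rs123, block: genetic, site: rs123, encoding: genotype}

    Genetic columns may hold 0/1 indicators directly, or raw genotype calls
    (``encoding: genotype``), which are expanded to one indicator per
    observed genotype category. Unparseable cells become NaN for the
    preprocessing stage. Labels come from ``label_column`` if present,
    otherwise from a strict-above-median split of ``crp_column``.
    """
    table_path = Path(table_path)
    meta = _load_metadata(metadata_path)
    feats_meta = meta.get("features")
    if not feats_meta:
        raise ValueError("metadata must declare a non-empty 'features' list")
    decimal = meta.get("decimal", ".")

    raw = pd.read_csv(table_path, sep=_sep_for(table_path), dtype=str,
                      keep_default_na=False)
    if raw.shape[0] == 0:
        raise ValueError("cohort table contains zero patients")

    declared = {f["name"] for f in feats_meta}
    special = {meta.get("id_column"), meta.get("label_column"), meta.get("crp_column")}
    undeclared = [c for c in raw.columns if c not in declared and c not in special]
    if undeclared:
        raise ValueError(
            f"column(s) {undeclared} present in table but absent from metadata"
        )
    absent = [f["name"] for f in feats_meta if f["name"] not in raw.columns]
    if absent:
        raise ValueError(f"feature(s) {absent} declared in metadata but absent from table")

    def parse_numeric(col: pd.Series) -> np.ndarray:
        s = col.str.strip()
        s = s.mask(s.isin(MISSING_MARKERS))
        if decimal == ",":
            s = s.str.replace(".", "", regex=False).str.replace(",", ".", regex=False)
        # python float() is correctly rounded; pandas' fast parser is not,
        # which would break bit-exact round-trips
        return np.array([_to_float(v) for v in s], dtype=float)

    columns: list[np.ndarray] = []
    features: list[FeatureInfo] = []
    for f in feats_meta:
        name, block = f["name"], f["block"]
        if block == GENETIC and f.get("encoding") == "genotype":
            # expand raw genotype calls into one indicator per observed category
            calls = raw[name].str.strip().mask(lambda s: s.isin(MISSING_MARKERS))
            cats = sorted(calls.dropna().unique())
            site = f.get("site", name)
            for cat in cats:
                ind = np.where(calls.isna(), np.nan, (calls == cat).astype(float))
                columns.append(ind)
                features.append(FeatureInfo(f"{name}={cat}", GENETIC, site=site))
        else:
            columns.append(parse_numeric(raw[name]))
            features.append(FeatureInfo(name, block, site=f.get("site")))

    X = np.column_stack(columns)

    ids_col = meta.get("id_column")
    patient_ids = (raw[ids_col].tolist() if ids_col and ids_col in raw.columns
                   else [f"P{j+1:04d}" for j in range(len(raw))])

    crp = None
    crp_col = meta.get("crp_column")
    if crp_col and crp_col in raw.columns:
        crp = parse_numeric(raw[crp_col])

    label_col = meta.get("label_column")
    if label_col and label_col in raw.columns:
        y = _parse_labels(raw[label_col])
    elif crp is not None:
        from .preprocess import median_split  # deferred: preprocess imports datamodel

        y = median_split(crp)
    else:
        raise ValueError("metadata must name a label_column or a crp_column")

    return LabeledDataset(X=X, y=y, features=features, patient_ids=patient_ids, crp=crp)


def _to_float(v) -> float:
    try:
        return float(v)
    except (TypeError, ValueError):
        return float("nan")


_LABEL_MAP = {"1": 1, "+1": 1, "-1": -1, "high": 1, "low": -1, "g+": 1, "g-": -1}


def _parse_labels(col: pd.Series) -> np.ndarray:
    vals = col.str.strip().str.lower().map(_LABEL_MAP)
    if vals.isna().any():
        bad = col[vals.isna()].unique()[:5]
        raise ValueError(f"unrecognised label values: {list(bad)}")
    return vals.to_numpy(dtype=int)


def write_cohort(dataset: LabeledDataset, table_path: str | Path,
                 metadata_path: str | Path) -> None:
    """Write a cohort back to CSV/TSV + sidecar; numeric values keep full
    precision so read_cohort(write_cohort(d)) round-trips bit-exactly."""
    table_path = Path(table_path)
    df = dataset.to_frame().copy()
    df.insert(0, "patient", dataset.patient_ids)
    if dataset.crp is not None:
        df["crp"] = dataset.crp
    df["label"] = dataset.y
    df.to_csv(table_path, sep=_sep_for(table_path), index=False,
              float_format="%.17g")

    meta: dict = {
        "id_column": "patient",
        "label_column": "label",
        "features": [
            {"name": f.name, "block": f.block, **({"site": f.site} if f.site else {})}
            for f in dataset.features
        ],
    }
    if dataset.crp is not None:
        meta["crp_column"] = "crp"
    p = Path(metadata_path)
    if p.suffix.lower() == ".json":
        p.write_text(json.dumps(meta, indent=2))
    else:
        p.write_text(yaml.safe_dump(meta, sort_keys=False))
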