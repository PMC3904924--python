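"""Synthetic mixed phenotypic/genetic cohort generator.

Emulates the structure of a two-group dialysis cohort split on the median
CRP concentration: ~112 vs ~113 patients, 57 continuous phenotypic
measurements, and 76 polymorphic sites whose genotype calls one-hot encode
to 228 binary indicators (285 features in total) when every site shows all
three genotypes. Class signal is injected two ways:

* *marginal mode* (default): informative phenotypic features are
  mean-shifted between classes by a chosen effect size (in SD units) and
  informative sites get a class allele-frequency shift, expanded to
  genotype frequencies under Hardy-Weinberg equilibrium.

* *complementary mode*: the class boundary lives on the sum of a
  phenotypic score and a genetic score. The genetic score s_g is the
  centered allele-count total over the informative sites (sampled with
  class-independent frequencies); the first informative phenotypic feature
  is then set to c*y - s_g with c = complementary_margin_factor * sd(s_g).
  The combined space is exactly separable (margin c along the direction
  pairing that feature with the allele-count weights), while each block
  alone overlaps: the phenotypic marginal has d' = 2c/sd(s_g) and the
  genetic block carries no marginal class signal. Neither block alone
  separates the classes, but their union does.

All randomness flows from a single seeded generator; a fixed seed gives
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GENETIC, PHENOTYPIC, FeatureInfo, LabeledDataset
from .preprocess import encode_genotypes

__all__ = ["SynthConfig", "GroundTruth", "generate_cohort", "inject_missingness"]

_GENO_LABELS = {0: "AA", 1: "AB", 2: "BB"}  # allele-B count -> genotype call


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults emulate the reference cohort geometry
    (112 + 113 patients, 57 phenotypic features, 76 sites -> 228 one-hot
    columns, 285 features in total)."""

    m_pos: int = 112
    m_neg: int = 113
    n_phenotypic: int = 57
    n_sites: int = 76
    informative_phenotypic: tuple[int, ...] = (0, 1, 2, 3, 4)
    phenotypic_effect: float = 1.0   # between-class mean shift, SD units
    informative_sites: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 8, 9)
    allele_freq_shift: float = 0.2   # class difference in allele-B frequency
    base_allele_freq: float = 0.5
    noise_sd: float = 1.0
    missingness: float = 0.0
    complementary: bool = False
    complementary_margin_factor: float = 0.8  # c in units of sd(s_g)
    seed: int = 0

    def __post_init__(self):
        if self.m_pos < 1 or self.m_neg < 1:
            raise ValueError("both classes need at least one patient")
        if not 0 <= self.missingness <= 0.5:
            raise ValueError("missingness rate must lie in [0, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be positive")
        if self.phenotypic_effect < 0:
            raise ValueError("phenotypic effect size must be non-negative")
        lo = self.base_allele_freq - self.allele_freq_shift / 2
        hi = self.base_allele_freq + self.allele_freq_shift / 2
        if not (0 < lo and hi < 1):
            raise ValueError("class allele frequencies must stay inside (0, 1)")
        if any(i >= self.n_phenotypic for i in self.informative_phenotypic):
            raise ValueError("informative phenotypic index out of range")
        if any(s >= self.n_sites for s in self.informative_sites):
            raise ValueError("informative site index out of range")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    informative_phenotypic: tuple[int, ...]   # column indices in X
    informative_sites: tuple[str, ...]        # site identifiers
    informative_genetic_columns: tuple[int, ...]  # one-hot column indices in X
    complementary: bool


def generate_cohort(config: SynthConfig = SynthConfig()) -> tuple[LabeledDataset, GroundTruth]:
    """Draw one cohort. Returns the dataset (complete unless a missingness
    rate was requested via :func:`inject_missingness`) and the ground truth."""
    rng = np.random.default_rng(config.seed)
    m = config.m_pos + config.m_neg
    y = np.concatenate([np.ones(config.m_pos, int), -np.ones(config.m_neg, int)])

    # raw CRP consistent with the labels under a strict-above-median split:
    # all G- concentrations below 5 mg/L, all G+ above
    crp = np.where(y == 1, rng.uniform(5.0, 9.0, m), rng.uniform(1.0, 5.0, m))

    # --- genetic block: genotype calls per site --------------------------
    p_pos = config.base_allele_freq + config.allele_freq_shift / 2
    p_neg = config.base_allele_freq - config.allele_freq_shift / 2
    counts = np.empty((m, config.n_sites), dtype=int)
    informative_sites = set(config.informative_sites)
    for s in range(config.n_sites):
        if s in informative_sites and not config.complementary:
            p = np.where(y == 1, p_pos, p_neg)
        else:
            p = np.full(m, config.base_allele_freq)
        counts[:, s] = rng.binomial(2, p)

    site_ids = [f"site{s+1:03d}" for s in range(config.n_sites)]
    if config.n_sites > 0:
        calls = pd.DataFrame(
            {site_ids[s]: [_GENO_LABELS[c] for c in counts[:, s]]
             for s in range(config.n_sites)}
        )
        genetic_df, site_records = encode_genotypes(calls)
    else:
        genetic_df = pd.DataFrame(index=range(m))
        site_records = []

    # --- phenotypic block ------------------------------------------------
    Xp = rng.normal(0.0, config.noise_sd, size=(m, config.n_phenotypic))
    if config.complementary:
        # genetic score: centered allele-count total over informative sites
        inf = sorted(informative_sites)
        s_g = (counts[:, inf] - 2 * config.base_allele_freq).sum(axis=1).astype(float)
        sd_g = np.sqrt(len(inf) * 2 * config.base_allele_freq * (1 - config.base_allele_freq))
        c = config.complementary_margin_factor * sd_g
        lead = config.informative_phenotypic[0]
        Xp[:, lead] = c * y - s_g
    else:
        shift = config.phenotypic_effect * config.noise_sd
        for i in config.informative_phenotypic:
            Xp[y == 1, i] += shift

    X = (np.column_stack([Xp, genetic_df.to_numpy()])
         if config.n_sites > 0 else Xp)
    features = [FeatureInfo(f"phen{i+1:03d}", PHENOTYPIC)
                for i in range(config.n_phenotypic)]
    features += [FeatureInfo(name, GENETIC, site=name.split("=")[0])
                 for name in genetic_df.columns]

    dataset = LabeledDataset(X=X, y=y, features=features, crp=crp)
    if config.missingness > 0:
        dataset = inject_missingness(dataset, config.missingness,
                                     seed=config.seed + 1)

    inf_site_ids = tuple(site_ids[s] for s in sorted(informative_sites))
    gen_cols = tuple(
        config.n_phenotypic + j
        for rec in site_records if rec.site in inf_site_ids
        for j in rec.column_indices
    )
    truth = GroundTruth(
        informative_phenotypic=(
            (config.informative_phenotypic[0],) if config.complementary
            else tuple(config.informative_phenotypic)
        ),
        informative_sites=inf_site_ids,
        informative_genetic_columns=gen_cols,
        complementary=config.complementary,
    )
    return dataset, truth


def inject_missingness(dataset: LabeledDataset, rate: float,
                       seed: int = 0) -> LabeledDataset:
    """Mask each cell independently with the given probability (NaN).

    The mask is reproducible from the seed and never alters unmasked
    values. Rates above 0.5 are rejected: beyond that the class-wise donor
    pool for imputation degenerates.
    """
    if not 0 <= rate <= 0.5:
        raise ValueError("missingness rate must lie in [0, 0.5]")
    if rate == 0:
        return dataset
    rng = np.random.default_rng(seed)
    mask = rng.random(dataset.X.shape) < rate
    X = dataset.X.copy()
    X[mask] = np.nan
    return LabeledDataset(
        X=X, y=dataset.y.copy(), features=list(dataset.features),
        patient_ids=list(dataset.patient_ids),
        crp=None if dataset.crp is None else dataset.crp.copy(),
    )
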