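"""Prepare a raw clinical export: missingness filter, genotype one-hot
encoding, CRP median split, and class-wise nearest-neighbour imputation."""

import numpy as np
import pandas as pd

from rlsep import (
    LabeledDataset,
    encode_genotypes,
    filter_missingness,
    impute_nearest_neighbour,
    median_split,
)
from rlsep.datamodel import FeatureInfo

# a raw export: two phenotypic measurements, one genotyped site, CRP
raw = pd.DataFrame({
    "age":  [54.0, 61.0, np.nan, 47.0, 70.0, 58.0],
    "bmi":  [22.5, np.nan, 27.8, 24.1, 30.2, 26.0],
    "rs42": ["AA", "AG", "GG", None, "AG", "AA"],
    "crp":  [9.1, 2.2, 8.4, 1.5, 7.7, 3.0],
})

# 1. drop patients/features observed too rarely (none here at 0.5/0.5)
kept = filter_missingness(raw[["age", "bmi"]], 0.5, 0.5)
print(f"after filtering: {kept.shape[0]} patients, {kept.shape[1]} phenotypic features")

# 2. one indicator per observed genotype category
genetic, sites = encode_genotypes(raw[["rs42"]])
print(f"site rs42 -> {len(sites[0].categories)} indicators: {list(genetic.columns)}")

# 3. labels from the strict-above-median CRP split
y = median_split(raw["crp"].to_numpy())
print(f"labels (+1 = high CRP): {y.tolist()}")

# 4. class-wise nearest-neighbour imputation, blocks treated separately
X = np.column_stack([raw[["age", "bmi"]].to_numpy(), genetic.to_numpy()])
features = [FeatureInfo("age", "phenotypic"), FeatureInfo("bmi", "phenotypic")]
features += [FeatureInfo(c, "genetic", site="rs42") for c in genetic.columns]
ds = LabeledDataset(X=X, y=y, features=features, crp=raw["crp"].to_numpy())
complete = impute_nearest_neighbour(ds)
print(f"missing cells before: {int(np.isnan(X).sum())}, "
      f"after: {int(np.isnan(complete.X).sum())}")
print(complete.to_frame().round(2).to_string())
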