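"""Presence filtering, log2 transform and optional median-centering.

The presence filter keeps a protein iff it is detected in at least a
minimum fraction (default 70%) of the samples of at least one group
(default grouping: histotype). "At least 70%" is a strict fraction rule:
a 10-sample group needs >= 7 detected values. No imputation is performed
anywhere; downstream statistics handle missing cells by complete-case
analysis.

Median-centering is provided as an optional stand-in when the input has
not been normalized upstream; it is off by default in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data_io import AbundanceMatrix, SampleMetadata, ValidationError


@dataclass
class FilterReport:
    """Bookkeeping for one presence-filter run."""

    n_before: int
    n_after: int
    min_fraction: float
    grouping: str
    max_group_presence: pd.Series  # per input protein, best group's presence fraction

    def to_frame(self) -> pd.DataFrame:
        df = self.max_group_presence.rename("max_group_presence_fraction").to_frame()
        df.insert(0, "retained", df["max_group_presence_fraction"] >= self.min_fraction)
        df.index.name = "protein_id"
        return df.reset_index()


class GroupPresenceFilter(BaseEstimator):
    """Feature selector keeping proteins detected in >= ``min_fraction`` of
    some group's samples.

    sklearn-style: ``fit(X, y)`` with X = samples x proteins and y = group
    labels; ``transform`` drops the unselected columns. The
    matrix-container front end is :func:`filter_by_group_presence`.
    """

    def __init__(self, min_fraction: float = 0.7):
        self.min_fraction = min_fraction

    def fit(self, X, y):
        if not 0 <= self.min_fraction <= 1:
            raise ValueError("min_fraction must be in [0, 1]")
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y have different numbers of samples")
        fractions = []
        for g in pd.unique(y):
            members = X.loc[y == g]
            if members.shape[0] == 0:
                raise ValidationError(f"group {g!r} has no samples")
            fractions.append(members.notna().mean(axis=0))
        frac = pd.concat(fractions, axis=1)
        self.max_group_presence_ = frac.max(axis=1)
        if self.min_fraction == 0:
            # boundary convention: keep anything observed at least once
            support = self.max_group_presence_ > 0
        else:
            support = self.max_group_presence_ >= self.min_fraction
        self.support_ = support.to_numpy()
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        X = pd.DataFrame(X)
        return X.loc[:, self.support_]


def filter_by_group_presence(matrix: AbundanceMatrix, metadata: SampleMetadata,
                             grouping: str = "histotype",
                             min_fraction: float = 0.7,
                             ) -> tuple[AbundanceMatrix, FilterReport]:
    """Retain proteins detected in >= ``min_fraction`` of some group.

    Protein order is preserved. ``grouping`` names a metadata column
    (default histotype).
    """
    if grouping not in metadata.df.columns:
        raise ValueError(f"unknown grouping column {grouping!r}")
    labels = metadata.df.loc[matrix.sample_ids, grouping].to_numpy()
    sel = GroupPresenceFilter(min_fraction=min_fraction).fit(matrix.values.T, labels)
    keep = [p for p, k in zip(matrix.protein_ids, sel.support_) if k]
    report = FilterReport(
        n_before=matrix.n_proteins, n_after=len(keep), min_fraction=min_fraction,
        grouping=grouping,
        max_group_presence=pd.Series(sel.max_group_presence_.to_numpy(),
                                     index=matrix.values.index))
    return matrix.subset_proteins(keep), report


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log2-transform a raw-scale matrix; missing cells stay missing."""
    if matrix.scale != "raw":
        raise ValidationError("matrix is already on the log2 scale")
    vals = matrix.values.to_numpy()
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-positive intensity for protein {matrix.protein_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r}")
    out = pd.DataFrame(np.log2(vals), index=matrix.values.index,
                       columns=matrix.values.columns)
    return AbundanceMatrix(out, scale="log2", gene_symbols=matrix.gene_symbols,
                           descriptions=matrix.descriptions)


def median_center(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Shift each sample so its present-value median equals the grand
    median of the pre-centering sample medians. Idempotent."""
    if matrix.scale != "log2":
        raise ValidationError("median_center expects a log2-scale matrix")
    medians = matrix.values.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = medians.index[medians.isna()].tolist()
        raise ValidationError(f"samples with all values missing: {bad}")
    grand = float(np.median(medians))
    out = matrix.values - (medians - grand)
    return AbundanceMatrix(out, scale="log2", gene_symbols=matrix.gene_symbols,
                           descriptions=matrix.descriptions)
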