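"""Replicate quality control via pairwise Spearman rank correlation.

Replicates of the same accession x organ x stage cell should rank
metabolites almost identically even when absolute intensities drift, so
rank correlation is the natural agreement score. Zeros (non-detects) are
kept as valid values in the ranking — an analyte missing from one
replicate but abundant in another is exactly the kind of disagreement QC
should see — while NaN (not measured) entries are dropped pairwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Dataset


class InsufficientDataError(ValueError):
    """Fewer than 3 complete pairs: a rank correlation is meaningless."""


class UndefinedCorrelationError(ValueError):
    """A vector with zero rank variance has no defined correlation."""


def spearman(x, y) -> float:
    """Spearman rho between two abundance vectors, average ranks for ties.

    Missing entries (NaN) are removed pairwise; at least 3 complete pairs
    are required, and both vectors must have non-zero rank variance.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be equal-length 1-D")
    complete = ~(np.isnan(a) | np.isnan(b))
    a, b = a[complete], b[complete]
    if a.size < 3:
        raise InsufficientDataError(f"only {a.size} complete pairs; need >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise UndefinedCorrelationError("zero rank variance in one of the vectors")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


@dataclass
class ReplicateGroupQC:
    """Per-group replicate agreement: group key plus rho matrix over samples."""

    key: tuple
    correlations: pd.DataFrame  # symmetric, unit diagonal, indexed by sample_id


def replicate_correlation_matrices(
    dataset: Dataset,
    group_by: tuple[str, ...] = ("accession", "organ", "stage"),
) -> tuple[list[ReplicateGroupQC], list[tuple]]:
    """Pairwise Spearman matrices among replicates of each design cell.

    Returns (matrices, skipped) where ``skipped`` lists the group keys with
    fewer than 2 replicates (each also emits a warning).
    """
    results: list[ReplicateGroupQC] = []
    skipped: list[tuple] = []
    for key, meta in dataset.samples.groupby(list(group_by), sort=False):
        ids = list(meta.index)
        if len(ids) < 2:
            warnings.warn(f"group {key} has a single replicate; skipped", stacklevel=2)
            skipped.append(key)
            continue
        block = dataset.abundance[ids]
        mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
        for i, si in enumerate(ids):
            for sj in ids[i + 1 :]:
                rho = spearman(block[si].to_numpy(), block[sj].to_numpy())
                mat.loc[si, sj] = rho
                mat.loc[sj, si] = rho
        results.append(ReplicateGroupQC(key=key, correlations=mat))
    return results, skipped


def flag_outlier_replicates(
    matrices: list[ReplicateGroupQC],
    threshold: float = 0.7,
) -> list[tuple[tuple, str]]:
    """Flag replicates whose median correlation to co-replicates < threshold.

    The 0.7 default is a pragmatic screening cut, not a published value;
    tune it to the platform's replicate behaviour.
    """
    flags = []
    for group in matrices:
        mat = group.correlations
        for sid in mat.index:
            others = mat.loc[sid].drop(sid)
            if float(others.median()) < threshold:
                flags.append((group.key, sid))
    return flags


def scatter_pairs(dataset: Dataset, sample_i: str, sample_j: str) -> pd.DataFrame:
    """Jointly observed (x, y) abundances of two samples, in feature order.

    The replicate scatterplot data: one row per feature measured in both
    samples, columns (feature_id, x, y).
    """
    for sid in (sample_i, sample_j):
        if sid not in dataset.abundance.columns:
            raise KeyError(f"unknown sample id {sid!r}")
    x = dataset.abundance[sample_i]
    y = dataset.abundance[sample_j]
    keep = x.notna() & y.notna()
    return pd.DataFrame(
        {"feature_id": dataset.abundance.index[keep], "x": x[keep].to_numpy(), "y": y[keep].to_numpy()}
    ).reset_index(drop=True)
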