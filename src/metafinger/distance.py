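"""Weighted Manhattan dissimilarity between metabolite profiles.

For two samples with non-negative abundance vectors y_i and y_j the
dissimilarity is the mean, over features observed in at least one of the
two samples, of the per-feature term

    |y_ki - y_kj| / sqrt(y_ki^2 + y_kj^2)

The denominator estimates the standard deviation of the abundance
difference, so each feature contributes a value in [0, 1] regardless of
the magnitude of its abundance — a highly abundant lipid and a trace
alkaloid weigh the same. Consequences:

* D is bounded in [0, 1]; D = 0 iff the profiles are identical on the
  shared support, and D = 1 iff the two samples have completely disjoint
  constituents (every feature present in one is absent in the other).
* D is invariant under common multiplicative rescaling of both vectors
  (peak areas, relative abundances and absolute concentrations give the
  same D as long as one is a constant multiple of the other). Rescaling
  only ONE sample does not in general preserve D.

Features that are zero in both samples carry no information about their
difference and are excluded from the averaging count; a strict mode that
divides by the full feature count instead is available for comparison.
Missing (not-measured, NaN) entries are removed pairwise before anything
else, which is distinct from zeros (measured, not detected).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dataset import Dataset


class UndefinedDistanceError(ValueError):
    """Raised when two profiles share no informative feature."""


def weighted_manhattan(
    y_i,
    y_j,
    normalization: str = "shared",
) -> float:
    """Weighted Manhattan dissimilarity D in [0, 1] between two profiles.

    Parameters
    ----------
    y_i, y_j
        Equal-length non-negative abundance vectors; NaN marks a missing
        (not-measured) entry and is dropped pairwise.
    normalization
        "shared" (default) divides the summed per-feature terms by the
        number of features present in at least one sample; "all" divides
        by the total number of (pairwise-complete) features, which dilutes
        D below 1 for profiles that share absences.

    Raises
    ------
    UndefinedDistanceError
        If no feature is positive in either sample (D is 0/0).
    ValueError
        On negative input or length mismatch.
    """
    a = np.asarray(y_i, dtype=float)
    b = np.asarray(y_j, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be equal-length 1-D vectors")
    complete = ~(np.isnan(a) | np.isnan(b))
    a, b = a[complete], b[complete]
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("abundances must be non-negative")

    support = (a + b) > 0
    k_star = int(support.sum())
    if k_star == 0:
        raise UndefinedDistanceError(
            "both profiles are zero for every shared feature; D is undefined"
        )
    aa, bb = a[support], b[support]
    # hypot avoids under/overflow in sqrt(a^2 + b^2) for extreme magnitudes
    terms = np.abs(aa - bb) / np.hypot(aa, bb)
    if normalization == "shared":
        denom = k_star
    elif normalization == "all":
        denom = a.size
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return float(terms.sum() / denom)


def _pairwise_terms(values: np.ndarray, normalization: str) -> np.ndarray:
    """Vectorized all-pairs D over the columns of a (features x samples) array."""
    n = values.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        a = values[:, i][:, None]
        b = values[:, i + 1 :]
        complete = ~(np.isnan(a) | np.isnan(b))
        a_ = np.where(complete, a, 0.0)
        b_ = np.where(complete, b, 0.0)
        support = complete & ((a_ + b_) > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.abs(a_ - b_) / np.hypot(a_, b_)
        term[~support] = 0.0
        k_star = support.sum(axis=0).astype(float)
        denom = k_star if normalization == "shared" else complete.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = term.sum(axis=0) / denom
        d[k_star == 0] = np.nan
        out[i, i + 1 :] = d
        out[i + 1 :, i] = d
    return out


def distance_matrix(
    dataset: Dataset,
    normalization: str = "shared",
    **select,
) -> pd.DataFrame:
    """All-pairs weighted Manhattan distances over (optionally selected) samples.

    Returns a symmetric DataFrame with zero diagonal, indexed by sample id.
    Pairs for which D is undefined (no shared informative feature) are set
    to NaN with a warning rather than raising, so one pathological pair
    does not void a whole matrix.
    """
    if select:
        dataset = dataset.select(**select)
    if dataset.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    values = dataset.abundance.to_numpy(dtype=float)
    if np.any(values[~np.isnan(values)] < 0):
        raise ValueError("abundances must be non-negative")
    if normalization not in ("shared", "all"):
        raise ValueError(f"unknown normalization {normalization!r}")
    mat = _pairwise_terms(values, normalization)
    if np.isnan(mat).any():
        n_bad = int(np.isnan(mat).sum() // 2)
        warnings.warn(
            f"{n_bad} sample pair(s) share no informative feature; distances set to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    ids = dataset.abundance.columns
    return pd.DataFrame(mat, index=ids, columns=ids)
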