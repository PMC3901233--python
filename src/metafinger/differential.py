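"""Differential abundance: volcano coordinates, ratio panels, fingerprints.

Three views of between-group abundance change:

* :func:`volcano` — per-feature log2 ratio of group means (x-axis) against
  a Welch t-test p-value (y-axis) for one two-group contrast.
* :func:`ratio_panels` — one log2-ratio column per accession for a fixed
  organ contrast (e.g. cauline leaves vs flowers), all panels sharing a
  single recorded feature ordering so the graphs are directly comparable.
* :func:`pairwise_accession_fingerprints` — log2-ratio profiles for every
  ordered accession pair, all organs pooled, again on one shared ordering;
  the pattern of each profile is the accession's metabolomic fingerprint
  relative to another accession.

Zeros are common (non-detects), so ratios use a pseudocount; by default
half the smallest positive abundance in the dataset, which keeps ratios
finite while scaling with the data rather than with an arbitrary unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import Dataset


class DegenerateVarianceError(ValueError):
    """Both groups constant but unequal: the t statistic is infinite."""


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch unequal-variance t-test; returns (t, df, two-sided p).

    Uses the Welch-Satterthwaite degrees of freedom. By convention two
    constant groups with equal value give (t=0, p=1); constant but unequal
    groups raise :class:`DegenerateVarianceError`.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise DegenerateVarianceError("both groups constant with unequal means")
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    # guard against p rounding to exactly 0 in double precision
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return float(t), float(df), p


def resolve_pseudocount(dataset_or_values, pseudocount: float | None) -> float:
    """A fixed pseudocount, or half the smallest positive value if None."""
    if pseudocount is not None:
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        return float(pseudocount)
    values = (
        dataset_or_values.abundance.to_numpy(dtype=float)
        if isinstance(dataset_or_values, Dataset)
        else np.asarray(dataset_or_values, dtype=float)
    )
    positive = values[np.isfinite(values) & (values > 0)]
    if positive.size == 0:
        raise ValueError("dataset has no positive abundance; supply a pseudocount")
    return float(positive.min() / 2.0)


def _resolve_group(dataset: Dataset, selector) -> list[str]:
    """Turn a selector (sample-id list or metadata-equality dict) into ids."""
    if isinstance(selector, dict):
        return list(dataset.select(**selector).abundance.columns)
    ids = list(selector)
    unknown = [s for s in ids if s not in dataset.abundance.columns]
    if unknown:
        raise KeyError(f"unknown sample ids {unknown}")
    return ids


def volcano(
    dataset: Dataset,
    group_a,
    group_b,
    pseudocount: float | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Volcano coordinates for the contrast group_a vs group_b.

    Parameters
    ----------
    group_a, group_b
        Either lists of sample ids or metadata-equality dicts such as
        ``{"organ": "flowers"}``. The groups must be disjoint and each
        must contain at least 2 samples.
    pseudocount
        Added to both group means before the ratio; None (default) uses
        half the smallest positive value in the dataset.
    adjust
        If True, append Benjamini-Hochberg q-values (off by default; raw
        p-values are the primary y-axis).

    Returns
    -------
    DataFrame indexed by feature_id with columns mean_a, mean_b, ratio,
    log2_ratio, t, df, p, neg_log10_p (plus q if requested) and a boolean
    ``skipped`` column for features without enough observed values in both
    groups (their statistics are NaN).
    """
    ids_a = _resolve_group(dataset, group_a)
    ids_b = _resolve_group(dataset, group_b)
    overlap = set(ids_a) & set(ids_b)
    if overlap:
        raise ValueError(f"groups overlap on samples {sorted(overlap)}")
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each group needs at least 2 samples")

    block_a = dataset.abundance[ids_a]
    block_b = dataset.abundance[ids_b]
    c = resolve_pseudocount(dataset, pseudocount)

    rows = []
    for fid in dataset.abundance.index:
        xa = block_a.loc[fid].to_numpy(dtype=float)
        xb = block_b.loc[fid].to_numpy(dtype=float)
        xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
        if xa.size < 2 or xb.size < 2:
            rows.append((fid, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, True))
            continue
        mean_a, mean_b = float(xa.mean()), float(xb.mean())
        ratio = (mean_a + c) / (mean_b + c)
        log2_ratio = float(np.log2(ratio)) if ratio > 0 else np.nan
        try:
            t, df, p = welch_t(xa, xb)
        except DegenerateVarianceError:
            t, df, p = np.nan, np.nan, np.nan
        nlp = -np.log10(p) if np.isfinite(p) else np.nan
        rows.append((fid, mean_a, mean_b, ratio, log2_ratio, t, df, p, False))

    out = pd.DataFrame(
        rows,
        columns=["feature_id", "mean_a", "mean_b", "ratio", "log2_ratio", "t", "df", "p", "skipped"],
    ).set_index("feature_id")
    out["neg_log10_p"] = -np.log10(out["p"])
    if adjust:
        out["q"] = np.nan
        ok = out["p"].notna()
        if ok.any():
            out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; monotone in p, q >= p."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _group_means(dataset: Dataset, ids: list[str]) -> pd.Series:
    return dataset.abundance[ids].mean(axis=1, skipna=True)


def shared_feature_order(
    dataset: Dataset, log_ratio_table: pd.DataFrame
) -> list[str]:
    """Deterministic feature ordering shared across comparison panels.

    Sort keys: platform block, chemical class, mean log-ratio over all
    panels, feature id. Fixing one order across every panel is what makes
    a stack of ratio plots directly comparable by eye.
    """
    meta = dataset.features.loc[log_ratio_table.index]
    key = pd.DataFrame(
        {
            "platform": meta["platform"].astype(str),
            "chemical_class": meta["chemical_class"].astype(str).fillna(""),
            "mean_log_ratio": log_ratio_table.mean(axis=1, skipna=True).fillna(0.0),
        },
        index=log_ratio_table.index,
    )
    key["fid"] = key.index.astype(str)
    key = key.reset_index(drop=True)
    order = key.sort_values(["platform", "chemical_class", "mean_log_ratio", "fid"])
    return list(order["fid"])


@dataclass
class RatioPanels:
    """Panel-aligned log2 ratios: one column per panel, one shared row order."""

    log2_ratios: pd.DataFrame       # ordered features x panels
    ordering: list[str]             # the shared feature order, explicit
    pseudocount: float
    contrast: tuple[str, str]


def ratio_panels(
    dataset: Dataset,
    contrast: tuple[str, str],
    panel_by: str = "accession",
    pseudocount: float | None = None,
) -> RatioPanels:
    """Per-accession log2 ratio of one organ against another.

    For each panel value (accession, by default) computes
    log2((mean over organ_a samples + c) / (mean over organ_b samples + c))
    per feature. A panel missing one of the two organs yields an all-NaN
    column and a warning rather than an error.
    """
    organ_a, organ_b = contrast
    c = resolve_pseudocount(dataset, pseudocount)
    panels = sorted(set(dataset.samples[panel_by]))
    columns = {}
    for panel in panels:
        meta = dataset.samples[dataset.samples[panel_by] == panel]
        ids_a = list(meta.index[meta["organ"] == organ_a])
        ids_b = list(meta.index[meta["organ"] == organ_b])
        if not ids_a or not ids_b:
            warnings.warn(
                f"{panel_by}={panel!r} lacks organ {organ_a if not ids_a else organ_b!r}; "
                "panel column is NaN",
                stacklevel=2,
            )
            columns[panel] = pd.Series(np.nan, index=dataset.abundance.index)
            continue
        mean_a = _group_means(dataset, ids_a)
        mean_b = _group_means(dataset, ids_b)
        columns[panel] = np.log2((mean_a + c) / (mean_b + c))
    table = pd.DataFrame(columns)
    order = shared_feature_order(dataset, table)
    table = table.loc[order]
    return RatioPanels(log2_ratios=table, ordering=order, pseudocount=c, contrast=contrast)


@dataclass
class AccessionFingerprints:
    """Log2-ratio profile for every ordered accession pair, organs pooled."""

    log2_ratios: pd.DataFrame       # ordered features x (numerator, denominator) pairs
    ordering: list[str]
    pseudocount: float


def pairwise_accession_fingerprints(
    dataset: Dataset,
    pseudocount: float | None = None,
) -> AccessionFingerprints:
    """Fingerprint profiles: log2(accession a / accession b) for all ordered pairs.

    Pools every organ and replicate of an accession into one mean profile,
    then forms log2 ratios for all n(n-1) ordered pairs with a single
    pseudocount, so log-ratio(a, b) == -log-ratio(b, a) exactly. All
    profiles share one recorded feature ordering.
    """
    accessions = sorted(set(dataset.samples["accession"]))
    if len(accessions) < 2:
        raise ValueError("need at least 2 accessions")
    c = resolve_pseudocount(dataset, pseudocount)
    means = {
        a: _group_means(dataset, list(dataset.samples.index[dataset.samples["accession"] == a]))
        for a in accessions
    }
    columns = {}
    for a in accessions:
        for b in accessions:
            if a == b:
                continue
            columns[(a, b)] = np.log2((means[a] + c) / (means[b] + c))
    table = pd.DataFrame(columns)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["numerator", "denominator"])
    order = shared_feature_order(dataset, table)
    table = table.loc[order]
    return AccessionFingerprints(log2_ratios=table, ordering=order, pseudocount=c)
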