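"""Core dataset container and validation.

A dataset couples a wide abundance matrix (features x samples, non-negative
relative abundances) with a sample-metadata table and a feature-metadata
table. Zero and missing are distinct states: a zero means the platform
measured the feature in that sample and detected nothing, while a missing
cell (NaN) means the feature was not measured for that sample at all (for
example because platforms differ between samples). All axes are keyed by
id, never positional, so the matrix can never silently misalign with its
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

PLATFORMS = ("amino_acid", "surface_lipid", "fatty_acid", "non_targeted")
STAGES = ("young", "immature", "mature", "unspecified")

SAMPLE_COLUMNS = ("sample_id", "species", "accession", "organ", "stage", "replicate")
FEATURE_COLUMNS = (
    "feature_id",
    "platform",
    "chemical_class",
    "mass",
    "retention_time",
    "identified",
)


class DatasetError(Exception):
    """Base class for dataset-level failures."""


class ValidationError(DatasetError):
    """Raised when a dataset violates a structural invariant."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        lines = "; ".join(str(v) for v in violations[:10])
        more = "" if len(violations) <= 10 else f" (+{len(violations) - 10} more)"
        super().__init__(f"dataset validation failed: {lines}{more}")


class EmptySelectionError(DatasetError):
    """Raised when a sample predicate matches nothing."""


@dataclass(frozen=True)
class Violation:
    """One validation finding: machine-readable kind plus offending id."""

    kind: str
    message: str
    offending_id: str | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tail = f" [{self.offending_id}]" if self.offending_id else ""
        return f"{self.kind}: {self.message}{tail}"

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "message": self.message,
            "offending_id": self.offending_id,
        }


@dataclass
class Dataset:
    """Abundance matrix plus aligned sample and feature metadata.

    Attributes
    ----------
    abundance
        DataFrame of shape (n_features, n_samples); index = feature_id,
        columns = sample_id; values float, NaN marks not-measured.
    samples
        DataFrame indexed by sample_id with columns species, accession,
        organ, stage, replicate.
    features
        DataFrame indexed by feature_id with columns platform,
        chemical_class, mass, retention_time, identified.
    """

    abundance: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame

    @property
    def n_features(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]

    def validate(self) -> list[Violation]:
        return validate_dataset(self)

    def require_valid(self) -> "Dataset":
        violations = self.validate()
        if violations:
            raise ValidationError(violations)
        return self

    def select(self, predicate: Callable[[pd.Series], bool] | None = None, **equals) -> "Dataset":
        """Restrict the sample axis; the feature axis and all values are untouched.

        Samples can be chosen either by keyword equality on metadata columns
        (``select(organ="flowers")``) or by an arbitrary predicate applied to
        each metadata row. Order of the surviving samples is preserved.

        Raises
        ------
        EmptySelectionError
            If no sample matches.
        """
        mask = pd.Series(True, index=self.samples.index)
        for column, value in equals.items():
            if column not in self.samples.columns:
                raise KeyError(f"unknown sample metadata column: {column!r}")
            mask &= self.samples[column] == value
        if predicate is not None:
            mask &= self.samples.apply(predicate, axis=1).astype(bool)
        kept = self.samples.index[mask]
        if len(kept) == 0:
            raise EmptySelectionError(f"no samples match selection {equals or predicate}")
        return Dataset(
            abundance=self.abundance.loc[:, kept],
            samples=self.samples.loc[kept],
            features=self.features,
        )


def _duplicates(index: Iterable) -> list:
    seen, dups = set(), []
    for key in index:
        if key in seen and key not in dups:
            dups.append(key)
        seen.add(key)
    return dups


def validate_dataset(dataset: Dataset) -> list[Violation]:
    """Collect every structural violation; an empty list means valid.

    Checked: duplicate sample/feature ids, duplicate
    (accession, organ, stage, replicate) tuples, keys present in the matrix
    but absent from metadata (and vice versa), negative abundances, invalid
    platform or stage labels, non-positive mass, negative retention time.
    Pure function: never mutates and never raises on invalid data.
    """
    out: list[Violation] = []
    ab, samples, features = dataset.abundance, dataset.samples, dataset.features

    for sid in _duplicates(ab.columns):
        out.append(Violation("duplicate_sample", "duplicate sample id in matrix", str(sid)))
    for fid in _duplicates(ab.index):
        out.append(Violation("duplicate_feature", "duplicate feature id in matrix", str(fid)))
    for sid in _duplicates(samples.index):
        out.append(Violation("duplicate_sample", "duplicate sample id in metadata", str(sid)))
    for fid in _duplicates(features.index):
        out.append(Violation("duplicate_feature", "duplicate feature id in metadata", str(fid)))

    sample_meta = set(samples.index)
    feature_meta = set(features.index)
    for sid in ab.columns:
        if sid not in sample_meta:
            out.append(Violation("orphan_sample", "sample in matrix but not in metadata", str(sid)))
    for sid in samples.index:
        if sid not in set(ab.columns):
            out.append(Violation("orphan_sample", "sample in metadata but not in matrix", str(sid)))
    for fid in ab.index:
        if fid not in feature_meta:
            out.append(Violation("orphan_feature", "feature in matrix but not in metadata", str(fid)))
    for fid in features.index:
        if fid not in set(ab.index):
            out.append(Violation("orphan_feature", "feature in metadata but not in matrix", str(fid)))

    values = ab.to_numpy(dtype=float, copy=False)
    neg_rows, neg_cols = np.where(values < 0)
    for r, c in zip(neg_rows, neg_cols):
        out.append(
            Violation(
                "negative_value",
                f"abundance {values[r, c]} < 0 at feature {ab.index[r]!r}, sample {ab.columns[c]!r}",
                f"{ab.index[r]}/{ab.columns[c]}",
            )
        )

    if "platform" in features.columns:
        bad = features.index[~features["platform"].isin(PLATFORMS)]
        for fid in bad:
            out.append(Violation("invalid_platform", f"platform {features.loc[fid, 'platform']!r} not in {PLATFORMS}", str(fid)))
    if "mass" in features.columns:
        mass = pd.to_numeric(features["mass"], errors="coerce")
        for fid in features.index[mass.notna() & (mass <= 0)]:
            out.append(Violation("invalid_mass", "mass must be > 0 when present", str(fid)))
    if "retention_time" in features.columns:
        rt = pd.to_numeric(features["retention_time"], errors="coerce")
        for fid in features.index[rt.notna() & (rt < 0)]:
            out.append(Violation("invalid_retention_time", "retention time must be >= 0", str(fid)))

    if "stage" in samples.columns:
        bad = samples.index[~samples["stage"].isin(STAGES)]
        for sid in bad:
            out.append(Violation("invalid_stage", f"stage {samples.loc[sid, 'stage']!r} not in {STAGES}", str(sid)))
    design_cols = ["accession", "organ", "stage", "replicate"]
    if all(c in samples.columns for c in design_cols) and len(samples):
        dup_mask = samples.duplicated(subset=design_cols, keep=False)
        tuples_seen = set()
        for sid in samples.index[dup_mask]:
            key = tuple(samples.loc[sid, design_cols])
            if key in tuples_seen:
                out.append(
                    Violation(
                        "duplicate_design_cell",
                        f"(accession, organ, stage, replicate)={key} assigned to more than one sample",
                        str(sid),
                    )
                )
            tuples_seen.add(key)

    return out
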