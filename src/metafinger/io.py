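"""Delimited-text serialization of datasets.

Dialect: comma-separated UTF-8, "." decimal point. The matrix file has
feature ids in the first column and sample ids in the header row; an empty
cell encodes a missing (not-measured) value, which is distinct from an
explicit 0. Round-trips are lossless to full float precision (values are
written with repr-level precision).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (
    FEATURE_COLUMNS,
    SAMPLE_COLUMNS,
    Dataset,
    ValidationError,
    Violation,
    validate_dataset,
)

MATRIX_FILE = "abundance.csv"
SAMPLES_FILE = "samples.csv"
FEATURES_FILE = "features.csv"


def read_dataset(matrix_path, samples_path, features_path) -> Dataset:
    """Read and validate the three CSV files of a dataset.

    Empty matrix cells become NaN (missing), never zero. Raises
    :class:`ValidationError` listing every violation (mismatched keys,
    negative values, duplicates) if the triple is inconsistent.
    """
    abundance = pd.read_csv(matrix_path, index_col=0, float_precision="round_trip")
    abundance.index = abundance.index.astype(str)
    abundance.columns = abundance.columns.astype(str)
    abundance = abundance.astype(float)

    samples = pd.read_csv(samples_path, dtype={"sample_id": str})
    _require_columns(samples, SAMPLE_COLUMNS, samples_path)
    samples = samples.set_index("sample_id")
    samples["replicate"] = samples["replicate"].astype(int)

    features = pd.read_csv(features_path, dtype={"feature_id": str})
    _require_columns(features, FEATURE_COLUMNS, features_path)
    features = features.set_index("feature_id")
    features["identified"] = features["identified"].astype(bool)
    # chemical_class is an optional string; absent normalizes to ""
    features["chemical_class"] = features["chemical_class"].fillna("").astype(str)

    dataset = Dataset(abundance=abundance, samples=samples, features=features)
    violations = validate_dataset(dataset)
    if violations:
        raise ValidationError(violations)
    return dataset


def write_dataset(dataset: Dataset, out_dir) -> dict[str, Path]:
    """Write a validated dataset to ``out_dir`` as three CSV files.

    Returns the mapping of logical names ("matrix", "samples", "features")
    to the paths written. Re-reading with :func:`read_dataset` reproduces
    the dataset exactly.
    """
    dataset.require_valid()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    matrix_path = out_dir / MATRIX_FILE
    samples_path = out_dir / SAMPLES_FILE
    features_path = out_dir / FEATURES_FILE

    # float_format=None + repr-precision via %.17g keeps round-trips exact
    dataset.abundance.to_csv(matrix_path, float_format="%.17g", na_rep="")
    dataset.samples.reset_index().to_csv(samples_path, index=False)
    dataset.features.reset_index().to_csv(features_path, index=False, float_format="%.17g")
    return {"matrix": matrix_path, "samples": samples_path, "features": features_path}


def read_dataset_dir(directory) -> Dataset:
    """Read a dataset from a directory written by :func:`write_dataset`."""
    directory = Path(directory)
    return read_dataset(
        directory / MATRIX_FILE, directory / SAMPLES_FILE, directory / FEATURES_FILE
    )


def _require_columns(frame: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValidationError(
            [Violation("missing_column", f"{path}: missing column(s) {missing}")]
        )
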