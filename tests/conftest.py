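import numpy as np
import pandas as pd
import pytest

from metafinger import Dataset


def make_dataset(values, sample_meta=None, feature_meta=None):
    """Build a small keyed Dataset from a dict {sample_id: [values...]}."""
    abundance = pd.DataFrame(values, dtype=float)
    abundance.index = [f"f{i + 1}" for i in range(abundance.shape[0])]
    abundance.index.name = "feature_id"
    sample_ids = list(abundance.columns)
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "species": "testus testus",
                "accession": [sid.split("_")[0] for sid in sample_ids],
                "organ": "organ1",
                "stage": "unspecified",
                "replicate": [
                    int(sid.split("_r")[1]) if "_r" in sid else i + 1
                    for i, sid in enumerate(sample_ids)
                ],
            }
        ).set_index("sample_id")
    if feature_meta is None:
        feature_meta = pd.DataFrame(
            {
                "platform": "non_targeted",
                "chemical_class": "",
                "mass": np.nan,
                "retention_time": np.nan,
                "identified": False,
            },
            index=abundance.index,
        )
    return Dataset(abundance=abundance, samples=sample_meta, features=feature_meta)


@pytest.fixture
def tiny_dataset():
    """3 features x 4 samples (2 accessions x 2 replicates), with a zero and a NaN."""
    return make_dataset(
        {
            "acc1_r1": [1.0, 4.0, 0.0],
            "acc1_r2": [1.1, 4.2, 0.1],
            "acc2_r1": [8.0, 2.0, np.nan],
            "acc2_r2": [7.5, 2.1, 5.0],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
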