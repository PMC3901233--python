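"""Synthetic multi-accession, multi-organ metabolomics datasets.

The generator emulates a germplasm fingerprinting design: several plant
accessions, each sampled across organs with biological replicates, measured
on a mix of targeted platforms (amino acids, surface lipids, fatty acids)
and one non-targeted platform. Abundances follow a log-normal model with
additive effects on the log scale:

    Y[k, j] = s_j * exp(mu_k + alpha[g(a), k] + beta[o, k] + eps) * present

where mu_k is the feature baseline, alpha a shared effect for the
accession-group the accession belongs to, beta an organ effect, eps
replicate (technical) noise, s_j a per-sample multiplicative scale factor,
and `present` a Bernoulli constituent-presence indicator drawn once per
accession-group x organ cell. Dropout at the cell level (rather than per
replicate) makes "completely different constituents" between two samples
expressible, so the distance statistic's upper boundary of 1 is reachable
by construction. Every stochastic quantity is drawn from a single
numpy Generator seeded explicitly; the same seed reproduces the dataset
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataset import Dataset

#: Accession identifiers and provenance of the five-accession preset design.
PRESET_ACCESSIONS = (
    "PI 664873",
    "PI 664874",
    "PI 664875",
    "PI 664876",
    "PI 664889",
)

#: Accession-group structure of the preset: three North American accessions
#: form one group, one North American accession stands alone, and the
#: Eastern European accession (South Ossetia, Georgia) stands alone.
PRESET_GROUPS = {
    "PI 664873": "NA-core",
    "PI 664874": "NA-core",
    "PI 664876": "NA-core",
    "PI 664875": "NA-outlier",
    "PI 664889": "Georgia",
}

PRESET_ORGANS = (
    "shoots",
    "cauline leaves",
    "flowers",
    "vegetative organs of shoots",
    "stems",
)

PRESET_PLATFORM_COUNTS = {
    "amino_acid": 21,
    "surface_lipid": 119,
    "fatty_acid": 83,
    "non_targeted": 222,
}

_PLATFORM_PREFIX = {
    "amino_acid": "aa",
    "surface_lipid": "sl",
    "fatty_acid": "fa",
    "non_targeted": "nt",
}


class DegenerateDesignError(ValueError):
    """Raised when a design would emit zero features or zero samples."""


@dataclass
class SimulationDesign:
    """Parameters of the generative model; see the module docstring.

    All effect magnitudes are standard deviations on the natural-log scale,
    so e.g. group_effect_sd = 1.0 means typical between-group fold changes
    of about e^1 ~ 2.7x per feature.
    """

    accessions: tuple[str, ...]
    group_of_accession: dict[str, str]
    organs: tuple[str, ...]
    n_replicates: int
    platform_counts: dict[str, int]
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 1.5
    group_effect_sd: float = 1.0
    organ_effect_sd: float = 1.0
    replicate_cv: float = 0.25
    dropout_prob: float = 0.1
    scale_factor_range: tuple[float, float] = (0.8, 1.25)
    species: str = "Prunella vulgaris"

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must lie in [0, 1]")
        for name in ("baseline_log_sd", "group_effect_sd", "organ_effect_sd", "replicate_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.scale_factor_range
        if not 0 < lo <= hi:
            raise ValueError("scale_factor_range must satisfy 0 < lo <= hi")
        if any(c < 0 for c in self.platform_counts.values()):
            raise ValueError("platform counts must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_features(self) -> int:
        return sum(self.platform_counts.values())

    @property
    def n_samples(self) -> int:
        return len(self.accessions) * len(self.organs) * self.n_replicates

    def to_dict(self) -> dict:
        d = asdict(self)
        d["accessions"] = list(self.accessions)
        d["organs"] = list(self.organs)
        d["scale_factor_range"] = list(self.scale_factor_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationDesign":
        d = dict(d)
        d["accessions"] = tuple(d["accessions"])
        d["organs"] = tuple(d["organs"])
        d["scale_factor_range"] = tuple(d["scale_factor_range"])
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth behind a simulated dataset, for recovery tests."""

    group_of_accession: dict[str, str]
    group_of_sample: pd.Series           # sample_id -> accession-group label
    group_effects: pd.DataFrame          # features x groups, log scale
    organ_effects: pd.DataFrame          # features x organs, log scale
    baseline_log_means: pd.Series        # feature_id -> mu_k
    scale_factors: pd.Series             # sample_id -> s_j
    presence: pd.DataFrame               # features x "group||organ" boolean
    null_features: pd.Series | None = None  # feature_id -> bool (all-null designs)

    def to_dict(self) -> dict:
        return {
            "group_of_accession": dict(self.group_of_accession),
            "group_of_sample": self.group_of_sample.to_dict(),
            "group_effects": self.group_effects.to_dict(),
            "organ_effects": self.organ_effects.to_dict(),
            "baseline_log_means": self.baseline_log_means.to_dict(),
            "scale_factors": self.scale_factors.to_dict(),
            "presence": self.presence.astype(bool).to_dict(),
            "null_features": None if self.null_features is None else self.null_features.to_dict(),
        }


def prunella_preset(**overrides) -> SimulationDesign:
    """Design matching the five-accession selfheal fingerprinting study.

    Five accessions assigned to three groups, five aerial organs, five
    replicates per accession x organ, and platform blocks of 21 amino
    acids, 119 surface lipids, 83 fatty acids and 222 non-targeted
    features (445 features total). Keyword overrides replace any design
    field, e.g. ``prunella_preset(organs=("flowers",))``.
    """
    kwargs = dict(
        accessions=PRESET_ACCESSIONS,
        group_of_accession=dict(PRESET_GROUPS),
        organs=PRESET_ORGANS,
        n_replicates=5,
        platform_counts=dict(PRESET_PLATFORM_COUNTS),
    )
    kwargs.update(overrides)
    return SimulationDesign(**kwargs)


def _feature_table(platform_counts: dict[str, int]) -> pd.DataFrame:
    rows = []
    for platform, count in platform_counts.items():
        prefix = _PLATFORM_PREFIX.get(platform, platform[:2])
        for i in range(count):
            rows.append(
                {
                    "feature_id": f"{prefix}{i + 1:04d}",
                    "platform": platform,
                    "chemical_class": "",
                    "mass": np.nan,
                    "retention_time": np.nan,
                    # roughly one third of features carry identifications
                    # on real mixed-platform designs; targeted platforms
                    # are the identified ones
                    "identified": platform != "non_targeted",
                }
            )
    return pd.DataFrame(rows).set_index("feature_id")


def simulate_dataset(design: SimulationDesign, seed: int) -> tuple[Dataset, TruthRecord]:
    """Draw one dataset (and its ground truth) from the generative model."""
    if design.n_features == 0 or design.n_samples == 0:
        raise DegenerateDesignError("design emits zero features or zero samples")

    rng = np.random.default_rng(seed)
    features = _feature_table(design.platform_counts)
    feature_ids = features.index
    n_feat = len(feature_ids)

    groups = sorted(set(design.group_of_accession.values()))
    organs = list(design.organs)

    mu = pd.Series(
        rng.normal(design.baseline_log_mean, design.baseline_log_sd, n_feat),
        index=feature_ids,
        name="baseline_log_mean",
    )
    alpha = pd.DataFrame(
        rng.normal(0.0, design.group_effect_sd, (n_feat, len(groups))),
        index=feature_ids,
        columns=groups,
    )
    beta = pd.DataFrame(
        rng.normal(0.0, design.organ_effect_sd, (n_feat, len(organs))),
        index=feature_ids,
        columns=organs,
    )
    presence = pd.DataFrame(
        rng.random((n_feat, len(groups) * len(organs))) >= design.dropout_prob,
        index=feature_ids,
        columns=[f"{g}||{o}" for g in groups for o in organs],
    )

    sample_rows = []
    columns = {}
    scale = {}
    group_of_sample = {}
    for accession in design.accessions:
        group = design.group_of_accession[accession]
        for organ in organs:
            cell_presence = presence[f"{group}||{organ}"].to_numpy()
            for rep in range(1, design.n_replicates + 1):
                sid = f"{accession.replace(' ', '')}_{organ.replace(' ', '-')}_r{rep}"
                s_j = rng.uniform(*design.scale_factor_range)
                eps = rng.normal(0.0, design.replicate_cv, n_feat)
                log_y = mu.to_numpy() + alpha[group].to_numpy() + beta[organ].to_numpy() + eps
                columns[sid] = s_j * np.exp(log_y) * cell_presence
                scale[sid] = s_j
                group_of_sample[sid] = group
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "species": design.species,
                        "accession": accession,
                        "organ": organ,
                        "stage": "unspecified",
                        "replicate": rep,
                    }
                )

    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    abundance = pd.DataFrame(columns, index=feature_ids)
    dataset = Dataset(abundance=abundance, samples=samples, features=features)
    truth = TruthRecord(
        group_of_accession=dict(design.group_of_accession),
        group_of_sample=pd.Series(group_of_sample, name="group"),
        group_effects=alpha,
        organ_effects=beta,
        baseline_log_means=mu,
        scale_factors=pd.Series(scale, name="scale_factor"),
        presence=presence,
    )
    return dataset, truth


def null_two_group_dataset(
    n_features: int,
    n_per_group: int,
    seed: int,
    baseline_log_mean: float = 8.0,
    baseline_log_sd: float = 1.5,
    replicate_cv: float = 0.25,
) -> tuple[Dataset, TruthRecord]:
    """Two sample groups drawn from one log-normal: every feature is null.

    Used to calibrate the type-I error of the differential tests. Both
    groups ("A" and "B", n_per_group samples each) share the identical
    per-feature distribution; the truth record marks all features null.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (t-test undefined otherwise)")
    if n_features < 1:
        raise DegenerateDesignError("n_features must be >= 1")

    rng = np.random.default_rng(seed)
    feature_ids = pd.Index([f"nt{i + 1:04d}" for i in range(n_features)], name="feature_id")
    mu = rng.normal(baseline_log_mean, baseline_log_sd, n_features)

    columns = {}
    sample_rows = []
    for group in ("A", "B"):
        for rep in range(1, n_per_group + 1):
            sid = f"{group}_r{rep}"
            columns[sid] = np.exp(mu + rng.normal(0.0, replicate_cv, n_features))
            sample_rows.append(
                {
                    "sample_id": sid,
                    "species": "synthetic",
                    "accession": group,
                    "organ": "organ1",
                    "stage": "unspecified",
                    "replicate": rep,
                }
            )

    features = pd.DataFrame(
        {
            "platform": "non_targeted",
            "chemical_class": "",
            "mass": np.nan,
            "retention_time": np.nan,
            "identified": False,
        },
        index=feature_ids,
    )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    abundance = pd.DataFrame(columns, index=feature_ids)
    dataset = Dataset(abundance=abundance, samples=samples, features=features)

    groups = pd.Series({s: samples.loc[s, "accession"] for s in samples.index}, name="group")
    truth = TruthRecord(
        group_of_accession={"A": "A", "B": "B"},
        group_of_sample=groups,
        group_effects=pd.DataFrame(0.0, index=feature_ids, columns=["A", "B"]),
        organ_effects=pd.DataFrame(0.0, index=feature_ids, columns=["organ1"]),
        baseline_log_means=pd.Series(mu, index=feature_ids, name="baseline_log_mean"),
        scale_factors=pd.Series(1.0, index=samples.index, name="scale_factor"),
        presence=pd.DataFrame(True, index=feature_ids, columns=["A||organ1", "B||organ1"]),
        null_features=pd.Series(True, index=feature_ids, name="is_null"),
    )
    return dataset, truth


def spiked_two_group_dataset(
    n_features: int,
    n_per_group: int,
    fold: float,
    fraction_spiked: float = 0.5,
    seed: int = 0,
    **null_kwargs,
) -> tuple[Dataset, TruthRecord]:
    """Null two-group dataset with a planted fold-change in group A.

    A deterministic subset (the first ``fraction_spiked`` of features) is
    multiplied by ``fold`` in every group-A sample; the truth record marks
    the remaining features null. Used for power and ratio-recovery checks:
    spiked features have a true group-A/group-B abundance ratio of exactly
    ``fold``.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if not 0.0 <= fraction_spiked <= 1.0:
        raise ValueError("fraction_spiked must lie in [0, 1]")
    dataset, truth = null_two_group_dataset(n_features, n_per_group, seed, **null_kwargs)
    n_spiked = int(round(fraction_spiked * n_features))
    spiked = dataset.abundance.index[:n_spiked]
    ids_a = dataset.samples.index[dataset.samples["accession"] == "A"]
    dataset.abundance.loc[spiked, ids_a] *= fold
    truth.null_features = pd.Series(True, index=dataset.abundance.index, name="is_null")
    truth.null_features.loc[spiked] = False
    truth.group_effects.loc[spiked, "A"] = float(np.log(fold))
    return dataset, truth
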