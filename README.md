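# metafinger

Metabolite fingerprinting for multi-accession, multi-organ plant
metabolomics designs.

Germplasm collections hold many accessions of the same species whose
specialized-metabolite chemistry can differ substantially — differences
that matter for anyone selecting material for bioactivity assays or
standardizing a medicinal herb. Given a wide table of relative metabolite
abundances (features × samples) from mixed targeted/non-targeted MS
platforms, `metafinger` answers: do replicates agree, which metabolites
differ between organs or accessions, and how do whole-sample fingerprints
group by genetic provenance?

The package provides:

* **Replicate QC** — pairwise Spearman rank correlations among replicates
  of each accession × organ × stage cell, with outlier flagging.
* **Differential abundance** — volcano coordinates (log₂ ratio of group
  means vs Welch t-test p-value), per-accession organ-contrast ratio
  panels on a shared metabolite ordering, and all-pairs accession
  fingerprint profiles; optional Benjamini–Hochberg adjustment.
* **Fingerprint dissimilarity** — the weighted Manhattan distance between
  samples *i* and *j*,

  ```
  D_ij = (1/K*) Σ_k |Y_ki − Y_kj| / √(Y_ki² + Y_kj²)
  ```

  where Y_ki is the abundance of metabolite *k* in sample *i* and K*
  counts the features present in at least one of the two samples. Each
  feature contributes a term in [0, 1] regardless of its magnitude, so
  D_ij ∈ [0, 1], equals 0 for identical profiles, equals 1 for samples
  with completely disjoint constituents, and is invariant to common
  multiplicative rescaling of the data (peak areas, relative abundances
  and concentrations give the same D).
* **Ordination and clustering** — classical (Torgerson) MDS of the
  distance matrix, max-standardization of abundances (each feature
  divided by its maximum over the selected samples), K-means and
  agglomerative hierarchical clustering, and the adjusted Rand index for
  partition comparison.
* **A synthetic-data generator** that emulates the five-accession,
  five-organ selfheal (*Prunella vulgaris*) design — platform blocks of
  21 amino acids, 119 surface lipids, 83 fatty acids and 222 non-targeted
  features; three accession groups; replicate noise, constituent dropout
  and per-sample scale factors — with a full ground-truth record for
  recovery testing.

## Worked example

Simulate one organ of the five-accession design (25 samples), compute the
distance matrix, embed it, and cluster:

```python
import numpy as np
import metafinger as mf
from scipy.spatial.distance import pdist, squareform

design = mf.prunella_preset(organs=("vegetative organs of shoots",))
ds, truth = mf.simulate_dataset(design, seed=7)
print(ds.abundance.shape)                      # (445, 25)

D = mf.distance_matrix(ds)                     # 25x25, in [0, 1]
res = mf.classical_mds(D, dims=2)
coords = res.coordinates

acc = ds.samples.loc[coords.index, "accession"].to_numpy()
emb = squareform(pdist(coords.to_numpy()))
same = acc[:, None] == acc[None, :]
off = ~np.eye(25, dtype=bool)
print(round(emb[same & off].mean(), 4))        # 0.0125
print(round(emb[~same].mean(), 4))             # 0.4245

std = mf.standardize_max(ds)
h = mf.hierarchical_cluster(std, k=3)
print(mf.adjusted_rand_index(
    h.assignments, truth.group_of_sample.loc[std.columns]))  # 1.0
```

Off-diagonal distances here span 0.179–0.649; replicates of the same
accession sit ~30× closer together in the 2-D embedding than samples of
different accessions (0.0125 vs 0.4245), and cutting the hierarchical
tree at k = 3 recovers the three planted accession groups exactly
(ARI = 1.0, cluster sizes 5/15/5 — one lone accession, the three-member
group, and the second lone accession).

The same pipeline is scriptable from the shell:

```sh
metafinger simulate --seed 7 --out data/
metafinger qc data/ --out qc/
metafinger distance data/ --organ "vegetative organs of shoots" --out distance.csv
metafinger mds distance.csv --out coords.csv
metafinger cluster data/ --k 3 --organ "vegetative organs of shoots" --out clusters.csv
```

or as a single configured run with a provenance manifest:
`metafinger run pipeline.yaml`.

## Data model

A dataset is three CSV files: the abundance matrix (first column
`feature_id`, header row of `sample_id`s; empty cell = not measured,
`0` = measured but not detected), a samples table
(`sample_id,species,accession,organ,stage,replicate`) and a features
table (`feature_id,platform,chemical_class,mass,retention_time,identified`).
See `docs/methods.md` for the statistical model, parameter choices and
limitations.
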