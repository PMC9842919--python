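# bundlekit

Tools for studying how intracranial volume (ICV), sex, and age relate to
white-matter microstructure in diffusion-tensor imaging (DTI), built for
population-scale cohort analyses. The package covers the full chain:

* **Diffusion metrics** — voxelwise log-linear tensor fits and the scalar
  indices FA, MD, AD, RD; a registration-free skeleton build/projection
  (maximum FA perpendicular to the tract-center skeleton, threshold
  FA ≥ 0.2); scan-to-scan RMS head motion from volume affines.
* **Bundle clustering** — multi-subject streamline segmentation: resample to
  25 points, pool subjects, partition into random subsets, Ward-cluster each
  subset on flip-invariant pairwise distances, match labels across subsets by
  optimal assignment on cluster representatives, and repeat with fresh
  partitions to form a consensus label with a per-streamline stability score.
* **Tract metrics** — rasterize tract streamlines to voxel ROIs; tract volume
  = voxel count × voxel volume; tract FA = mean FA over the ROI.
* **Cohort statistics** — maximum-cardinality ICV-matched man/woman pairs
  (|ΔICV| < 10 ml), mean-centered multiple regression `index ~ ICV + age +
  sex`, Freedman–Lane permutation inference with max-statistic or TFCE
  family-wise correction, Benjamini–Hochberg correction within variable
  families, Cohen's *d* and partial η² effect sizes.
* **Synthetic data** — geometric streamline phantoms for 8 tract archetypes
  (CC, CG, SLF, ILF, IFO, CST, OR, UNC), simulated single-shell DWI signal
  with Rician noise, and covariate cohorts whose tract FA follows the forward
  model

  `FA = β₀ + β_ICV·(ICV − ICV̄) + β_age·(age − agē) + β_sex·1[female] + ε`

  with sex-specific ICV distributions (men 1667.9 ± 120.2 ml, women
  1455.9 ± 115.8 ml), ages uniform on 50–66 years, and ε ~ N(0, σ).

Everything is seeded and deterministic; the whole study replays end to end on
synthetic data with no downloads.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from bundlekit import clustering, stats, synthetic

# 1. Cluster a 3-subject, 8-bundle phantom and check recovery
pooled, truth = [], []
for s in range(3):
    sls, labels = synthetic.default_phantom(n_streamlines=200, radius=2.0, seed=100 + s)
    pooled.extend(sls); truth.append(labels)
seg = clustering.consensus_cluster(pooled, k=8, subset_size=500,
                                   n_repetitions=10, seed=0)
print("ARI:", adjusted_rand_score(np.concatenate(truth), seg.labels))
print("mean stability:", seg.stability.mean())

# 2. Generate a cohort and recover the generating coefficients
spec = synthetic.CohortSpec(n_men=1000, n_women=1000, seed=31)
table = synthetic.generate_cohort(spec)
fit = stats.fit_glm(table["CC_fa"].to_numpy(), stats.build_design(table))
print(fit.summary_frame().loc[["icv", "age", "sex"], ["beta", "p"]])

# 3. ICV-matched pairs and the group t before/after matching
men, women = table[table.sex == "M"], table[table.sex == "F"]
pairs = stats.match_by_icv(men, women, tolerance=10.0)
print("pairs:", len(pairs),
      "unmatched t:", round(stats.two_sample_t(men.icv_ml.to_numpy(),
                                               women.icv_ml.to_numpy()), 1))
```

Output:

```
ARI: 1.0
mean stability: 1.0
         beta              p
icv  0.000050  1.854623e-117
age -0.000305   8.372263e-09
sex  0.003852   5.664292e-09
pairs: 390 unmatched t: 40.0
```

The consensus segmentation recovers the ground-truth bundles exactly; the
fitted betas sit on the generating values (β_ICV = 4.7 × 10⁻⁵ FA/ml,
β_age = −3.0 × 10⁻⁴ FA/yr, sex offset +0.004 FA for women); and the
unmatched ICV *t* of 40 at n = 2000 collapses to near zero within the 390
matched pairs.

The full study — cohort, phantoms, segmentation, tract extraction, matching,
regression + permutation report — runs from one JSON config:

```bash
bundlekit run --config study.json     # see StudyConfig.desk_scale()
dti-metrics fit --dwi dwi.nii.gz --bval dwi.bval --bvec dwi.bvec --out-prefix sub01
```

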