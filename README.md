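# radhist

Radiomics-based classification of tumor histology, packaged as a tested,
reusable pipeline.

Non-small cell lung cancer splits into histologic subtypes — chiefly
adenocarcinoma and squamous cell carcinoma — that call for different
therapies, but subtype is normally established by invasive biopsy.
Radiomics offers a non-invasive alternative: extract hundreds of
quantitative features from the segmented tumor on a routine CT scan and
learn a classifier that predicts the subtype.  `radhist` implements that
workflow end to end for methodologists who want to study *how* such a
classifier should be built: which of the many candidate feature-selection
methods and classifiers hold up on an independent validation cohort.

## What the pipeline computes

1. **Feature extraction** — 440 3D radiomic features per tumor:
   15 first-order intensity statistics, 8 shape descriptors, 22 gray-level
   co-occurrence (GLCM) and 11 gray-level run-length (GLRLM) texture
   features on the original image, and the 48 intensity+texture features
   recomputed on each of the 8 subbands of an undecimated coiflet-1 wavelet
   decomposition (56 + 8 × 48 = 440).  Reads NIfTI and NRRD volumes with
   aligned 0/1 masks.
2. **Univariate screen** — per-feature AUC (Mann–Whitney,
   orientation-free), permutation significance (1000 relabelings, add-one
   corrected) and Benjamini–Hochberg control at 5% FDR.
3. **Stage-1 selection** — correlation-based redundancy elimination: every
   feature pair with |Pearson r| > M (default M = 0.8) loses the member with
   the larger column-wise mean absolute correlation C; afterwards no
   surviving pair exceeds M (asserted on every run).
4. **Stage-2 selection** — 24 filter ranking methods: information-theoretic
   impurity gains on discretized values (InfGain, GainRatio, Gini, MDL,
   DKM, Accuracy and equal-column-weight variants), distribution-distance
   scores (Hellinger/Euclidean against uniform), and the Relief family
   (classic Relief plus ReliefF with equal-k, exponential-rank, best-k,
   inverse-distance, squared-distance, merit, class-weighting, pooled-miss
   and sampled-reference variants).
5. **Classifiers** — Gaussian naive Bayes, random forest (100 trees,
   √p features per split) and 9-nearest-neighbors, each emitting a
   positive-class probability score on features standardized by
   training-cohort statistics only.
6. **Benchmark** — the full 24 methods × 9 selection sizes (5, 10, …, 45)
   × 3 classifiers grid of validation AUCs (648 cells), with per-classifier
   median ± SD summaries, best/worst methods, Youden-optimal cutoff and
   sensitivity/specificity/PPV/NPV/accuracy of the best model.

Because no public imaging cohort ships with the package, a first-class
synthetic-data module generates the study conditions: two-class feature
tables with heavy block collinearity (latent-factor blocks, within-block
r = 0.95), planted informative features (Cohen's d = 1.2), imbalanced
cohorts (75/25 train, 41/59 validation, positive class = adenocarcinoma),
and labeled 3D tumor volumes with class-dependent intensity texture.

## Worked example

```python
from radhist import (paper_like_table_config, simulate_feature_tables,
                     eliminate_correlated, rank_features, ReliefFConfig,
                     select_top, train_classifier, positive_scores, roc_result)
from radhist.io import split_xy

cfg = paper_like_table_config(seed=1)          # 440 features, 200/150 cohorts
train, valid = simulate_feature_tables(cfg)
X, y = split_xy(train); Xv, yv = split_xy(valid)

report = eliminate_correlated(X, threshold=0.8)
print(f"redundancy filter: {X.shape[1]} -> {len(report.retained)} features "
      f"(mean |r| {report.mean_abs_corr_before:.3f} -> {report.mean_abs_corr_after:.3f})")

ranking = rank_features(X[report.retained], y, "ReliefFdistance",
                        relieff=ReliefFConfig(k=10, seed=1))
top5 = select_top(ranking, 5)
model = train_classifier(X[top5], y, "naive_bayes", seed=1)
result = roc_result(positive_scores(model, Xv[top5]), yv, n_iter=1000, seed=1)
print(f"validation AUC {result.auc:.3f} (95% CI {result.ci_low:.3f}-{result.ci_high:.3f}, "
      f"permutation p = {result.p_perm:.2e})")
```

prints

```
redundancy filter: 440 -> 67 features (mean |r| 0.073 -> 0.054)
validation AUC 0.971 (95% CI 0.939-1.000, permutation p = 9.99e-04)
```

The filter collapses each collinear block to a single survivor (440 → 67);
ReliefFdistance puts the five planted informative features at the top; and
naive Bayes on those five generalizes to the distribution-shifted
validation cohort with AUC 0.97 (the permutation p is at its add-one floor
1/1001).  The same workflow runs from the shell:

```bash
radhist run --seed 1 --out study/        # full 648-cell benchmark + manifest
radhist simulate --seed 1 --out cohorts/
radhist filter --table cohorts/train.tsv --corr-threshold 0.8 --out filtered.tsv
radhist rank --table filtered.tsv --method ReliefFdistance --size 5 --out top.tsv
```

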