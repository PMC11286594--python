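# graftaxis

Serum–allograft axis discovery for kidney transplant cohorts.

After kidney transplantation, the state of the graft is usually read from
an invasive biopsy, while blood markers like creatinine react late.
`graftaxis` implements, as a reusable and tested library, an analysis that
links the two compartments directly: it derives coregulated gene networks
from the bulk biopsy transcriptome, correlates each network's per-sample
activity with a time-matched serum protein panel, pools metabolic (MB) and
inflammatory (INF) networks into two opposing axes, and extracts serum
protein signatures — HEALTH (MB up, INF down) and INJURY (MB down, INF up)
— that can be validated in cohorts where only serum was measured. It is
aimed at translational nephrology and systems-immunology groups working
with matched biopsy RNA-seq and targeted serum proteomics (NPX-scale
panels).

## Method

Given a gene × sample matrix of normalized counts *X* (median-of-ratios
size factors are built in for raw counts), the network step

1. ranks genes by coefficient of variation CV = s/μ and keeps the top
   *m* (≈2,000 by default),
2. z-scores each gene across samples,
3. embeds the genes in 2-D with t-SNE (samples are the feature
   dimensions) and
4. calls *k* networks by k-means on the embedding (fixed *k*, or a
   silhouette scan over a grid).

A network's activity in sample *j* is the mean z-score of its member
genes. Activities are correlated against every serum protein with
Spearman's ρ (two-sided t-approximation p-values, pairwise deletion of
missing values); rows and columns are ordered by hierarchical clustering
with distance 1 − ρ and complete linkage. Axis activity pools all genes
of an axis's member networks (gene-weighted). A protein joins a
directional category when |ρ| > 0.6 and p < 0.05 against that axis; the
top 10 by |ρ| form the signature. Validation requires the signature's
mean pairwise ρ (intrasignature correlation) to exceed every one of 10
random 10-protein control sets and its score (mean NPX) to associate
with kidney function (eGFR, creatinine).

Cross-cohort reproducibility is measured on the genes that are variable
in both cohorts: for each network of cohort A, the fraction of its common
genes falling in each network of cohort B; a network reproduces when
≥ 80% land in a single counterpart.

A bundled synthetic-cohort generator provides ground truth for all of
this: gene modules driven by latent per-sample factors, MB/INF factors
anti-correlated, proteins coupled to the factors at exact Spearman
targets via a Gaussian copula (Pearson parameter 2·sin(πρ/6)), and eGFR
coupled to the same factors.

## Worked example

```sh
python examples/02_call_networks.py
```

```
selected 2000 variable genes (CV threshold 0.395)
called 15 networks; sizes: [139, 138, 136, 135, 135, 134, 134, 133, 132, 131, 131, 131, 131, 131, 129]
adjusted Rand index vs planted modules: 0.988
```

The reference scenario (15 samples, 15 planted modules of 130 genes plus
650 background genes, 159 proteins) is generated, the 2,000 most variable
genes are embedded and clustered, and the recovered networks are compared
with the planted modules: an adjusted Rand index of 0.988 means the
partition is recovered almost exactly. Continuing with the serum layer
(`examples/04_serum_axes.py`, at n=200):

```
INJURY top-10: P001, P002, P003, P004, P005, P008, P007, P006, P009, P010
planted INJURY-like proteins recovered: 10/10
```

All ten proteins planted with MB-down/INF-up couplings (0.9 → 0.7) are
recovered from the 159-protein panel, in near-coupling order. Validation
(`examples/05_validate_signature.py`) shows the signature's
intrasignature correlation (top-3: 0.881) exceeding every random-set
control (max 0.048), and the expected directional associations with
kidney function.

The command-line interface exposes the same stages
(`graftaxis simulate|networks|compare|axes|validate|run`); see
`graftaxis --help`.

## Scope

The package starts from expression and protein matrices as delimited
text. Read alignment and quantification, functional term enrichment (axis
membership is an input), assay chemistry and histological scoring are out
of scope.
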