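# plscog

Connectome–cognition mapping with partial least squares (PLS) correlation.

`plscog` is for researchers who have per-subject brain connectivity —
hemodynamic (BOLD-fMRI) or metabolic (FDG-fPET) correlation matrices over a
fixed parcellation — and a battery of cognitive scores, and who want to know
which multivariate pattern of connections co-varies with which pattern of
cognitive performance, whether that pattern is significant, which individual
loadings are reliable, and how two imaging modalities differ in the cognition
they express.

## The method

Let **X** (subjects × edges) hold the vectorized upper triangles of each
subject's region-by-region Pearson correlation matrix (82 regions → 3,321
edges) and **Y** (subjects × variables) the cognitive scores. Both blocks are
z-scored column-wise and the cross-block correlation matrix

&nbsp;&nbsp;&nbsp;&nbsp;**R** = **X**ᵀ**Y** / (n − 1)

is decomposed by SVD, **R** = **U S V**ᵀ. Each latent variable (LV) pairs a
brain salience **u**ₖ, a behavior salience **v**ₖ and a singular value sₖ;
sₖ²/Σⱼsⱼ² is the fraction of cross-block covariance the LV explains. Subject
scores are **Lx** = **XU** and **Ly** = **YV**, and *loadings* — the Pearson
correlations between original columns and scores — are the interpreted
quantities. Significance of each LV comes from a permutation test on the
singular values (re-pairing behavior rows with brain rows); reliability of
each loading comes from bootstrap resampling of subjects, with percentile
confidence intervals. Cross-modality agreement is quantified by the cosine of
the two modalities' saliences, a region-by-region correlation of their
loading matrices, and lobe attribution of top-percentile edges.

Because real multimodal MR-PET data cannot ship with a package, `plscog`
includes a synthetic-data module that plants a known rank-k latent
brain–behavior covariance (plus ROI time series with an fPET-like
accumulation trend), so every stage can be validated against ground truth.

## Worked example

```python
from plscog import (PLSCorrelation, generate_latent_dataset,
                    random_ground_truth, salience_cosine)

truth = random_ground_truth(n_subjects=26, n_regions=15, n_variables=13,
                            effect=3.0, seed=7)
data = generate_latent_dataset(truth)

model = PLSCorrelation(data.edges, data.cognition)
res = model.fit()
res.permutation_test(n_iterations=5000, seed=11)
res.bootstrap_loadings(n_iterations=5000, seed=11)
print(res.summary(0))
```

```
PLS correlation results
==========================================================
subjects: 26   edges: 105   variables: 13   LVs: 13
LV 0: singular value = 5.0026, covariance explained = 40.25%
permutation P = 0.0002 (significant at alpha=0.05)
----------------------------------------------------------
variable                      loading            95% CI rel.
cog_01                          0.319     [-0.26, 0.73]
cog_02                         -0.209     [-0.67, 0.48]
cog_03                         -0.683    [-0.86, -0.18]    *
...
cog_08                          0.861      [0.24, 0.95]    *
```

The first latent variable explains 40.25% of the brain–cognition covariance
and survives permutation testing (P = 0.0002, 5,000 iterations). Starred
variables have bootstrap CIs excluding zero: they contribute reliably to the
latent pattern. The fitted brain salience aligns with the planted one at
|cos| = 0.647 — with 26 subjects and 105 edges the edge-level pattern is
recovered only partially, which is exactly the small-sample behavior the
synthetic module lets you quantify.

A shell interface mirrors the library:

```bash
plscog simulate --subjects 26 --regions 82 --variables 13 --effect 3 --seed 7 --out sim/
plscog pls --brain sim/edges.csv --cognition sim/cognition.tsv \
       --metadata sim/variables.tsv --permutations 5000 --bootstraps 5000 \
       --seed 11 --out pls_out/
```

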