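# Methods

## Model

`plscog` implements PLS correlation (PLSC) between a brain-connectivity
block and a cognition block. For n subjects, X (n × p) holds edge-level
connectivity (upper triangle of each subject's region-by-region Pearson
matrix, strict row-major order, i < j, 0-based internally; serialized files
label regions by name) and Y (n × q) holds cognitive outcome variables.
Both are z-scored column-wise with the sample SD (n − 1). The cross-block
matrix R = XᵀY/(n − 1) — each entry the Pearson r of one edge with one
variable — is decomposed by thin SVD, R = USVᵀ, giving min(p, q) latent
variables. Scores are Lx = XU, Ly = YV; loadings are Pearson correlations
of original columns with scores. PLSC assumes linear brain–behavior
coupling and exchangeable subjects; it makes no distributional assumption
beyond what the resampling inference supplies.

Assumed preprocessing contract: connectivity matrices are symmetric with
unit diagonal, built from ≥ 3 timepoint series with no missing values and
no zero-variance regions (both are hard errors, never silently imputed).
Negative correlations are retained; matrices are not thresholded,
binarized, or Fisher-transformed before PLS (a Fisher transform is
available as an explicit, off-by-default step). Thresholding exists only
for reporting (top-percentile edge selection).

## Inference

**Permutation test.** Y rows are re-paired with X rows uniformly at
random; the full decomposition is recomputed per permutation and LV k's
p-value is the add-one fraction (1 + #{sₖ_perm ≥ sₖ}) / (1 + n_iter). The
add-one form is unbiased, never returns zero, and is standard for Monte
Carlo tests. By default the k-th permuted singular value is compared with
the k-th observed one; a Procrustes variant (rotating each permuted
solution onto the observed behavior-salience basis before extracting
singular values) is available for near-degenerate spectra, since toolboxes
in this lineage differ on this point. Permuting Y rather than X is an
arbitrary choice; the two are equivalent in distribution.

**Bootstrap.** Subjects are resampled with replacement jointly in X and Y;
the PLS is refit per resample and aligned to the original solution — by
sign by default (flip LV k when uₖ·uₖ_boot < 0), or by a joint orthogonal
Procrustes rotation of the stacked saliences. Loadings are recomputed per
resample; percentile CIs at the requested level (default 0.95) flag a
loading reliable when the interval excludes zero. Percentile intervals
were chosen over BCa as the simplest defensible construction consistent
with asymmetric reported intervals in this literature; the bootstrap ratio
(original loading / bootstrap SE) is emitted as an auxiliary statistic. A
resample that leaves any column constant is redrawn (at most 10 times,
then an error). No stratification: the design is single-group.

**Determinism.** Every stochastic routine takes a seed. Per-iteration
generators are spawned from a `numpy` SeedSequence, so permutation and
bootstrap results are bit-identical whether iterations run serially or in
chunks (`chunk_size` is a scheduling hint, never a result-changing knob).

## Numerical conventions

- **Sign convention.** SVD signs are arbitrary; each (uₖ, vₖ) pair is
  flipped jointly so the element of vₖ with the largest absolute value is
  positive (first index on ties). Joint flipping preserves R = USVᵀ and
  makes outputs reproducible. A consequence worth knowing: negating Y
  leaves V unchanged and flips U — the solution is an equivalence class up
  to joint sign, and p-values and CI widths are invariant to it.
- **Scaling of R.** Default `correlation` (1/(n − 1)); an `unscaled` mode
  reproduces raw XᵀY magnitudes. Saliences, covariance-explained fractions
  and p-values are identical under either; only the singular-value scale
  differs.
- Loadings of an LV whose score column has zero variance are undefined and
  returned as NaN with a warning.
- `salience_cosine` clamps float round-off to [−1, 1].
- The region-by-region loading-similarity matrix correlates row profiles
  of the two devectorized loading matrices; the undefined diagonal entries
  are masked by excluding positions {i, j} from both profiles, so compared
  profiles always cover identical region pairs. An alternative reading
  (lobe-block-wise correlation) exists in the literature; the row-profile
  form is implemented because it yields a region-by-region matrix directly.
- Top-percentile selection operates on signed loadings (largest positive)
  with ties at the cutoff included; an absolute-value mode exists for
  exploration. Lobe attribution defaults to counting distinct incident
  regions (`mode="regions"`), the reading consistent with published
  attribution percentages; per-endpoint counting is available.
- Battery correlations use Spearman when either member of a pair is
  ordinal, Pearson otherwise; Spearman p-values use the t-approximation,
  with exact permutation enumeration available for n ≤ 8. Which variables
  are ordinal is metadata supplied with the score table; the default
  synthetic battery marks score-capped recall/recognition variables
  ordinal. FDR control is Benjamini–Hochberg step-up (via statsmodels)
  over all off-diagonal pairs; the reported critical p is a realization on
  the data at hand, not a method constant.

## Synthetic data

The generator emulates the *shape* of a simultaneous MR-PET cognition
study: 26 subjects, an 82-region Desikan–Killiany parcellation (34
cortical + 7 subcortical per hemisphere; the insula is grouped with the
subcortical division for reporting, matching how such regions are listed
in attribution summaries), two modalities, and a 6-test battery scored
into 14 outcome variables whose means and SDs follow the published
descriptives, including one at-ceiling constant score (Stroop congruent
total, all 112) that the QA stage must remove, leaving 13. The derived
Stroop composite ("frontal lobe dysfunction" score) is omitted from the
synthetic battery in favor of the raw congruent score so that exactly 14
variables are emitted. Within-test correlation defaults to r = 0.5 through
a shared per-test factor — enough structure for internal-consistency
statistics to be meaningful without fitting any real covariance.

The central fixture is the rank-k latent model: X = Z·diag(e)·Uᵀ + E,
Y = Z·diag(e)·Vᵀ + F with standard-normal subject scores Z, unit-norm
orthogonal planted saliences, and i.i.d. Gaussian noise (default SD 1).
Rank 1 is the default — one significant LV per modality is the regime this
emulates — with a rank-k extension for multi-LV behavior. Edge values from
this model live on an unbounded correlation-like scale; devectorized
stacks built from it therefore relax the [−1, 1] range check (real
pipelines entering through time series keep the strict check). The
`population_pls_solution` helper computes the closed-form population
cross-block correlation, saliences and loadings implied by a truth — the
estimand sample solutions converge to, used as the oracle in coverage
studies.

ROI time series are multivariate Gaussian with block-community population
correlation (within_r / between_r, positive-definiteness checked by
Cholesky). The fPET-like accumulation component is a monotone
non-decreasing linear + quadratic trend added per region and removed by
per-region polynomial least squares (order 1–3). This is a deliberately
simple stand-in for dedicated fPET signal filtering: it reproduces the
qualitative problem (a dominating cumulative-uptake component masking
short-term fluctuations) but not any specific published filter.

**What passing tests do and do not show.** The generator satisfies the PLS
model exactly: Gaussian noise, no spatial autocorrelation among edges, no
subject heterogeneity, no motion or physiological confounds, and
correlation-scale values that are unbounded rather than squashed into
[−1, 1]. Green tests therefore validate the *statistical machinery* —
calibration, coverage, recovery, determinism — not robustness to the ways
real neuroimaging data violate these assumptions.

## Study conditions used by the checks

Problem sizes were fixed once as representative desk-scale analogues of
the emulated study: null calibration uses 500 datasets (26 subjects, 105
edges, 13 variables, effect 0) × 199 permutations, with the LV1 rejection
rate at α = 0.05 required to fall in [0.03, 0.08]; salience recovery uses
effect 5 at 100 subjects over 50 seeds (mean |cos| > 0.9 both blocks); the
coverage study uses 300 simulations (100 subjects, 45 edges, 8 variables,
effect 3) × 199 resamples against the closed-form population loading of
the dominant behavior variable, with sample-to-population alignment by the
sign of v̂·v_pop, requiring empirical coverage in [0.90, 0.99]. Effect 3
places the dominant population loading near 0.85 — the regime the
percentile bootstrap is designed for; loadings pressed against ±1 are a
known failure mode of percentile intervals and are not a sensible
validation target. The acceptance script runs a study-scale fit (26 × 3,321
× 13, effect 3) with 999 permutations and 499 bootstrap resamples, a
200-dataset calibration and the 300-simulation coverage study.

## Known limitations

- Time series are correlated as a single block; if acquisitions come in
  blocks (e.g., multiple EPI runs), split-and-average must happen upstream
  or inputs provided pre-split.
- The polynomial detrend is not a validated fPET preprocessing method;
  numeric agreement with any specific filter is out of scope.
- Brain-loading CI storage is O(iterations × edges × LVs); restrict
  `brain_lvs` (the CLI keeps LV 1 only) for large edge counts.
- At 26 subjects and 3,321 edges, edge-level salience recovery is weak
  even at moderate effect sizes (the acceptance script reports the
  measured cosine); behavior-side saliences are far better determined.
  This is a property of the design, not of the implementation.
- No PLS regression (NIPALS/SIMPLS), sparse PLS, or CCA; no graph-theoretic
  summaries or plotting — outputs are tables, JSON and CSV.
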