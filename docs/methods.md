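# Methods

## Model

`o2weave` integrates two omics data matrices measured on the same samples —
typically a transcript-abundance block X (n × p) and a metabolite
ion-abundance block Y (n × q) — with the two-block O2PLS decomposition

```
X = T Wᵀ + T_yo P_yoᵀ + E
Y = U Cᵀ + U_xo P_xoᵀ + F
```

Each block is split into three parts: **joint** variation (scores T, U
correlated across the blocks, loadings W, C), **orthogonal** variation unique
to one block (scores T_yo, U_xo, uncorrelated with the joint scores), and
residual noise (E, F). An inner relation B = (TᵀT)⁻¹TᵀU links the two joint
score sets. The model is symmetric: neither block is "predictor" or
"response".

### Estimation

Fitting is deterministic, with no random initialisation:

1. **Joint loadings** are the top `n_joint` singular vector pairs of the
   cross-product XᵀY. When n < min(p, q) the SVD is computed through
   economy QR factorizations of the two blocks (XᵀY = Q_x R_x R_yᵀ Q_yᵀ,
   SVD of the small n × n core), which is algebraically identical to the
   dense route and keeps permutation loops fast.
2. **Orthogonal components** are extracted one at a time per block: the
   leading left singular vector of (X − TWᵀ)ᵀT gives a direction whose score
   t_o = X w_o captures block-specific structure; the block is deflated by
   t_o p_oᵀ with p_o = Xᵀt_o/(t_oᵀt_o) and the joint scores are refreshed.
   Deflation makes every feature column of the deflated block exactly
   orthogonal to t_o, so the final joint scores are orthogonal to the
   orthogonal scores up to round-off (asserted at 1e-8 in tests).
3. The joint part is **re-estimated** on the deflated blocks, and the
   residuals close both reconstruction identities exactly by construction.

Conventions needed for reproducible downstream thresholds:

* **Sign**: each loading column is flipped so its largest-magnitude entry is
  positive; ties break toward the earliest feature index.
* **Order**: joint components follow decreasing singular value of the
  (current) cross-product; orthogonal components follow extraction order.
* **Rank**: a requested joint rank beyond the numerical rank of XᵀY (machine
  epsilon × max dimension × leading singular value) is an error reporting the
  achievable rank, never silently regularized. n = 6 samples with 3 joint +
  1 orthogonal components per block — the scale this pipeline targets — fits
  without any special casing.

### Variance accounting

With Frobenius sums of squares, `r2x_model` (Rt2) = 1 − ‖E‖²/‖X‖² is the
fraction of X captured by joint + orthogonal parts; `r2x_joint` (RtCORR) =
‖TWᵀ‖²/‖X‖² is the joint part alone; analogously Rm2 and RmCORR for Y. The
ratios RtCORR/Rt2 and RmCORR/Rm2 measure how much of the modeled variation is
shared across blocks. Because the deflated block is orthogonal to the removed
orthogonal part, r2_joint ≤ r2_model holds exactly, and with the orthogonal
count fixed the model fractions are non-decreasing in `n_joint`.

## Preprocessing

Three steps, mirroring common two-block practice: (1) mean-center every
feature in both blocks; (2) scale each feature of the metabolome block to
unit variance (sample standard deviation, n − 1 denominator), since ion
intensities span orders of magnitude; (3) scale each whole block to a total
sum of squares of 1 so neither block dominates the joint fit through its
feature count or units. Both flags are configurable per block. Fitted
recipes (means, standard deviations, block factor) serialize to JSON so a run
can be reproduced exactly. Feature subsetting to the externally supplied
significant-feature lists happens **before** block scaling — the subsetted
matrices are what enter the model, so they are what gets equalized. An
optional log2(x+1) pre-transform for abundance matrices is off by default and
recorded in the run manifest when used. Zero-variance features under
unit-variance scaling and all-zero blocks are hard errors; missing values are
rejected at parse time (imputation is out of scope).

## Permutation thresholds and influence selection

The null hypothesis is "no cross-block association". It is simulated by
permuting the sample rows of the Y block with uniformly random permutations
(sampled with replacement; X fixed — permuting one block is equivalent under
the null and fixing which one keeps runs deterministic), refitting the full
O2PLS model each time, and pooling the sign-fixed joint loadings per block
and per joint component. The default is 1000 permutations at α = 0.05. The
empirical α/2 and 1 − α/2 quantiles of each pool (inclusive definition,
linear interpolation between order statistics) become that latent variable's
lower/upper thresholds. A feature is flagged as influential when its observed
loading falls outside the interval on *any* joint component; summary counts
are over distinct features. Flagged sets are nested in α by construction.

Pooling is per component rather than global per block: thresholds are "for
the latent variables". Component label-switching across permutations is
mitigated by singular-value ordering plus the sign convention; residual
ambiguity at near-equal singular values is an accepted limitation. The
type-I calibration study uses one joint latent variable so that the flagged
fraction estimates the per-latent-variable rate directly; with several
components the any-component union rate is correspondingly larger (roughly
1 − (1 − α)^k for independent components).

## Differential-ion prefilter and signature comparison

An ion is differentially accumulated between a control and a treated group
when its one-way ANOVA p-value is ≤ 0.05 **and** |log2 fold change| ≥ 1
(both thresholds inclusive, both arms required). With two groups the ANOVA is
algebraically the pooled-variance two-sample t test (F = t²), verified to
1e-12 against an independent implementation and, on 3 vs 3 fixtures, against
the exhaustive 20-relabeling permutation test in rank order. Raw p-values are
used — no multiple-testing correction is applied at this screen. Fold
changes floor all intensities at half the smallest positive intensity in the
table before taking group means, so the log is always defined; an ion that is
all-zero in both groups gets p = 1 and log2fc = 0 and is never selected.
Degenerate rows with zero within-group variance take the vanishing-variance
limit of the F test (p = 0 if the group means differ, else p = 1). Transcript
differential expression is *not* recomputed: the pipeline ingests the gene
list produced by a dedicated count-based DE analysis as a plain feature-list
file. Signature comparison is an exact three-way partition (shared / only-A /
only-B) preserving input order.

## Synthetic data generator

The generator emulates exactly the structure the model assumes: joint latent
scores drawn once and shared by both blocks, block-specific orthogonal
scores, orthonormal loading matrices, and i.i.d. Gaussian noise. Key choices:

* **Exact variance splits.** Each of the three components is rescaled so its
  realized sum of squares equals its configured fraction of the block's
  budget — from realized sums of squares, not expectations — so even 6-sample
  fixtures hit their nominal split; only the noise cross terms (O(1/√n))
  separate the emitted block's total from the budget.
* **Orthogonality is enforced empirically, not just in expectation.** The
  orthogonal scores are residualized against the joint scores, and the second
  block's orthogonal scores additionally against the first block's: at small
  n, accidental correlation between the two block-specific parts *is* joint
  variation by the model's definition and would contaminate the
  joint/orthogonal split. This implies n_joint + n_orth_x + n_orth_y ≤ n − 1.
* **Planted features.** Chosen feature rows of the joint loading matrix are
  boosted and the columns re-orthonormalized by polar (symmetric)
  orthogonalization, iterating the boost until every planted row holds at
  least 3× the average per-feature loading mass. Planted identities, realized
  variance fractions and generating loadings are returned as ground truth.
* Defaults mirror the targeted study scale: 6 samples (three replicates in
  each of two treatment groups), 126 transcript features, 85 ion features,
  3 joint + 1/1 orthogonal components, a 0.6/0.2/0.2 variance split, and a
  mandatory seed with no hidden global state.

The peak-table generator produces two groups of lognormal, mean-preserving
multiplicative noise around base × 2^effect intensities, so at zero noise the
group-mean ratio is exactly 2^effect, and ions with |effect| ≥ 1 are the
ground-truth positives.

What the generator does **not** emulate: count overdispersion and
library-size effects (DE territory), LC–MS peak shapes, retention-time drift,
adducts/isotopes, missingness, or heavy-tailed biological variation. Passing
tests therefore certify the algebra, calibration and selection logic of the
pipeline under the model's own assumptions, not robustness to real-data
pathologies.

## Problem sizes and what the checks show

The validation studies run at desk scale, chosen to finish in seconds to
minutes: oracle equivalence on 100 random 6×20/6×15 pairs; recovery at
n = 50, p = 200, q = 100 under a 0.6/0.2/0.2 split; selector calibration on
50 independent null pairs (n = 6, p = q = 200) with 200 permutations each;
planted-feature recall pooled over three draws (54 planted features total)
at a 0.78/0.2/0.02 split. Recall is reported pooled across draws because
with 8–10 planted features per block a per-draw proportion is too granular
to be meaningful.

A fundamental accuracy limit worth knowing: the joint loading subspace is
estimated with angular error on the order of √(p·σ²_noise)/s per component,
where s is that component's signal singular value — the same floor a
least-squares fit handed the true latent scores attains. At a 0.6 joint
fraction split over three components with 20% noise (n = 50, p = 200) this
floor is ≈ 8°, and the fitted model lands within ~1° of it; pushing below a
few degrees requires either higher signal-to-noise or structural priors
(sparsity) outside this model class. The fitted joint variance fraction
likewise absorbs ≈ n_joint·σ²_noise/n of noise (plus selection bias), so at
those settings it overshoots the generating fraction by ≈ 0.02.

## Known limitations

* Permutation thresholds are not FDR-controlled across features; they are
  plain per-latent-variable quantile cutoffs.
* The permutation null preserves each block's internal covariance but breaks
  *all* cross-block structure, so any real shared variation inflates the
  null pools slightly (conservative thresholds).
* Component counts are user-fixed; there is no cross-validated selection.
* No predictive projection of new samples, and no sparse/penalized variants.
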