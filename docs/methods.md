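# Methods

This note documents the statistical model behind `audseg`, the defaults and
why they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions used throughout.

## The measurement and segmentation model

Respondents answer Likert items (integer codes 1..L, default L = 5) grouped
into blocks of related questions. The working model is a linear factor model:
respondent *i* carries a latent attitude vector **f**ᵢ in ~10 dimensions,
item *j* measures one factor with a signed loading *aⱼ*, and the observed
code is a discretization of `aⱼ·f_ij + εⱼ`. Segments are regions of the
factor space: each segment has a centroid, and within-segment variation is
isotropic around it. Segmentation is therefore a centroid-recovery problem,
attacked with k-means on factor scores plus the judgment-driven additions
described below.

Two response styles break the measurement model and are handled explicitly:

* **Straight-lining** (one constant answer): detected by per-block sample
  variance. A respondent invariant (variance ≤ `var_eps`, default 0) in at
  least `min_invariant_blocks` (default 3) non-exempt blocks, or across all
  of them, is removed. Blocks where a constant answer is reasonable
  (life-satisfaction, behaviour-frequency) are exempt and never counted.
* **Acquiescence** (agreeing with everything, including contradictory
  statements): shows up as high-mean/low-variance rows. The extreme form is
  removed at screening (block mean within 0.25 of the scale top and overall
  variance ≤ 0.25 over non-exempt blocks). The milder, correctable form is
  neutralized by standardizing the designated blocks at the respondent
  level: `z_ij = (x_ij − mean_i) / sd_i` over those blocks' items. An
  additive row shift cancels exactly in this transform; the attitude signal
  survives because the blocks contain items keyed in both directions, so the
  respondent mean carries the response style, not the attitude. The numeric
  screening thresholds are package choices — the screening rules themselves
  are principled but no canonical threshold values exist; all are exposed in
  `QCRules`.

## Factors

* **Extraction** is principal-axis factoring (iterated communalities,
  squared-multiple-correlation start) with oblimin (quartimin, gradient
  projection) rotation by default; attitude factors correlate, so an oblique
  default is the safer convention, and varimax is available. Extraction and
  rotation are deterministic given the data.
* **Scoring**: score = Σⱼ aⱼ·zⱼ over the factor's items, then renormalized
  to unit sample sd. Negative loadings reverse-code items. Cross-loading
  items may appear in several factors; scores feed clustering, not
  coefficient inference, so cross-loading is harmless here.
* **Reliability**: Cronbach's α = k/(k−1)·(1 − Σ item variances / variance
  of sum), computed after flipping negatively keyed items, gated at the
  conventional 0.7. `refine_to_reliable` does a greedy drop/add search over
  a candidate pool and reports failure rather than raising when the pool is
  exhausted.
* **Meta-factors** (pooling many correlated first-order factors into a
  manageable set) use principal-component extraction on the factor-score
  correlation matrix with varimax. PAF is inappropriate at this stage: with
  near-orthogonal base factors the communalities collapse toward zero and
  the solution degenerates, whereas components recover an orthogonal base
  exactly (up to sign/permutation).

## Segmentation

The default path, in order:

1. **Map and central group.** Classical (Torgerson) MDS gives each
   respondent a 2-D map position; for raw coordinates this is computed as
   centered PCA, to which Torgerson scaling of Euclidean distances is
   exactly equivalent. The `central_fraction` (default 2%) of respondents
   with smallest map radius — people with no distinctive views — are set
   aside, because they sit between every cluster and blur the partition.
   Polar-coordinate sectoring (default 36 sectors, half-open at θ = 0) is
   provided as a profiling diagnostic of the map.
2. **Stable k-means.** `n_runs` (default 20) independent k-means runs on the
   remaining respondents; the best-inertia solution is kept and the mean
   pairwise adjusted Rand index across runs is reported as a stability
   score. k is a config decision, not automated.
3. **Seed segments.** A config-supplied map of segment name → respondent ids
   can carve out additional judgment-defined segments before refinement (the
   mechanism for reinstating a segment that clustering merged away). The
   default synthetic run needs none.
4. **Central reinstated** as its own segment (centroid = mean of its
   members), so the neutral core is a reported segment rather than
   discarded respondents.
5. **One-step nearest-centroid refinement**: every respondent moves to its
   Euclidean-nearest centroid and centroids are recomputed once — exactly
   one iteration of Lloyd's k-means (ties to the lowest segment index;
   an emptied segment keeps its previous centroid with a warning).

**Rebuild matching.** Whether a segmentation rebuilt from a revised factor
set "matches" the original cannot be judged by raw label agreement, because
respondents on a segment edge flip under tiny perturbations. The bootstrap
threshold δ is the chosen quantile (default 0.95) of the null distribution
of `d(x, own centroid*) − min_j d(x, centroid_j*)` over bootstrap-resampled
centroid sets — the apparent improvement that resampling noise alone
produces. A respondent counts as matched if the labels agree or the distance
improvement of the move is ≤ δ. The definition of the bootstrap null on
assignment margins is this package's interpretation of "a simple bootstrap";
it is documented as such and controlled by `n_boot` and `quantile`.

**Booster allocation.** Over-sampled (booster) respondents are held out of
clustering and allocated afterwards with quadratic discriminant analysis:
per-class Gaussians with class-specific covariances and empirical priors,
implemented directly so that a singular class covariance (tiny class,
collinear factors) falls back to an explicit ridge (λ·I, λ = 1e−3 default)
with a logged warning instead of failing. Training accuracy and an adjacency
report (whether misallocations land in the respondent's next-nearest
segment) are returned.

## Profiling and validation

Profile tables test every segment pair per row: pooled two-proportion z for
percentages, Welch (unpooled) t with Welch–Satterthwaite df for means —
Welch because segment variances are not assumed equal; the pooled z follows
the standard large-sample form. Per-comparison α = .05 with **no**
multiple-testing correction, the market-research convention these tables
follow; the letter strings are a reading aid for patterns, not confirmatory
inference. With weights, statistics are weighted and tests run on Kish
effective bases n_eff = (Σw)²/Σw² (configurable off).

Validation compares the 7-level segment variable against demographics as
predictors of (a) a summative 0–5 protective-behaviour score, via a Type III
GLM (sum-to-zero coding, marginal SS per term, SPSS-compatible layout with
Intercept/Error/Total/Corrected-Total rows) and partial
η² = SS_term/(SS_term + SS_error); and (b) binary vaccine refusal, via
logistic regression with per-term (multi-df for factors) Wald χ². Demographic
coding mirrors the published df pattern: gender one indicator, ethnicity a
4-df factor, education/income/age single-df numeric terms. A "combined
demographics" η² is reported from the joint full-vs-reduced Type III SS of
all demographic terms; summing the individual term SS gives a slightly
different number in non-orthogonal designs, and the package reports the
joint-term definition. Two-sided p-values, no multiplicity correction.

## The synthetic generator

`audseg.synth` emulates the population structure the pipeline assumes, with
defaults frozen as the package's study conditions:

* n = 5,507 respondents; 7 segments at the published population shares
  (14/14/13/13/15/21/15 %, normalized onto the simplex since the printed
  values total 105%); a 2% central group at the grand centroid.
* A 112-item, 12-block instrument mirroring the ten named factor scales
  (22-item manageability … 5-item health anxiety), loadings 0.6–0.85 with
  signs mixed within blocks; item noise sd 0.8 against within-segment sd 1.
* Segment centroids: a hand-crafted ±pattern matrix reflecting each
  segment's narrative profile, scaled by `centroid_scale = 2.0`. The true
  centroid magnitudes are unknown — these are **illustrative**, and the
  scale was set so the generated population reproduces the qualitative
  behavior the workflow reports (highly repeatable k-means solutions,
  cleanly separated segments: recovery ARI ≈ 0.85, stability ≈ 0.85).
* Response styles: 4% straight-liners (one constant answer across
  non-exempt blocks); 10% acquiescers shifted 2.5 scale points toward
  agreement (clipped at the top) on the two designated blocks — strong
  enough that they "agree with almost every statement" there.
* Discretization: equal-width bins over the item mean ± 3 sd, clipped —
  monotone and reproduces floor/ceiling pile-up.
* Demographics (age, gender, ethnicity, social grade, education, income)
  drawn from per-segment distributions patterned on the published
  demographic profile; binary outcomes (vaccination status, five
  protective behaviours) drawn from per-segment rates patterned on the
  published behaviour table (e.g. 24% vaccine refusal among the
  resister-type segment).
* One global seed; every stage draws from a named substream
  (`SeedSequence.spawn`), so outputs are bit-identical given the config.

What the generator does **not** emulate: quota weighting to national
margins, regional geography, telephone-mode effects, item-level missingness
beyond an optional uniform rate, non-additive response styles (e.g.
extreme-response style), and correlation between acquiescence and
ethnicity/culture. Passing recovery tests therefore show the pipeline works
when its model holds — segments that are Gaussian blobs in factor space and
acquiescence that is an additive location shift — not that real survey data
satisfies those assumptions.

A note on the size of the ipsative-standardization benefit: with
acquiescence confined to two blocks (22 of 112 items, one factor of ten),
the uncorrected pipeline degrades only modestly, so the paired ARI advantage
of the corrected pipeline is consistently positive but small (≈ +0.003–0.007
mean ARI at 15% acquiescers). The correction's exactness property (invariance
to additive row shifts) is unconditional and unit-tested.

## Numerical conventions and edge cases

* Sample (n−1) variances and sds everywhere, including α and screening.
* Constant columns standardize to 0 with a warning (configurable to error);
  constant rows in ipsative scaling become 0 and are flagged.
* Missing values are excluded pairwise; no imputation.
* Nearest-centroid ties break to the lowest segment index; central-excision
  ties break by respondent id; MDS axes carry a fixed sign convention
  (largest-magnitude coordinate positive).
* Tiny negative term SS from matrix arithmetic (|SS| < 1e−10·SS_total) are
  floored at zero before η² is computed.
* Degenerate tests: both-sds-zero Welch t is 0 (equal means) or ±∞ with
  p = 0 (flagged); zero-variance α is NaN with a warning.

## Problem sizes

The test suite and acceptance script run the full pipeline at n = 5,000–5,507
(the instrument's natural size), the law-of-large-numbers check at
n = 50,000, paired standardization comparisons at n = 1,500 × 10 seeds, and
oracle-equivalence checks on 50 random instances each; these sizes give
stable Monte-Carlo margins while keeping a complete run in the
seconds-to-minutes range on one CPU.
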