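# Methods

`aggnet` re-implements, as a tested library, an analysis pipeline linking
proneness to aggression and general psychopathology in a community youth
cohort: outcome scoring, stability-style penalized regression ensembles with
cross-outcome prediction, factor reduction of the overlapping predictors,
and a Gaussian graphical model (GGM) over factors and outcomes with
bootstrap stability analysis. Because no participant-level data are
deposited for this design, the package ships a synthetic-cohort generator
that reproduces the *statistical structure* the analysis assumes, so every
stage can be exercised and verified against known ground truth at desk
scale.

## Synthetic cohort model

Participants carry latent factors z ~ N(0, I_K) (default K = 12). Each
numeric item loads on exactly one factor, x_i = λ_i z_f(i) + √(1−λ_i²) ε,
with λ_i ~ U(0.4, 0.8), giving unit-variance items whose correlation matrix
is ΛΛᵀ + Ψ. Items are organised into scales (default 300 items over 29
scales, scale → factor assignment cyclic). Nominal items threshold the same
latent variable into 3–5 equiprobable labeled categories; a handful of
free-text items and a block of high-missingness items (missing rates drawn
from U(0.30, 0.60)) exist solely so the filtering rules have work to do:
with the defaults, 300 items reduce to 230 features after filtering.

The outcomes are linear in factor subsets A and B with |A∩B| =
round(f·|A|) for shared-factor fraction f (default |A| = |B| = 4):

    y1 = Σ_{j∈A} w1_j z_j + σ η1      y2 = Σ_{j∈B} w2_j z_j + σ η2

with w ~ U(0.5, 1.0) and shared factors carrying identical weights in both
outcomes, so f = 1 with σ = 0 makes the two signals coincide exactly. y1 is
delivered as eight symptom-scale totals (loadings U(0.42, 0.58) on the
standardized signal, chosen so the first principal component explains about
35% of the variance, matching the regime the pipeline expects); y2 as
twelve Likert items (1–5, right-skewed cut points giving a 12-item total
near 19.6) summed into a BPAQ-style total. The defaults (f = 0.75,
σ = 0.3) put the observed outcome correlation near 0.55;
`tune_overlap_for_target_r` calibrates f (discrete search) and σ
(bisection) to any attainable target within ±0.05, and reports a
bracketing failure for unattainable ones.

Missingness is MCAR: a base per-cell rate (default 0.001), a boosted rate
(+0.10) for a random 5% of participants, and a small rate (0.005) on
outcome items. MCAR is a deliberate simplification — it matches the
assumption under which kNN imputation is unbiased and keeps recovery tests
interpretable. What the generator does **not** emulate: item wording and
content, ordinal response scales for the battery items (they are
continuous), MNAR mechanisms, measurement non-invariance, and longitudinal
structure. Tests passing on these cohorts therefore validate the
*machinery* (estimation, selection, stability, absence of leakage), not
substantive conclusions about real survey data.

## Preprocessing

Items with strictly more than 25% missing values and free-text items are
removed; participants missing any outcome item, age or sex, or strictly
more than 5% of the remaining items are excluded. The discovery/holdout
split is 3/4 vs 1/4 with the floor taken on the smaller block (2184 →
1638/546); each of the (default 100) ensemble repeats draws an independent
3/4 vs 1/4 train/test partition of the discovery set, all reproducible from
one seed.

Nominal items expand to full indicator sets (one column per category, not
reference coding — the L1 penalty absorbs the induced collinearity).
Zero-variance training columns are dropped. Every design column is centered
and scaled with training statistics; imputation runs *after* scaling (the
two orders are both defensible; scaling first keeps the kNN metric
comparable across columns) using the k = 20 nearest training rows by
nan-Euclidean distance (jointly-missing coordinates ignored, squared
distance rescaled by the fraction observed; sklearn's `KNNImputer`, which
leaves exact-distance ties to the partial sort — on continuous data exact
ties have measure zero). Categories unseen in training map to all-zero
indicators. Outcomes are standardized with training statistics, so all
reported RMSE/MAE are on the standardized-outcome scale.

## Ensembles

Per repeat: preprocessing statistics are refitted on the inner-train rows,
the L1 penalty λ is tuned on a 100-point geometric grid spanning exactly
[1e-10, 1] by mean out-of-fold RMSE over 10 folds (ties resolve toward
heavier shrinkage), and the LASSO is fitted at the chosen λ by coordinate
descent (scikit-learn paths; the final single-λ fit runs at tolerance 1e-8
so KKT stationarity holds to ~1e-6). Coefficients live on the
standardized-design scale, which is what makes averaging across repeats
meaningful; the intercept is the mean of per-repeat intercepts (≈0 for
standardized outcomes).

A feature is *significant* when the percentile 2.5–97.5% interval of its
coefficient across the repeats excludes zero. This is a stability
heuristic, not a calibrated test: under a global null its per-feature
false-flag rate is far below 10% (the acceptance suite checks the bound)
because the tuned penalty zeroes most coefficients outright. Significant
features keep their mean coefficient, the rest are zeroed; the averaged
vector predicts the holdout sample. "Models with only overlapping
features" are the zero-restriction of the averaged coefficients to the
intersection of the two outcomes' significance masks — a restriction, not a
refit, because the same averaged-coefficient object is what the
cross-prediction reuses. The Elastic Net variant adds a mixing grid
(default {0.2, 0.4, 0.6, 0.8, 1.0}) tuned jointly with λ and reproduces the
LASSO exactly at mixing 1.

## Factor reduction

Parallel analysis compares factor-model eigenvalues — the correlation
matrix with squared multiple correlations on the diagonal — against the
mean (or, by option, the 95th percentile) of eigenvalues from 100 random
normal datasets of identical shape, counting leading observed eigenvalues
until the first failure. On pure noise the first comparison is essentially
a coin flip around the reference, so the count is small but jittery rather
than exactly zero; the recovery contrast (structured data → exact count) is
the meaningful property and is what the tests assert.

Extraction is minimum-residual: uniquenesses ψ are optimized (L-BFGS-B,
bounds [0.005, 1]) so that the rank-k eigen-approximation of R − diag(ψ)
minimizes the squared off-diagonal residuals; for an equicorrelated block
with ρ = 0.49 this reproduces the closed-form loadings √ρ = 0.7 to 1e-5.
Rotation is oblimin via oblique gradient projection with γ = 0 (direct
quartimin); γ is exposed. Factors are ordered by explained variance and
sign-oriented so each factor's largest-|loading| entry is positive. Scores
are regression (Thurstone) scores Z R⁻¹ Λ Φ (Bartlett scores were the
alternative; regression scores are the common default and are what the
score-recovery tests calibrate against), with a ridge-stabilized inverse
and a warning if R is singular.

## Normalizing transforms

Seven candidates in fixed tie-break order: identity, Yeo–Johnson (ML λ),
Box–Cox (ML λ, positive data only), log10(x+a), √(x+a) (a = max(ε, ε −
min x), ε = 1e-3), arcsinh, ordered quantile. The ordered-quantile map uses
mid-ranks for ties and plotting position (r − 0.5)/n (r/(n+1) available by
option), linear interpolation between training values and linear tail
extrapolation beyond them. Selection minimizes a Pearson normality
statistic: standardize, bin into B = ⌈2 n^0.4⌉ classes equiprobable under
the standard normal, Σ(O − n/B)²/(n/B), divided by B. Cross-checked in the
tests against R `nortest::pearson.test` (which reports the un-normalized
statistic). All candidates are monotone on the training range, so ranks
are preserved exactly.

## Network estimation and stability

Edges are partial correlations w_ij = −κ_ij/√(κ_ii κ_jj). Because the
target regime has n ≫ p, estimation is unregularized model *selection*: a
100-point graphical-lasso path (α from α_max down to 0.01·α_max) proposes
structures, each is refitted by constrained maximum likelihood (iterative
conditional fitting over the covariance; the saturated structure returns
S⁻¹ exactly and the empty one diag(1/S_ii)) and scored by

    EBIC = −2 ℓ + |E| log n + 4 γ |E| log p,    γ = 0 by default,

then single-edge additions *and* removals are evaluated each sweep
(steepest descent, lexicographic tie-break) until no strict improvement
remains. On four-node problems the result matches the exhaustive
64-structure EBIC argmin in ≥95% of seeds; on a 15-node sparse benchmark
(|partial r| ≈ 0.25, n = 5000) edge sensitivity and specificity both exceed
0.9.

Stability: (1) nonparametric bootstrap — resample rows, full refit,
percentile 95% CIs per edge with absent edges contributing zero; (2)
case-drop bootstrap — at each drop proportion d ∈ {0.05, …, 0.75} subsample
(1−d)·n rows without replacement, refit, and correlate subsample expected
influence (signed strength) with the full-sample values; the CS coefficient
is the largest d at which ≥95% of correlations stay ≥0.7. The 0.75 grid
ceiling is the conventional maximum; a CS coefficient above it is not
representable, which is a known ambiguity of the statistic. Default
resampling counts are desk-scale choices (the reference tools default to
1000 bootstraps; the pipeline defaults to 200 edge bootstraps and 20
case-drop resamples per level, and the reproduction script to 100 and 10)
— percentile CIs at these counts are coarser but the stability
classifications they feed are stable in the tests.

## Pipeline and reproducibility

Stage seeds are SHA-256 hashes of (master seed, stage name) truncated to 31
bits, so any stage can be re-run in isolation and two runs with the same
master seed produce byte-identical reports. The p-factor PCA is fitted on
discovery rows only and holdout rows are projected with the fitted
loadings; the preprocessing transform used for the holdout design is fitted
on the full discovery sample; per-repeat transforms refit on inner-train
rows. A dedicated test corrupts every holdout row and asserts that no
fitted statistic, penalty choice, or coefficient changes.

Desk-scale problem sizes used by the tests and the reproduction script
(chosen as the package's defaults for interactive work): ensembles at 50
repeats on the full-scale cohort and 10–50 repeats in tests; the
cross-prediction sweep at n = 2000 with 10 repeats per seed; CS benchmarks
at n = 20000 with 10 resamples per drop level and a 30-point seed path.

## Known limitations

- The CI-over-repeats significance rule has no formal error control; it is
  validated empirically as a conservative stability filter.
- Parallel analysis near the noise boundary is jittery by construction (see
  above); factor counts within ±1 of each other are common on weakly
  structured data.
- Box–Cox applied to out-of-domain (nonpositive) new values clips to the
  smallest positive training value; ordered-quantile extrapolation beyond
  the training range is linear in the tails.
- The generator's items are conditionally Gaussian given the factors;
  heavy-tailed or strongly ordinal real items will make the normalizing
  stage do more work than these tests exercise.
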