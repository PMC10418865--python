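# Methods

`metabosig` implements a stability-driven discovery workflow for two-group
targeted-metabolomics experiments of the kind used to study stroke-heart
syndrome in rodents: a small cohort (tens of animals, unbalanced groups), a
Biocrates-style quantification panel (hundreds of metabolites with per-assay
limits of quantification), and the question *which metabolites robustly
discriminate the two groups?*

## Data model

A dataset is a `QuantMatrix`: a samples x metabolites concentration table,
per-metabolite LLOQ/ULOQ bounds, per-value quantification-status flags
(`valid`, `below_LLOQ`, `above_ULOQ`, assigned by strict comparison against
the bounds) and per-sample metadata (binary group label, tissue, tissue
weight). Plasma concentrations are micromolar; tissue concentrations are
divided by tissue weight (mg), with status flags kept in raw assay units.

## Quality control

1. **Weight normalization** divides each tissue sample's profile by its
   weight; plasma passes through.
2. **LOQ filter**: a metabolite with more than 30% of values out of
   quantification range (strict inequality) is removed, unless the 2x2 table
   of out-of-range status against group shows a significant association
   (Pearson chi-squared without continuity correction, alpha = 0.05), the
   situation of a metabolite quantifiable in only one group; such metabolites
   are kept (`retained_by_rescue`). Degenerate tables (zero margins) count as
   no association.
3. **Imputation** of retained censored values: below-LLOQ cells become
   LLOQ/2, above-ULOQ cells become ULOQ (divided by sample weight for
   weight-normalized tissue matrices). These are the standard conventions
   for targeted panels; the workflow records the rule in its provenance log.
4. **Standardization**: column z-scores with the sample (ddof = 1) standard
   deviation. Descriptive analyses (PCA) standardize the full matrix; inside
   the machine-learning loop the scaler is fitted on the training split only
   and reused on the test split, so no test information leaks into training.
   Zero-variance columns are dropped with a warning.

## Univariate statistics

Per metabolite (and per indicator ratio): group means, sample SDs, t-based
95% confidence intervals (mean +/- t_{n-1,0.975} * sd/sqrt(n)), ranges,
two-sided Mann-Whitney U tests (exact enumeration when the smaller group has
at most 8 untied observations, normal approximation with tie correction
otherwise), Benjamini-Hochberg adjustment across all rows, log2 fold change
of group means (positive class over reference), and Cohen's d with the
degrees-of-freedom-weighted pooled SD

    d = |m_b - m_a| / sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2)/(n_a+n_b-2)).

Fold changes are computed on unstandardized concentrations. Volcano
coordinates floor q at 1e-300 before -log10 so they stay finite.

## Indicator ratios

A small catalogue of interpretable sums/ratios ships with the package:
Pro/Cit (arginase vs NO-synthase flux), Cit/Arg (NO-synthase activity), the
global arginine bioavailability ratio Arg/(Orn+Cit), total-SM/total-PC
(sphingomyelin-synthase activity), Hex2Cer/Cer and Hex2Cer/HexCer
(glycosphingolipid turnover; both forms are provided because either
denominator is used in practice), Gly/Ser (serine
hydroxymethyltransferase), and the strictly ketogenic amino-acid sum
Lys + Leu. Class-level terms (`class:SM`) expand through the metabolite
catalogue. Ratios are scale invariant, sums degree-1 homogeneous; a zero
denominator yields NaN for that sample rather than a dropped row.

## PCA screening

PCA is an SVD of the column-centered standardized matrix, with each
component's sign fixed so its largest-magnitude loading is positive. Sample
outliers are flagged by the robust z-score (median/MAD, MAD scaled by
1.4826; SD fallback when the MAD is zero) of the score distance over the
first k = 2 components, each component scaled by its SD, at a threshold of
z > 4. The criterion is exposed in configuration; on generated data with a
whole-profile x10 sample it flags that sample, though at these sample sizes
the z > 4 rule occasionally flags one additional borderline sample.

## Stability selection

The core engine repeats R = 30 times:

1. **Stratified split** into 70% training / 30% test by largest-remainder
   allocation per class; the training size is ceil(0.7 n), reduced when
   n >= 40 so at least 12 samples remain in the test set (40 samples give
   28/12; 39 give 28/11).
2. **All-relevant selection** on the training split by the shadow-feature
   procedure: each round appends an independently permuted copy of every
   surviving feature, fits a random-forest importance model (depth 5; forest
   size scales with matrix width), and scores a *hit* for features whose
   importance exceeds the 100th percentile (maximum) of the shadow
   importances. Cumulative hit counts are tested against Binomial(r, 1/2):
   one-sided tests in each direction, Benjamini-Hochberg corrected across
   the features under test and alpha/r-corrected across rounds. Rejected
   features leave the matrix; undecided features at `max_iter` remain
   tentative and are treated as not selected.

   *Shadow pool*: the shadows are tiled to at least 60 columns. With the
   one-shadow-per-feature pool, the bar collapses once rejection narrows the
   arena, and the panel's strongest chance-correlate — which is the maximum
   of m noise draws and therefore beats a max-of-m shadow bar with
   probability roughly uniform across datasets — racks up hits, so the
   familywise confirmation rate on small pure-noise panels runs several-fold
   above alpha. With the 60-column pool the test suite verifies the rate
   stays at or below 5% on 40-sample/20-feature noise panels, at a real
   cost in sensitivity to moderate effects (see Limitations).
3. **Model tuning**: regularized logistic regression, linear SVM, RBF SVM
   and random forest, each over a small grid, scored by mean validation AUC
   over 10 stratified 70/30 subsampling resamples of the training split
   (sampling without replacement). Ties break toward the earlier family and
   the simpler grid point; the winner is refit on the full training split.
4. **Test AUC** via the rank statistic AUC = (R+ - n+(n+ + 1)/2)/(n+ n-)
   with midranks for ties.
5. **Shapley attribution** of the test-set scores by Monte-Carlo permutation
   sampling: for each random feature ordering, absent features are filled
   from a training-split draw and marginal contributions are accumulated;
   the sum over features telescopes to f(x) minus the baseline, so local
   accuracy holds in expectation. Signed means and mean |phi| per feature
   are both reported; the consensus ranking uses mean |phi|.

Rounds in which nothing is confirmed are marked failed and excluded.
**Aggregation** drops rounds whose test AUC is strictly below the empirical
25th percentile of all successful rounds (nothing is dropped when all AUCs
are equal), then keeps metabolites selected in strictly more than half of
the retained rounds, ranked by mean |phi|. Reported AUC median/SD covers
all successful rounds. The over-representation input list instead uses
metabolites selected at least 3 times over *all* rounds, pre-exclusion.

## Over-representation analysis

Pathways (user-supplied JSON, plus a small built-in demonstration library)
are intersected with the measured background (all metabolites surviving QC
in the analysed tissue); each is scored by the hypergeometric upper tail
P(X >= k) for an overlap of k between the selected list (size n) and the
pathway (size K within a background of N), with BH adjustment across
pathways.

## Synthetic data

The generator draws log concentrations from a one-factor-per-class latent
model: `log x = mu_m + sigma_m (sqrt(rho) F_class + sqrt(1-rho) eps) +
shift_m [group b]`, with `mu_m ~ U(log 0.05, log 500)` (micromolar),
`sigma_m ~ U(0.25, 0.6)` and `shift_m = d_m sigma_m`, so informative
metabolites differ by the configured Cohen's d on the log scale. Defaults
mirror the targeted study design: a plasma panel of 420 metabolites
(classes PC, lysoPC, SM, Cer, HexCer, Hex2Cer, TG, amino acids, bile
acids) over 28 sham / 12 stroke samples with 20 informative metabolites at
d in 0.4-1.8, of which ~400 survive the LOQ filter; and a heart panel of
160 metabolites over 40 weighed tissue samples with one injected
whole-profile outlier (so 39 samples survive the PCA screen). LLOQ is the
empirical quantile of each metabolite's marginal distribution at the target
censoring fraction (upper censoring is left to explicit configurations);
class-associated censoring plants a -3 sigma group shift so the censored
values concentrate in one group, the case the chi-squared rescue must keep.
Outliers multiply a sample's whole profile by 10. One global seed spawns
per-stage child generators, so identical configurations are bit-identical.

The generator emulates the *statistical* structure only: no raw spectra,
no batch/plate effects, no instrument drift, no missing-at-random cells.
Passing recovery tests on these fixtures shows the pipeline's statistical
machinery behaves as designed; it does not certify performance on real
matrices, whose correlation structure and censoring mechanisms are richer.

Two benchmark fixtures are fixed once: `recovery_config` (28/12 samples,
200 *independent* metabolites, 10 informative at d = 1.3, negligible
censoring) and the matched `null_config` (no informative metabolites).
Independence is deliberate: with correlated blocks, the neighbours of an
informative metabolite carry genuine signal, and recall/precision against
the planted list would penalize an all-relevant selector for being right.

## Benchmark problem sizes

The recovery benchmark (`metabosig.benchmark`) sweeps 10 fixture seeds for
each arm, R = 30 rounds per seed, with per-round compute trimmed as the
package's benchmark configuration: 20 shadow rounds (confirmations under
the 60-column shadow pool require near-perfect hit streaks, which resolve
well before round 20), 10 Shapley permutations, and two-point tuning grids.

## Known limitations

* **Sensitivity at these sample sizes.** With 28 training samples and 200
  metabolites, the largest chance point-biserial correlations (~0.55) match
  the correlation a true d = 1.3 effect produces. Any per-split selector
  strict enough to stay quiet on noise therefore confirms true d = 1.3
  features in only a minority of rounds, and the majority-vote consensus
  recovers only the strongest planted subset (measured recall on the
  recovery fixture is of order 0.1, with precision near 1 whenever the
  consensus is non-empty). The liberal
  shadow pool (`min_shadows=5`) roughly doubles per-round sensitivity but
  abandons familywise control on small panels and lets the dataset-level
  chance-correlate reach consensus on null data. This trade-off is a
  property of the problem dimensions, not of the implementation.
* **Null consensus with few successful rounds.** When almost every round of
  a null run fails, the majority vote runs over a tiny denominator and a
  single lucky round can constitute a "consensus" of one feature. The
  consensus should be read together with `n_successful`.
* The Mann-Whitney/BH workflow detects a lone d = 1.8 effect at 28/12 in
  ~86% of datasets — the power ceiling of the rank test at these group
  sizes — so single-metabolite discoveries near that effect size are not
  guaranteed.
* Exact pathway identities in the bundled demonstration library are
  illustrative, not a curated database.
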