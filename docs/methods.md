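# Methods

## Model and assumptions

The pipeline treats cross-domain drug-response prediction as supervised
domain adaptation.  The working assumption is that a subset of genes is
*domain-invariant*: their class-conditional distributions P(X | Y) are the
same in cell lines and in patients/PDX.  If the selected features are
invariant and their class-conditionals are mutually independent, the
source-trained posterior P_S(Y=1 | X) transfers to the target exactly when
the responder odds ratio

    r = (P_S(Y=1)/P_S(Y=0)) / (P_T(Y=1)/P_T(Y=0))

equals 1; for r ≠ 1 the transferred probability is biased upward (r > 1)
or downward (r < 1), and the Bayes-consistent decision threshold for the
transferred score is r/(r+1) instead of 0.5.  The simulation suite checks
all three statements empirically (bias direction, calibration at r = 1,
and accuracy gain of the adjusted cutoff at r ∈ {0.05, 0.2, 5, 20}).

The adjustment applies only to predictors emitting continuous
probabilities (logistic ridge).  KNN vote fractions are not calibrated
probabilities, so `cl2pt` refuses to combine KNNDA with the adjustment.

## Feature selection

1. **DA filter.**  Per gene, two two-sample KS tests: source-vs-target
   values among responders, and among non-responders.  A gene passes iff
   *both* p-values are ≥ α.  The both-classes rule is the stricter of the
   plausible readings of the selection criterion and matches the two
   sup-norm distances that define it; `ks_rule={both,either,pooled}` is
   exposed without changing the default.  The exact (permutation) null is
   used when both sides of a test have ≤ 10 samples — test cohorts here
   can have as few as 3 responders, where the asymptotic null is
   unreliable — and the asymptotic null otherwise.
   Note a consequence of stringency: under the null (a truly invariant
   gene), p-values are roughly uniform per class, so only about (1−α)²
   of invariant genes pass (≈ 9–10% at α = 0.7, measured on the
   generator).  The filter buys domain robustness at a real cost in
   retained signal genes; α trades those off.
2. **Differential expression.**  Welch's unequal-variance t-test
   (group sizes in real cohorts are badly unbalanced, e.g. 28 vs 342),
   Benjamini–Hochberg FDR across the candidate set, at most the 1,000
   smallest-FDR genes kept.  Ties at the cap break by raw p, then gene
   id, for determinism.  DE uses source-domain data only, keeping all
   target-label usage inside the DA filter.
3. **BW ratio.**  Degenerate conventions preserve a total order:
   0/0 → 0 (uninformative, ranked last); positive/0 → +inf (perfectly
   separating, ranked first).

## Training protocols

* Logistic ridge minimizes mean negative log-likelihood + λ‖β‖² with an
  unpenalized intercept.  The mean (not sum) scaling makes λ's meaning
  independent of n.  Optimization is L-BFGS-B with analytic gradients
  followed by a damped-Newton polish; fits are rejected unless the
  gradient inf-norm is below 1e-8.  Near machine precision the Newton
  line search accepts steps on gradient decrease, since the objective
  itself can no longer resolve progress.
* λ is tuned in two stages: 11 exponents −3.0(0.3)0.0, then 11 points
  ±0.05 in steps of 0.01 around the stage-1 winner; ties prefer the
  smaller penalty.  The published per-drug tuned penalties are *averages
  over CV repeats* by all appearances: most of them (e.g. 0.242, 1.039,
  0.521) are not expressible as any reachable grid point 10^a, so exact
  grid membership cannot hold for them; the grids themselves follow the
  protocol exactly.
* The top-p gene grid is 50(10)200 ∪ 200(20)400 ∪ 400(100)1000,
  deduplicated.  (p, λ) ties prefer smaller p, then smaller λ.  The
  orchestration layer clips the grid to the ranking length when the DA
  filter leaves fewer genes than the smallest grid point; the library
  trainer itself treats that as an error.
* KNN uses distance 1 − Spearman ρ between sample profiles (average-rank
  ties), vote-fraction scores (required for a CV *AUC*), an odd-K grid
  3..29 (all plausibly reported optima are odd and ≤ 29; odd K avoids
  0.5-vote ties), and neighbor ties broken by reference sample order.
* CV is stratified 5-fold with 10 repeats (configurable); per repeat the
  out-of-fold scores are pooled into one AUC (a `per_fold` averaging
  switch exists).  Repeat seeds derive from one seed via a PCG64
  generator, making the whole (p, λ/K, score) table bit-reproducible.

## Evaluation

AUC is the tie-aware rank (Mann–Whitney) estimator — KNN vote fractions
tie heavily, where trapezoidal ROC variants are ambiguous.  Error rates
are reported with explicit numerator/denominator counts ("0.40 (4/10)")
so small-cohort results stay auditable.  Repeat summaries are mean and
s.e. = sd(ddof=1)/√n.

## Synthetic data generator

The generator emulates the study conditions: class-conditionally Gaussian
invariant genes (class mean shift `effect_size` s.d. units, alternating
sign, identical law in both domains given Y), invariant null genes, and
shifted nuisance genes, with per-domain responder proportions fixing the
true odds ratio.  Default panel: 50 invariant-informative + 100 null +
500 shifted genes, 200 samples per domain, effect 1 s.d., domain shift
3 s.d.

Shifted genes by default carry a class effect *in the source only* (same
magnitude as the informative genes) on top of the target mean offset.
This is a deliberate design choice: a purely label-independent location
shift adds the same constant to every target sample's linear score and
leaves AUC invariant, so it cannot produce the negative transfer the DA
filter exists to prevent.  Genes that look predictive in vitro but whose
class relationship breaks in vivo are the textbook mechanism of that
failure, and `shifted_source_effect=0` restores the label-independent
variant.  A t(3) noise option (variance-normalized) stresses the KS
filter with heavy tails.

What the generator does **not** emulate: platform/batch structure,
gene–gene correlation, RNA-seq count noise, or censored/ordinal clinical
response.  Passing tests therefore demonstrate correctness of the
machinery and the prior-shift theory under the stated model, not clinical
performance.

## Numerical and degenerate-input conventions

* Standardization uses sample s.d. (ddof = 1); zero-variance genes map to
  all-zero rows (they can never pass DE ranking, and NaNs would poison
  downstream matrices).
* Duplicate gene rows collapse by mean at load time.
* Harmonization is per-domain per-gene location-scale matching, a
  deliberately simple batch harmonizer, with `none` for pre-harmonized
  inputs.  Empirical-Bayes batch correction is out of scope.
* IC50 dichotomization: sensitive iff IC50 ≤ maximum screening
  concentration (boundary inclusive).
* A score exactly equal to the decision cutoff classifies as 0 (strict
  ">"), keeping 0.5-cutoff behavior conventional.
* Cutoffs are stored at full precision and rounded to 2 decimals only
  for display, so chained computations do not compound rounding.

## Problem sizes in the test and acceptance suites

Simulation-backed checks are sized to run on one CPU in minutes: the
cutoff-gain study uses 100 seeds × 4 odds ratios with a 10-gene invariant
panel (n_source = 300, n_target = 200, fixed λ = 1e-3 since the study of
interest is the cutoff, not the tuning); calibration pools 30 seeds;
bias direction uses 20 seeds; the ablation direction check uses 8 seeds
of the default shift-heavy panel with p_grid = {5, 50} and 2 CV repeats.
These sizes are the package's own choices; the effects they measure are
large relative to the Monte-Carlo error at these sizes.

## Known limitations

* The DA filter needs target labels; it is supervised domain adaptation
  by construction, with the label-efficiency questions that implies.
* With stringent α and few genes, the filter can leave very small gene
  sets (or none, which raises an error advising a lower α).
* The odds ratio is estimated from the target cohort's own labels; for
  tiny cohorts this estimate is noisy, and a user-supplied prior can be
  passed instead (`cutoff=` override).
* Exact KS p-values are used only up to 10 samples per side; between
  exact and asymptotic regimes p-values can shift slightly at the
  boundary.
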