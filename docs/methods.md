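# Methods

## Model and procedure

csearch estimates, per gene, whether treated carriers do better under
treatment than treated non-carriers, using a rank-based individual
treatment effect for censored outcomes.

1. **Basal risk projections.**  Two scalar "survival state" scores are fit
   on the whole cohort by ridge-penalized Cox partial likelihood: one on
   the clinical block V (age, sex, ...), one on the binary gene matrix G.
   Treatment is included as an adjustment covariate during fitting but
   excluded from the projection, so the score reflects baseline risk.  The
   projection is defined up to an additive constant; only differences
   |P_i − P_j| are used downstream.  If the partial-likelihood fit fails
   (e.g. complete separation at tiny n), a logistic regression of
   event-by-median-follow-up stands in, with a loud log message — any
   monotone risk score yields usable similarities.
2. **Similarity weights.**  For each treated patient, Boltzmann weights
   exp(−|ΔP|/kτ) over the untreated pool, row-normalized, computed per
   covariate block and combined multiplicatively.
3. **Pairwise win scores.**  Wilcoxon–Mann–Whitney comparability for
   censored pairs: both events → order decides (ties score ½); censored
   time ≥ the other's event time → the censored patient wins; otherwise
   the pair is incomparable and carries no evidence.
4. **Win posteriors.**  Conjugate Beta accumulation of weighted win/loss
   evidence per treated patient, starting from Beta(1, 1).
5. **Per-gene decision.**  Carrier and non-carrier win probabilities pool
   into two Beta posteriors; a gene is flagged when the carrier 95%
   equal-tailed credible interval sits entirely above the non-carrier one.
   Genes are ranked by the separation margin (carrier lower bound minus
   non-carrier upper bound), flagged genes first, ties by carrier count
   then name.

Assumptions: no unmeasured-confounding *requirement* is claimed — the
benchmark deliberately violates it — but the method assumes the basal
projections capture enough outcome-relevant structure that
similarity-weighted untreated patients are usable counterfactual stand-ins;
binary, complete gene calls; a single binary treatment; independent
censoring.

## Hyperparameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k_tau` | `"auto"` | similarity bandwidth kτ; "auto" uses the SD of the untreated pool's projections per block (adaptive: scales with how spread the risk scores are). Fixed, not annealed. |
| `prior_alpha/beta` | 1, 1 | uniform Beta prior on every win probability. |
| `basal_ridge` | 0.1 | L2 penalty of the Cox fits; the genetic block (300 binary, sparse columns) needs it for well-posedness. |
| `basal_fit_pool` | `"all"` | fit basal models on the whole cohort (treatment-adjusted); `"untreated"` available — full-pool fitting is stabler at small n. |
| `incomparable` | `"drop"` | incomparable pairs contribute nothing and their weight is renormalized over comparable pairs, keeping total evidence at one pseudo-observation per patient; `"half"` scores them ½. |
| `ipw` | off | see below. |
| `propensity_clip` | (0.05, 0.95) | inverse weights explode near 0/1. |
| `ci_level` | 0.95 | credible level of the decision rule. |
| `k` | 10 | size of the suggested gene list. |

**Weight renormalization.**  The product of two individually normalized
weight vectors does not itself sum to 1; we renormalize it so each treated
patient contributes exactly one pseudo-observation to their Beta posterior.
Without this, posterior concentration would depend artificially on pool
size and on how different the two blocks' similarity profiles are.  The
verbatim unrenormalized product is available
(`combine_weights(..., renormalize=False)`).

**Why IPW is off by default.**  An inverse-propensity-weighted per-gene
aggregation (wins scaled by 1/(ê(V)ê(G)), losses by 1/((1−ê(V))(1−ê(G))))
is implemented and unit-tested, but it is not the default: on the
benchmark it reduces recovery from 10/10 to 0/10.  Two reasons.  First,
the genetic propensity ê(G) is a 300-covariate logistic fit whose
per-patient estimation noise enters the aggregation as a multiplicative
factor on the evidence — asymmetrically for wins and losses — so the
per-gene posterior mean ends up tracking propensity noise rather than win
evidence.  Second, when confounding operates through *hidden* variables
(as in the benchmark, and plausibly in real panels with thin clinical
annotation), observed-covariate propensities cannot remove it anyway.  The
`--stabilized-ipw` variant rescales the added pseudo-counts to one per
patient (restoring calibrated interval widths; identical to the unweighted
update when all propensities are 0.5) but inherits the same noise problem.

**Point estimate.**  Pw_i enters the per-gene pooling as the posterior
mean; full uncertainty propagation of each Pw_i posterior is not
attempted (the per-gene posterior width already reflects the number of
carriers, which dominates).

## The benchmark simulator

Per patient: 300 i.i.d. Bernoulli(0.1) genes, 10 of them (chosen per seed)
planted as positive treatment modulators; 10 hidden standard-normal
confounders; age ~ N(60, 10) years, sex ~ Bernoulli(0.5).  Treatment
assignment is logistic in the summed confounders (0.3 log-odds each);
event times are exponential with log-hazard

    0.3·z_age + 0.2·sex + 0.3·Σc + T·(0 + (−1.0)·#causal genes carried)

with baseline hazard 0.03/month and administrative censoring at 60 months
(≈ 34% censoring under the defaults; the horizon was set once so roughly
two-thirds of patients have observed events).  Treated patients are
therefore systematically sicker (confounding by indication), and the
benefit of treatment exists *only* through carried modulator genes, at a
strong e⁻¹ hazard ratio per gene.

What the simulator does **not** emulate: correlated gene profiles (real
mutation panels are strongly co-occurring/exclusive), prognostic main
effects of the modulators (available via `main_effect_causal`, default 0),
non-proportional hazards, informative censoring, and measurement error in
the gene calls.  Passing benchmarks therefore demonstrate recovery of
independent interaction signals under hidden confounding — not robustness
to correlated genomes.

## Evaluation protocol

"Five-fold" evaluation partitions a cohort into five treatment-stratified
folds and runs the full discovery on each complementary four-fifths,
reporting mean precision@10 against the planted truth.  The held-out fold
is withheld rather than scored: the discovery task is unsupervised, so
there is no per-patient prediction to test, and the five 80% subsamples
serve as replicates.  (Running instead on five *disjoint* 20% subsets
caps every run at n/5 patients and, under the benchmark's effect sizes,
no cohort size in the 100–4000 grid then reaches 9/10 recovery — the
n-axis of the discovery curve is the number of samples the discovery
actually sees.)

The log-rank comparator screens genes among treated patients after one
global 1:1 clinical propensity matching (greedy nearest-neighbor on the
logit, caliper 0.2 SD, ascending-id tie-break for determinism), with BH
control at FDR 0.05 and a carrier-benefit direction filter; suggested
genes are the rejections ranked by p.

## Numerical choices

- Boltzmann weights subtract the row-minimum distance before
  exponentiation, so kτ → 0 concentrates cleanly instead of underflowing.
- kτ = "auto" falls back to 1.0 when the pool projections are constant.
- Tied event times score ½ in pairwise comparisons; censoring exactly at a
  death time counts as surviving past it.
- Beta credible intervals are equal-tailed (scipy `beta.ppf`); the
  separation margin is the decision rule's own scalar, so ranking and
  decision never disagree.
- Matching and fold assignment derive from explicit seeds / sorted-id
  tie-breaks; two identical runs produce bit-identical outputs.
- Cohort construction coerces clinical columns to float64 with
  correctly-rounded string parsing, so write → read round-trips exactly.

## Known limitations

- The individual win posteriors are shrunk hard toward ½ (one
  pseudo-observation against a Beta(1,1) prior); carrier/non-carrier
  contrasts are compressed by a factor ≈ 3.  Ranking is unaffected, but
  the interval-separation rule is conservative at realistic carrier
  counts — at a few dozen carriers per gene the flag rarely fires even for
  true modulators, and the ranked top-k is the informative output.
- The asymptotic log-rank chi-square tail is anti-conservative below
  roughly 10 carriers per gene (measured: P(p < 0.001) ≈ 4.5×10⁻³ at 6 vs
  24 subjects).  At small cohort sizes the BH screen's global-null
  any-rejection rate therefore exceeds its nominal level through no fault
  of the BH step; the null-calibration test runs at carrier counts inside
  the approximation's working regime, and small-panel users of `csearch
  baseline` should treat borderline q-values at low carrier counts with
  suspicion.
- Negative modulation (genes whose carriers are harmed by treatment) is
  symmetric in principle but deliberately not reported.
- Only single-gene effects are scored; interactions between genes are out
  of scope.
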