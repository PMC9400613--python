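# Methods

## Task and design

The simulated task is a two-alternative orientation discrimination with
two placeholder locations. Each trial carries a spatial cue (directional,
valid with p = .8; or bidirectional, p = .5 per side) and two coloured
value cues signalling the points available at the target and distractor
locations (high = 100, low = 10 at defaults). The main phase is 2 blocks
of 360 trials: per block 200 directional trials (160 valid / 40 invalid)
and 160 bidirectional, every cue-validity condition divided equally over
the four value configurations (hT/hD, hT/lD, lT/hD, lT/lD), target side
counterbalanced, order drawn as a seeded uniform permutation per block,
and the 720 trials indexed into 36 sub-blocks of 20. Learning phases: one
32-trial bidirectional block (16 target-left) and two 40-trial
directional blocks (32 valid / 8 invalid), then 16 trials per value cue.

Reward on a correct trial is `base + bonus · clamp((850 − RT)/500, 0, 1)`
points (50 + 50 high, 5 + 5 low), so the printed 50–100 and 5–10 point
ranges are attainable and faster responses earn more; reward is available
on a p = .8 lottery of trials. The direction of the RT-to-bonus mapping
and the application of the availability lottery to the main phase are
design choices; both are configurable in `RewardRule`.

## Encoding models

Every model is a condition-level regressor through the Hick–Hyman law
`log(1/p + 1)` (natural log; the fitted slope β absorbs any base change,
and mixed-model likelihoods are invariant to affine rescaling of the
regressor, so regressors are not standardised). The piecewise branch
returns exactly 0 at p = 0.

Open choices, fixed as follows:

- **Units in the value models**: raw point values (100/10), not
  normalised shares. With raw points the squared term of the
  counterfactual loss dominates for hT/lD (loss 8102 → regressor
  1.2e-4 ≈ 0), which is what makes hT/lD behave like the zero-loss
  cells; normalising would break that qualitative pattern.
- **Counterfactual assignment per trial**: `x` = value at the target
  location (the experienced outcome), `x′` = value at the distractor
  location, `y′` = max of the two; MAD is taken over the signalled value
  set {high, low} (= 45 at defaults), single-feature, no consistency
  constant.
- **Spatial counterfactual null** (`sh_cf_null`): the loss is applied to
  the attended-location match indicator (x ∈ {0, 1}, x′ its complement,
  y′ = 1, MAD over {0,1} = 0.5; neutral cue → x = x′ → 0), giving
  {valid: ln 4/3, neutral: 0, invalid: ln 1.5}. Its only job is to be a
  null model that selection-history-shaped data reject, which it is.
- **Motivational location probabilities**: 0.5 each, because value cues
  are non-predictive of target side in this design; configurable.

## Synthetic cohorts

`simulate_cohort` generates, per subject, the full 720-trial schedule
with

`median RT(s, v) = β₀ + u_subj + u_cell(s, v) + β_sh·r_sh(s) + β_val·r_model(v)`

and a shifted-lognormal residual (shift 150 ms, σ = 0.28 at defaults,
≈ 100 ms trial-level sd). The linear predictor anchors the conditional
*median*, not the mean: the pipeline summarises cells by medians, and a
mean-anchored lognormal would attenuate every fitted slope by
exp(−σ²/2) ≈ 4 %, biasing coefficient recovery. Accuracy is Bernoulli
with a logit-linear condition effect of opposite sign to the RT effect
(base .75, the titrated level; 0.005 logits/ms), so slower conditions
are also less accurate — no speed–accuracy trade-off.

Two subtypes: *trackers* (β_val ~ N(145, 12) ms/unit, so the expected
lT/hD − hT/hD slowing is 145·ln 1.5 ≈ 59 ms) and *followers*
(β_val = 0). Every subject has β_sh > 0; followers draw a larger spatial
coefficient (mean 70 vs 40), reflecting that participants who ignore
value cues lean harder on the spatial cue. All randomness flows through
one seeded generator per cohort.

**What the defaults do and do not emulate.** The subject × cell random
intercept (sd 15 ms) and the slope heterogeneity (sd 6–12 ms/unit) are
deliberately *smaller* than real data imply. Real cohorts show
split-half feature reliabilities of ~0.7–0.93 and a between-subject sd
of value-effect differences near 77 ms, which would require cell
intercept sds around 85–90 ms; at that idiosyncrasy the cf and rv
regressors (pattern correlation ≈ .97) cannot be distinguished reliably
at 40 subjects, and the no-random-slope mixed model's intervals
undercover. The defaults instead define a regime in which 40-subject
model recovery, coefficient coverage and the printed 59 ms effect are
all simultaneously measurable; consequences: simulated effect sizes are
larger (d ≈ 1.9 vs the real ~0.8) and split-half reliabilities smaller
(~0.2–0.3) than deposited data. Passing recovery tests therefore
demonstrates correctness of the machinery under these conditions, not
that the real dataset is as decisive at 40 subjects.

`CohortSpec.subtype_separated` is the regime for clustering validation:
tighter within-subtype noise (cell sd 6 ms, σ = 0.12) and a stronger
follower spatial coefficient (mean 100), putting the subtype separation
at ~4 within-sds on two features. With a 131/15 imbalance the k-means
sum-of-squares objective prefers halving the majority cloud until the
minority sits that far out (on ideal Gaussian blobs: ARI ≈ 0.2 at 2 sd
separation, ≈ 1.0 at 4 sd), so marginal separation cannot validate label
recovery regardless of implementation.

## Preprocessing

Fixed order: subject exclusion (overall accuracy < 60 %, strict) → RT
outlier filtering on correct trials (< 250 ms strict, then > 2.5 sample
sd above the cell median per subject × spatial × value cell, stats
recomputed after the fast cut; incorrect trials pass through untouched) →
summaries → features. The "sd above the median" rule is implemented
literally as printed. It is applied once: re-applying it recomputes cell
statistics that shrink after truncation, so a second pass can remove a
few more rows on continuous data — the filter is a fixed point only when
outliers are well separated from the body.

Summaries are median correct RT, accuracy and inverse efficiency
(median RT / accuracy) per subject × 12 cells; empty cells are NaN,
never zero, and nothing is imputed. Clustering features:
SC = RT(p=.2) − RT(p=.8), IVi = RT(hT/hD) − RT(lT/lD),
IVii = RT(hT/hD) − RT(lT/hD), IViii = RT(hT/hD) − RT(hT/lD), value cells
collapsed over spatial certainty. Split-half reliability correlates the
features computed on odd vs even trials (presentation order).

For the mixed-model response we pool trials within each marginal
condition and take one median per subject × condition, rather than
averaging the twelve cell medians: the invalid-cue cells hold only ~15
correct trials each, and the small-sample bias of the median (positive
under right-skewed RTs, ∝ 1/n) otherwise correlates with the spatial
regressor and inflates the slope by several ms. Cluster features keep
the cell-mean definition above, which is how they are defined.

## Inference

`fit_lme` fits `response ~ 1 + regressor` with a subject random intercept
plus a subject × condition variance component, by maximum likelihood
(fixed effects differ across compared models, so REML deviances would
not be comparable). With one response per subject × condition the cell
component and the residual are jointly identified only in sum; the
likelihood, fixed effects, their standard errors, AIC and BIC are all
identified, and the arbitrary split is harmless for comparison. The
parameter count is k = 5 (intercept, slope, two variances, residual);
AIC/BIC identities are asserted in tests. Convergence failures are
flagged on the result, never silently replaced.

Wald test: W = (β̂/se)², df = 1, chi-square upper tail. Under the null at
40 subjects its empirical size is ~6 % at α = .05 (ML variance estimates
are slightly anti-conservative at finite n; the calibration study
reports the measured rate). RM-ANOVA uses Greenhouse–Geisser correction
with partial eta squared (via pingouin); the mixed design supports one
within factor crossed with a group factor, so the published
group × 3 × 4 follow-up is run as group × value on accuracy averaged
over spatial certainty, which is also how the original follow-up was
decomposed. Follow-up paired t-tests use Cohen's d = mean difference /
sd of differences and Benjamini–Hochberg control at q = .05. The JZS
Bayes factor integrates the non-central-t marginal over a Cauchy(0, √2/2)
prior on effect size by adaptive quadrature; tests cross-check it
against an independent closed-form implementation to 1e-4 relative.

## Clustering

Features are z-scored with the sample sd (ddof = 1). The multivariate
screen flags squared Mahalanobis distances beyond the chi-square 99th
percentile (df = number of features); a raw-threshold override exists
because a fixed literal cut (e.g. 98) does not correspond to any df = 4
chi-square quantile. The k-means sweep covers k = 1..10 with plain
random restarts (default 1000 in tests, 10000 for full runs); selection
takes the majority over largest relative within-SS drop, maximum mean
silhouette and maximum Dunn index, ties toward smaller k, disagreement
always reported. The Dunn index uses single-linkage separation over
maximum diameter, with +inf for all-singleton clusterings.

OPTICS runs with min_samples = features + 1 (= 5). Extraction defaults
to a reachability threshold at 1.8 × the median finite reachability —
above the dense main body, below the discontinuity to sparse points —
because xi-steepness extraction proved unstable on cohort-sized samples
(~146 × 4), fragmenting the main cluster or inverting the
cluster/outlier assignment in about a third of seeds; xi mode remains
available (`method="xi"`). Outliers are points not reachable within any
cluster of ≥ min_samples members. Per-group refits in the subtype
analysis use the k-means grouping; the OPTICS outlier set can absorb a
few extreme trackers, which would leak a small value slope into the
follower group.

## Reproducibility and problem sizes

Every stochastic stage derives its seed deterministically from one
top-level seed (`SeedSequence`, children < 2³¹). The validation studies
use 20 replicate cohorts of 40 subjects × 720 trials for model and
parameter recovery, 1000 replicates for Wald and BH-FDR null
calibration, and 3 replicate 131/15 cohorts for subtype recovery —
sizes chosen so the full suite and the reproduction script each complete
in minutes on a single CPU while leaving the Monte Carlo error of each
reported rate at a few percent.

## Known limitations

- The generator makes no attempt to match the deposited dataset's
  subject-level values, only the qualitative statistical structure; see
  the idiosyncrasy note above for where it is deliberately cleaner.
- The Bayesian mixed-model ANOVA Bayes factor reported in the original
  subtype follow-up is out of scope; only the JZS paired t-test BF is
  implemented.
- Accuracy summaries are computed on trials surviving the RT filter, so
  removing correct outlier trials can lower a cell's accuracy by a few
  tenths of a percent.
- The Wald test inherits mild finite-sample anti-conservatism from ML
  estimation; at 24 subjects its size is ~7.5 %, at 40 ~6 %.
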