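# Methods

`shapdrift` monitors a deployed admission-risk classifier by tracking two
weekly series over the post-training data stream: the model's discrimination
(bootstrap-interval AUROC) and, per input feature, the mean *normalised
Shapley share* of the model's predictions. The combination types what has
changed: moving shares are direct evidence that the covariate stream the
model consumes has drifted; falling discrimination with *stable* shares
means the model is using its inputs exactly as before yet ranking outcomes
worse, which is evidence that the feature–outcome relationship itself has
changed (concept drift).

## Attribution model

For a fitted gradient-boosted tree ensemble with margin (log-odds) output
f(x), the Shapley value of feature i at instance x is

    φ_i(x) = Σ_{S ⊆ F\{i}} |S|!(d−|S|−1)!/d! · [v(S∪{i}) − v(S)]

with the interventional (background-marginal) value function

    v(S) = E_z~B [ f(x_S, z_{F\S}) ]

over a background set B of reference rows. Interventional conditioning was
chosen over path-dependent conditioning because it has an unambiguous
brute-force definition — the engine ships `brute_force_shapley`, a 2^d
coalition enumerator, and the production algorithm must agree with it to
1e−8, which the test suite enforces on randomly fitted ensembles.

The production algorithm is exact and polynomial: for one tree, one
background row z and one leaf with value c, the coalition game restricted to
that leaf is c·[IN ⊆ S]·[OUT ∩ S = ∅], where IN are the deduplicated path
features whose splits x satisfies but z does not, and OUT the reverse. The
Shapley value of that conjunction game is a closed form in (|IN|, |OUT|, d),
computed once in exact rational arithmetic and cached as a lookup table;
summing leaf contributions over trees and background rows gives the exact
ensemble attribution. Cost is O(trees × leaves × |B| × depth) per cohort,
vectorised over instances.

Properties guaranteed (and tested): local accuracy φ0 + Σφ_i = f(x) with
φ0 = E_B[f]; exact zero for features no tree uses; additivity across trees;
symmetry.

**Attribution space.** Attributions are computed on the margin scale, where
tree-path computation is exact. A probability-scale view multiplies each row
by the chord slope of the logistic link between φ0 and the row's margin, so
local accuracy holds on the risk scale too. Because that is a per-row scalar,
normalised shares are identical in both spaces — the drift statistics do not
depend on the choice.

**Background.** Default 256 training rows (32 in the monitoring pipeline,
where thousands of instances are attributed per run). Rows are drawn by
balanced systematic sampling: training rows are sorted lexicographically
with low-cardinality (discrete) columns as the leading keys and sampled at a
fixed stride with a seeded offset. With small backgrounds, simple random
sampling leaves the discrete composition (e.g. the walk-in/ambulance mix)
off by O(1/√B), which biases interventional attribution magnitudes directly
and can mask a genuine case-mix drift; systematic sampling pins every
discrete level's proportion to within ~1/B.

## Normalised shares and their invariance

Per attendance, s_i = |φ_i| / Σ_j |φ_j| (the base value is not a feature and
is excluded; an all-zero row is flagged degenerate and given the uniform
vector). Shares are invariant to per-row rescaling, hence to shifts of the
outcome (target) distribution: if the admission base rate moves and the
deployed model is intercept-recalibrated, every row's probability-scale
attributions rescale by a common factor, so Σ|φ| moves while shares do not.
`experiments.prevalence_invariance_experiment` demonstrates this with two
20,000-episode cohorts identical except for the generating intercept
(admission rates ≈0.30 and ≈0.50): one model is fitted on the low-rate
cohort and deployed on the high-rate cohort after a prior-shift intercept
correction estimated from data; mean Σ|φ| on the risk scale changes by
~25% while no feature's mean share moves by more than ~0.002. (A variant
that refits the model per cohort leaves residual per-feature share
differences of ~0.01 — boosting's curvature weighting differs across
operating points — which is why the fixed-model reading is the one the
package demonstrates.)

## Drift flagging and typing

Weekly bins are ISO weeks (Monday-anchored, half-open). Importance series
carry seeded percentile-bootstrap 95% intervals (default 1000 resamples);
weekly AUROC likewise (Mann–Whitney tie convention, ½ credit; single-class
weeks are reported undefined, not fatal).

- **Importance flag:** feature flagged at week b if its weekly mean share
  falls outside its baseline 95% interval, on the same side, for k
  consecutive bins ending at b. The baseline interval for a bin of n
  episodes is the percentile interval of means of bootstrap samples of size
  n drawn from the pooled baseline-window episodes — the null distribution
  of a weekly mean at that bin's size. Default k = 3: with ~14 share series
  on 95% intervals, two-week runs alone still produce false drift calls in
  roughly one stable stream in six, which null simulations showed is too
  trigger-happy for a retraining alarm.
- **Performance flag:** week flagged when its AUROC interval lies entirely
  below the pre-period reference for k = 2 consecutive defined bins
  (one-sided: only degradation should trigger retraining review).
- **Typing rule**, over a classification window (default the final 8
  weeks): importance flags only → data drift without degradation;
  performance flags only → concept drift suspected; both → data drift with
  degradation; neither → stable. The quantitative thresholds are this
  package's operationalisation of a rule that is usually applied by eye;
  reports label them as such via their provenance block.

Categorical prevalence tables (per-level period prevalences and B/A ratios,
with new-category flags for levels unseen at fit time) accompany every
report so a flagged feature can be traced to the levels that moved.

## Synthetic attendance streams

Real ED extracts are private, so the generator supplies cohorts with a known
admission mechanism: P(admit|x) = σ(β0 + Σ contributions) with numeric
vitals contributing β·(x−μ)/σ on their baseline standardisation (missing
vitals contribute zero — missingness is non-informative/MCAR), categorical
levels and history flags contributing fixed log-odds offsets. Histories are
observed for a configurable 55% of attendances (linkage). Defaults, chosen
once as realistic study conditions: base admission rate ≈0.30 (intercept
−1.37); walk-in/ambulance mix 60/40 with admission rates ≈0.16/0.53;
vital-sign recording ≈70%; six numerics, four target-encoded categoricals,
four history flags (14 encoded features). The time grid is weeks 0..H−1
(default H=48) with uniform timestamps within the week, 150 episodes/week
by default, and a temporal train / pre / monitored split at weeks 16 and 36.

Drift events are step functions at an onset week t\*: covariate shift
(level-mix or numeric-location change), prevalence shift (intercept step),
missingness shift, category emergence (a new level absorbing probability
mass proportionally from existing levels, so level probabilities still sum
to one), concept shift (coefficient change, e.g. a sign flip), and volume
shift. The pandemic-like composite combines a walk-in collapse
(0.60 → 0.15), an intercept rise (+0.8), a vitals-recording rise
(missingness 0.30 → 0.08), an emergent "viral_illness" complaint level
(mass 0.50, log-odds +3.0) invisible to a model trained earlier, and an
attendance-volume drop (×0.55). These magnitudes were set so that the shock
reproduces, at this cohort scale, the qualitative picture that motivates the
method: an admission-rate jump, an attendance collapse, share series that
move at onset, and a weekly-AUROC depression that clears the bootstrap
intervals.

What the generator does not emulate: clinically calibrated vital-sign
distributions or their mutual correlation, informative missingness,
seasonality, patient-level repeat attendances, and free-text fields. Passing
tests therefore demonstrate the *method's* statistical behaviour under
known drift mechanisms, not performance on real hospital data.

## Model fitting

XGBoost (binary logistic, native NaN routing) behind a thin adapter that
extracts the booster into a self-contained array representation; extraction
fidelity is asserted at fit time (internal vs backend margins, float32-
accumulation limited). Attribution and prediction run only on the internal
representation. Hyperparameters are a fixed documented set (200 trees,
depth 4, learning rate 0.1, subsample 0.8); the monitoring pipeline default
is 150 trees of depth 2, which fits these additive-mechanism cohorts better
at their sample sizes and halves attribution cost. A plain cross-validated
grid-search helper is provided but nothing depends on it.

## Numerical choices and degenerate inputs

Shapley conjunction weights: exact `fractions` arithmetic, converted to
float64 once. AUROC ties: ½ credit; single-class inputs raise rather than
return a value. Bootstrap: percentile method, seeded `default_rng`;
resamples that degenerate (single-class) are skipped and counted, and an
all-degenerate bootstrap is an error. Confusion at fixed recall: the largest
threshold whose recall meets the target (predictions are score ≥ threshold).
Temporal splits: half-open intervals, boundary records join the later
period. All pipeline randomness descends from one seed via SeedSequence
spawning; identical (config, seed) runs produce byte-identical reports.

## Problem sizes

Simulation-based checks use 48-week streams at 150 episodes/week (20 seeds
for null and power estimates), 20,000-episode cohorts for the invariance
experiment, and 600 episodes/week for the pandemic-shock classification and
weekly-AUROC-shape demonstrations, where the during-period weekly bins need
enough outcomes for interval-based detection of a ~0.06 AUROC drop.

## Known limitations

- The flagging thresholds control family-wise false alarms only empirically;
  no formal sequential-testing guarantee is claimed (or possible for the
  rule as stated).
- Concept drift is inferred by elimination ("performance fell, shares did
  not move"), so a concept shift that also changes the covariate stream is
  reported as data drift with degradation.
- Share series of weakly used features are noisy at small weekly volumes;
  the persistence rule trades detection lag for false-alarm control.
- The probability-space attribution view uses a per-row chord slope; it is
  exact for local accuracy but is not the Shapley value of the
  probability-scale game.
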