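# Methods

This note documents the models, parameters and design choices behind
`rehabdss`, and what the synthetic-data experiments do and do not show.

## Scope and assumptions

The system supports Brunnstrom stages II–V and muscle tone grades
0/1/1+/2/3/4; stages I and VI are outside the rule base and rejected with
an explicit error. Muscle strength (0–5) and range of motion are recorded
in the assessment but gate no rule — this mirrors clinical practice, where
they inform the therapist but the operational tables key only on stage and
tone. The supported (stage, tone) space is not the full product: tone 0 is
only meaningful at stage II, and tones 3/4 only at stage III; other
combinations raise an unsupported-assessment error rather than guessing.

## Rule engine

The rule base is a versioned JSON resource with six rows
(stage × tone-set → weeks, mode, strength level). It is deliberately
data, not code: a clinic can ship an override file, which is validated
for non-overlapping keys against the same schema.

Two published rule tables disagree on the stage V strength level (F2 vs
F3) and on duplicated stage III week rows; the operational cycle-plan
table (stage V → resisted F3; II→1, III→2, IV→5, V→8 weeks) is taken as
authoritative, since it is the one the inference engine executes.

Days are derived as weeks × 7 capped at 21 — the cap reflects the
insurance limit on consecutive training days at a single facility. The
cap truncates rather than compresses: a stage V patient gets the first 21
days of the 8-week progression, the remainder being the next facility's
concern. Phase durations (2/10/10/2 min) and the fixed training speed
level (1) are module constants, configurable per prescription.

## Session metrics

* **Engagement** `100·(W_total − W_motor)/(W_total − W_robot)`, defined
  only when `W_total > W_robot` (otherwise the task demands no arm work
  and the ratio is meaningless — an invalid-measurement error, never a
  silent NaN).
* **Fitness** `100·R²` with `R² = 1 − SS_res/SS_tot`, where the
  normalizer `SS_tot` uses the mean of the *actual* (observed) sequence.
  A constant actual trajectory makes `SS_tot = 0` and fitness undefined.
* Both are clipped to [0, 100]: the deployed device's feature library
  shows exact 0.000 minima and 100.000 maxima, which implies clipping
  rather than raw values.
* Feature extraction computes {mean, max, min, sd, median} per signal.
  The **sample (n−1) standard deviation** is used; the convention is not
  fixed anywhere upstream, so it is fixed here and tested.
* Velocity is held in m/s internally; the 25 cm/s advancement threshold
  is converted to 0.25 m/s at the comparison site. The nominal session
  length is 12,000 samples per signal, configurable everywhere.

Session CSVs carry a `# mode=` header and either a precomputed fitness
trace or raw actual/preset positions, in which case a rolling 50-sample
R² produces the trace. The engagement trace cannot be derived from the
stream (it needs work quantities the log does not carry) and must be
present.

## Case base and retrieval

Cases are partitioned by mode and never mixed across modes, matching the
per-mode modelling throughout. Similarity is Euclidean distance on
min-max-normalized features, with bounds fit on the queried partition —
chosen for consistency with the pipeline's normalization; no published
weighting exists, so features are unweighted. Ties break on case id for
determinism. Retrieval feeds the level model and the analyst; retrieved
solutions are not adapted directly (no adaptation procedure is
published).

## Strength-level improvement model

Pipeline: min-max normalization → chi-square selection → random forest.

* Normalization maps each column onto [0, 1]; a constant column maps to 0
  with a warning (a degenerate clinical feature should not abort
  training). At predict time the training-set bounds are reapplied and
  the output clipped at 0, because chi-square-selected features must stay
  non-negative even for out-of-range test points.
* Chi-square selection keeps the k features with the largest chi-square
  statistic against the label, k = 19 of 20 by default, ties broken
  toward the lower feature index (no published tie rule). k = 19 is
  applied to all three modes.
* Random forest defaults: 54 trees, max depth 16, random seed 70. The
  comparison harness also carries logistic regression (l2, liblinear,
  C = 0.1, 1000 iterations), SVM (RBF, gamma auto, cache 5000, with
  probability estimates enabled for AUC), AdaBoost (depth-16 base trees,
  1000 estimators, learning rate 3.0) and XGBoost (340 estimators,
  colsample 0.6, learning rate 0.3, depth 3, subsample 0.7).
* Train/test protocol: seeded stratified 80/20 split (unspecified
  upstream; configurable). Decision threshold on the predicted
  probability: 0.5.
* The level-up label is treated as a given binary column of the library;
  synthetic data defines it by an explicit generative rule (below).
* Models persist as a single joblib artifact embedding the config, seed,
  selected feature names and a fingerprint of the training matrix; a
  loaded model refuses sessions whose feature schema differs.

Scalers and the k-best selection ordering are implemented in-package
because their degenerate-input and tie behaviour is part of the contract;
the chi-square scores, classifiers and evaluation metrics (accuracy,
recall, F1, trapezoidal ROC AUC) come from scikit-learn/xgboost.

## Pattern advancement

Thresholds: engagement ≥ 70 % (passive → assisted), speed ≥ 25 cm/s
(assisted → resisted), both inclusive; resisted is terminal and there is
no demotion path (only progression is specified). "Average in training"
is read as the mean over one session's samples; a configurable lookback
window (default 1 session) averages over recent sessions instead. On
advancement the strength level resets to the most conservative level the
rule base assigns the new mode (assisted → F2, resisted → F2): rule-base
levels are keyed by rehabilitation stage, not mode, so the minimum over
the mode's rows is the safe reading.

## Decision loop

Order of updates after each session: strength level first, then mode —
the system's update flow runs the level decision before the mode
decision, and on a simultaneous trigger the mode advance's level reset
wins (the level-up remains in the trace). Only future days of the plan
are rewritten; completed days are immutable. Every solved session is
appended to the case library with the level decision as its label. Extra
same-day training sets are treated as additional sessions through the
same path. Traces serialize one JSON object per decision.

Expert-panel scoring: ten raters award 0 or 5 marks for the mode and the
level of each decision; component percentages are summed marks over full
marks (50), the overall percentage over 100.

## Synthetic data

The simulator encodes only the qualitative structure the decision rules
rely on, with all parameters in `GenerationSpec`:

* a latent ability in [0, 1] per patient, incremented by a per-session
  recovery rate;
* session signal means that increase monotonically in ability
  (engagement 5 + 90·ability %, speed 0.02 + 0.15·ability m/s, fitness
  62 + 30·ability %, force 0.2 + 2.5·ability N), a small positive
  strength-level effect on engagement, and iid Gaussian noise per signal
  (sd 20 % engagement, 15 % fitness, 0.025 m/s, 1 N — chosen to put the
  session statistics on the same order as the deployed device's feature
  library, e.g. mean velocity ≈ 0.07 m/s, mean engagement ≈ 37 %);
* percent traces clipped to [0, 100], force and speed to ≥ 0;
* a level-up label defined by an explicit threshold rule on named
  features (default: mean engagement ≥ 55 and mean fitness ≥ 78) with an
  optional label-flip noise rate.

Default cohort scale mirrors the deployed system (≈50 patients, ≈10
sessions each); tests and examples use reduced sizes (hundreds of cases,
100–500 samples per session) so the full suite runs in seconds on one
CPU.

Two generators exist on purpose. `generate_case_library` simulates whole
sessions, so the 20 features inherit the physical couplings of the
signals — right for end-to-end tests. `generate_feature_library` draws
the feature matrix directly with exactly two informative columns and 18
label-independent columns (order statistics per signal kept internally
consistent) — the controlled setting in which feature selection and
hold-out accuracy have a known ground truth. On such libraries (600
cases, 5 % label noise, 20 seeds) the default pipeline reaches ≥ 90 %
mean hold-out accuracy and retains both informative features in every
seed.

What passing these tests does **not** show: the simulator has no
within-session dynamics (fatigue, warm-up effects), no inter-signal noise
correlation, no device artefacts, and its label rule is axis-aligned —
real clinical level-up decisions are noisier and need not be axis-aligned
in these 20 features. Accuracy figures on synthetic libraries therefore
validate the pipeline's mechanics, not its clinical performance.

## Numerical choices

* Sample sd (ddof = 1) throughout; chi-square ties toward lower index;
  retrieval ties toward lower case id.
* Threshold comparisons are `>=` exactly; boundary behaviour is tested by
  scanning in 0.01-unit steps around each gate.
* Fitness clips below at 0 before scaling, engagement clips to [0, 100].
* All randomness flows through `numpy.random.default_rng` seeds; refitting
  with the same library and seed is bit-reproducible.

## Known limitations

* The rule base covers six rows; rule learning or induction from data is
  out of scope.
* No case-base maintenance (forgetting/compaction) — libraries grow
  monotonically.
* The engagement trace cannot be reconstructed from session CSVs lacking
  work quantities.
* Advancement considers only the two published gates; fitness and force
  are carried in the features but gate nothing.
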