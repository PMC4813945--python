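# Methods

## The M-training procedure

M-training maintains M ≥ 3 base classifiers over a labeled pool *L* and
an unlabeled pool *U*. Diversity is created at initialization: each
classifier *cᵢ* is fitted on an independent draw, without replacement,
of `round_half_up(init_fraction · |L|)` samples of *L* (default
init_fraction 0.75). A draw that misses a class entirely is retried with
a derived substream and the retry is logged; a pool smaller than the
number of classes is an error.

Each refinement round *t* proceeds synchronously:

1. **Error estimate.** For each slot *i*, the committee *Cᵢ* (the other
   M−1 classifiers, at their start-of-round state) votes on every sample
   of *L*. Over the samples where the modal label's vote share is at
   least θ, the error bound `e_i(t)` is the fraction whose agreed label
   contradicts the true label. The committee's error on *U* is what the
   bound actually needs, but it is unobservable; *L* is used under the
   assumption that *L* and *U* are identically distributed. If no sample
   reaches θ-agreement the estimate is the uninformative 0.5 and the
   slot skips the round. (A flag switches to scoring the committee's
   plurality label on all of *L*.)
2. **Proposal.** If `e_i(t) < e_i(t−1)`, the committee votes on all of
   *U* (the previous round's pseudo-labels were implicitly returned to
   *U*: the whole pool is re-voted every round). Samples whose modal
   vote share is ≥ θ become the candidate set `L_i(t)` with that modal
   label. θ is restricted to (0.5, 1], so an accepted label is always
   the unique majority.
3. **Noise-compensation decision.** Injecting pseudo-labels adds label
   noise at rate `e_i(t)`; refitting helps only if the utility
   `u = m(1−2η)²` of the combined pool — the quantity that the
   Angluin–Laird worst-case bound `m = σξ²/(1−2η)²` holds fixed at a
   given target error — increases over the previous round. With pool
   sizes growing (`|L_i(t−1)| < |L_i(t)|`) and the injected-noise
   product shrinking (`e_i(t)|L_i(t)| < e_i(t−1)|L_i(t−1)|`), both
   factors of *u* improve. The decision is therefore:
   * **update** when the product condition holds;
   * **update after sub-sampling** `L_i(t)` down to
     `s_i = ⌈e_i(t−1)|L_i(t−1)|/e_i(t) − 1⌉` entries when it fails but
     `|L_i(t−1)| > e_i(t)/(e_i(t−1)−e_i(t))`, which guarantees both
     `e_i(t)·s_i < e_i(t−1)|L_i(t−1)|` and `s_i > |L_i(t−1)|`;
   * **skip** otherwise.
   On the first productive round `|L_i(t−1)| = 0` carries no
   information, so it is virtually bootstrapped to
   `⌊e_i(t)/(e_i(t−1)−e_i(t))⌋ + 1` before the checks — the smallest
   previous size that makes the sub-sampling route meaningful. A
   measured `e_i(t) = 0` accepts the full proposal (zero injected noise;
   the sub-sampling formula would divide by zero).
4. **Refit.** An accepted slot refits on its *own diversified pool*
   united with the pseudo-labeled set, deduplicated by sample id with
   the labeled copy winning. Uniting with the slot's pool rather than
   the full *L* keeps the diversification alive across rounds and
   matches the refined-pool accounting this design targets (initial +
   added = final, e.g. 149 + 454 = 603); a flag selects the
   full-*L* union instead.

The loop terminates at a fixed point — a round in which no slot changes
— or at `max_rounds` (default 50, recorded as the termination reason,
not an error). Prediction is a plurality vote over all M classifiers;
vote ties resolve to the lowest label in the dataset's sorted label
ordering, everywhere (committee modes face no ties because θ > 0.5).

Synchronous rounds make the result invariant to slot order; a
`sequential` flag updates each slot in place within the round instead,
recomputing committee votes per slot. Every random draw (initial pools,
sub-sampling) comes from a substream of a single root seed keyed by
(purpose, round, slot), so runs reproduce exactly regardless of M.

With M = 3 and θ = 2/3 a committee has two members and the acceptance
rule requires vote share ≥ 2/3, i.e. unanimity of the two
co-classifiers: the procedure degenerates to tri-training, which the
test suite verifies against a brute-force two-vote oracle.

## Base classifiers

The ensemble is agnostic to the base learner, which enters as a
scikit-learn estimator (anything with fit/predict), a `ClassifierSpec`,
or a kind string. Shipped kinds and their default hyperparameters:

| kind | defaults | notes |
|---|---|---|
| `svm_rbf` | γ = 0.2749, C = 0.4848 | RBF-kernel SVM, one-vs-one multi-class; the package default |
| `plsda` | 5 latent variables | PLS2 regression on one-hot indicators, argmax decision |
| `rbf_network` | goal MSE 0.4329, spread 0.0176 | greedy orthogonal-least-squares center selection, ≤ 60 neurons |
| `nearest_centroid` | — | deterministic; used for fast exact tests |

The defaults for the first three are the tuned optima of the e-nose
study this design follows; the hyperparameter-search procedure itself
(a particle-swarm optimizer) is out of scope and all values are
user-overridable. `svm_rbf` and `rbf_network` standardize features on
their training pool inside `fit`, because an RBF kernel at a fixed
width is scale-sensitive; zero-variance features are passed through
unscaled rather than failing. The SVM width convention is γ multiplying
the squared distance (`exp(−γ‖x−x′‖²)`).

Two default values deserve caveats. PLS-DA's 5 latent variables exceed
the 4-dimensional feature space of the standard sensor array, so
`n_components` is clamped to the feature dimension at fit time with a
warning. The RBF network's spread of 0.0176 is degenerate on
standardized inputs (each neuron covers essentially one training
point); tests that need a functioning network override the spread, and
practitioners should treat that default as dataset-specific.

## Data layer

Feature tables are CSV with header
`sample_id,sensor_1..sensor_F,label,concentration`; an empty label marks
an unlabeled row. Floats are serialized with `repr` and parsed with
pandas' round-trip parser, so write→read is bit-exact. Ground-truth
labels of synthetic unlabeled pools live in a separate diagnostics
table, never in the learner's input.

All fractional subset sizes use one rounding convention, round half up:
75% of 198 is 149, of 99 is 74, of 297 is 223. `split_train_test` is
stratified per class by default (75% of each gas). The
labeled/unlabeled split is simple random by default — stratification is
optional and off, since the protocol it mirrors does not state it — and
defines `unlabeled_rate = |U|/(|L|+|U|)`; a draw whose *L* misses a
class retries with a derived seed.

Raw response curves are sampled at 1 Hz over 2 min clean-air baseline,
4 min gas exposure and 9 min recovery (boundaries at 120/360/900 s,
grid inclusive of t = 0: 901 points). The per-channel feature is the
maximum response in the steady-state window, which this package defines
as the exposure phase `[baseline_end, exposure_end]` — the response
plateaus during exposure and decays in recovery, so the exposure
maximum is the plateau. No baseline subtraction is applied by default;
a `subtract_baseline_mean` option exists because practitioners often
baseline-correct, and the choice is recorded in the extraction call
site rather than hidden. Feature vectors follow the fixed channel order
TGS2620, TGS2602, TGS2201A, TGS2201B; temperature/humidity channels are
dropped with a log line, and a missing gas channel is an error naming
it.

## Synthetic benchmark

The generator emulates the *structure* of the three-gas study — class
sizes 144/132/252 from 12 experiments at each of 12/11/21 concentration
points, 4 features, stratified 75/25 train/test, unlabeled rates
{0.25, 0.5, 0.75} — not its chemistry, whose feature geometry is
unknown because the dataset was never deposited.

Two routes exist. The curve route draws per-gas response curves with a
linear concentration-to-plateau map (`sensitivity · concentration`),
saturating-exponential rise (τ_rise 20 s), exponential recovery
(τ_decay 60 s) and additive Gaussian noise, then runs the real feature
extractor; with zero noise the extracted feature equals the closed form
`baseline + sensitivity·c·(1 − e^{−240/τ_rise})` to 1e−9, which the
tests assert. Real metal-oxide sensors respond nonlinearly (power-law)
and drift; neither is modeled, so passing tests say nothing about
drift robustness. The direct route draws one 4-D Gaussian cluster per
gas with mildly anisotropic, correlated covariances.

The cluster `separation` multiplier scales class-mean deviations from
the grand mean. Its default (1.5) was calibrated once, by a small sweep
at the design conditions, so that the default M = 4 SVM ensemble starts
at 70–85% test accuracy at unlabeled rate 0.5 — overlapping enough that
refinement has headroom, separable enough that committees agree. This
constant is part of the benchmark definition and is not adjusted per
experiment.

A consequence worth stating plainly: on Gaussian clusters where train
and test share one distribution, the committee error on *L* plateaus
around 0.1–0.2, so the noise-compensation schedule admits only small
pseudo-label batches (the first-round bootstrap caps the initial batch
at a handful of samples) and typical accuracy gains are modest, with
median improvement ≥ 0 across seeds. Large gains of the kind the
algorithm can deliver arise when committees are near-perfect on *L*
(`e_i(t) → 0` unlocks the full proposal in one round), a regime real
e-nose features with tight within-gas clustering can occupy but a
deliberately overlapping Gaussian benchmark does not. The benchmark
therefore validates the machinery and its invariants, not the magnitude
of any published improvement.

## Numerical conventions

* Accuracies and Impro are reported at two decimals, round-half-up on
  the decimal representation.
* Impro = (final − initial)/initial × 100 requires initial > 0.
* The utility diagnostic compares `u_i(t)` against `u_i(t−1)` computed
  with the *virtual* previous size on bootstrap rounds; with the
  literal 0 the inequality can fail for `e_i(t)` near 0.5 even though
  the decision was sound.
* Experiment-grid cells derive their seeds from (root seed, cell index)
  via `numpy.random.SeedSequence`, and a failed cell is logged and
  skipped without aborting the grid.
* `run_experiment` aggregates by the median across seeds; a best-of-N
  selection would bias upward and is deliberately not the default.

## Known limitations

* The noise-rate bookkeeping treats `e_i(t)` as exact; it is an
  estimate on *L*, optimistic when committees overfit their pools.
* No drift correction, no transient features, no sensor physics beyond
  the saturating first-order response.
* Leave-one-out refits the model n times with no shortcut; it is meant
  for the small pools the design uses (hundreds of samples).
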