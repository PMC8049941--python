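# Methods

`apiat` implements an adaptive test of pitch-imagery ability end to end:
automatic item generation, a cognitive-feature description of every item, an
explanatory four-parameter-logistic (4PL) response model, a calibration
pipeline for fitting that model from response data, a computerized adaptive
testing (CAT) engine, and a respondent simulator that makes every stage
testable without human data. This note records the model, the defaults, and
the design decisions that were genuinely open.

## Task and item model

A trial establishes a major key (ascending scale), sounds a start note
(tonic or dominant), then shows up/down arrows. The first 3–5 arrows are
accompanied by stepwise scale tones; the remaining 1–6 arrows are silent and
their tones must be imagined. The trial ends with a sounded probe that the
respondent judges against their final imagined tone.

Items are represented in diatonic scale-step coordinates relative to the
start note (offset 0), which makes every constraint integer-exact; concrete
pitches use MIDI semitone numbers with the five admissible tonics
(C, C#, D, Eb, E) placed in the octave of middle C, tonic 60–64 and the
dominant a fifth above. The register is a representational choice — the
task's difficulty structure does not depend on it.

Constraints enforced by the generator:

* every note of the walk stays within ±4 scale steps of the start note, and
  the same bound is applied to the probe (a probe is a note of the trial;
  a config flag `range_bound` exposes the bound);
* the probe is never the start note, so a correct-probe trial requires a
  walk with nonzero net offset (the generator resamples otherwise);
* an incorrect probe lies exactly 1 or 2 steps from the true final note;
* the final silent arrow is the "hold" cue and counts as one of the
  `level` silent steps; it displays for 2 s where ordinary arrows display
  for 1 s (trial schedules expose these timings symbolically).

Walks are sampled **exactly uniformly** over the set of sign sequences that
respect the range bound, by enumerating that set once per walk length
(≤ 2^11 sequences) and drawing an index. Variation uniqueness within a
factor cell is on the (arrow sequence, probe) pair, with a retry cap of
10,000 per cell before a hard error naming the cell — some cells are tight
(a correct-probe level-1/heard-3 cell has exactly 10 valid variations).

The calibration bank crosses 5 levels × 3 heard counts × 2 start degrees ×
2 probe accuracies × 5 keys = 300 cells × 10 variations = 3000 items; the
extension adds the same grid at level 6 (600 items) to raise the difficulty
ceiling, for a 3600-item adaptive bank.

## Item features

Six predictors per item: `Level` (silent-arrow count), `Heard_Range`
(count of unique tones sounded during set-up, start note included),
`ProbabilityProbe_LastHeard` (empirical probability of the signed distance
between last heard note and probe over a reference bank),
`ProbeTrueIm_AbsDiff` (|probe − true final|, 0 / {1,2} by probe accuracy),
`Probability_Probe` (empirical probability of the probe offset among bank
items with the same total arrow count), and `ProbeNote_is_StartNote`
(always false for generated banks, kept for external data).

Two decisions worth recording. The distance table is **signed** by default:
direction and parity both carry information (with an even number of imagined
steps the true probe must sit an even distance from the last heard note);
`absolute=True` folds the sign for sensitivity analyses. Heard range is
implemented as a unique-tone **count**; for strictly stepwise walks the
min–max span equals count − 1, so the two definitions differ only by an
affine shift absorbed by the intercept. Probability features are raw
relative frequencies with no smoothing — an unseen value scores 0, matching
the empirical-frequency definition. The extension bank's tables are computed
over the combined 3600 items by default (tables are an explicit argument
everywhere, so any reference bank can be substituted).

## Response model

P(correct | θ, b) = c + (d − c) · logistic(a(θ − b)), with guessing floor
c = 0.3 and inattention ceiling d = 0.95 (the task is a two-alternative
judgement with demonstrated floor/ceiling behaviour), constant
discrimination a = 1 (Rasch-style unit discrimination; the logistic is in
the natural metric, no 1.7 factor), and explanatory difficulty b = −η/s,
where η is the item's linear "easiness" predictor and s rescales difficulty
to the ability SD of a calibration sample (default 1 until a sample supplies
an estimate).

η uses the joint interaction parameterization: a shared intercept plus
branch-specific coefficients chosen by probe accuracy —
`correct:{ProbabilityProbe_LastHeard, Level, Heard_Range}` and
`incorrect:{ProbabilityProbe_LastHeard, Level, ProbeTrueIm_AbsDiff,
Heard_Range}`. The default coefficient values are the fitted calibration
model (intercept −0.918; correct: 2.778, −0.176, 0.157; incorrect: 0.228,
−0.157, 1.151, −0.553). Signs encode the cognitive story: more imagined
tones are harder on both branches; high-probability probes and large heard
ranges pull responses toward "match", which helps on correct probes and
hurts on incorrect ones; a 2-step-wrong probe is easier to reject than a
1-step-wrong one.

## Calibration fitting

The observation model for fitting is the same curve with a random
participant intercept inside the logistic: P = c + (d−c)·logistic(Xβ + u_p),
u_p ~ N(0, σ²). The marginal likelihood integrates u_p per participant with
15-node Gauss–Hermite quadrature and is maximized by L-BFGS-B with an
analytic gradient (posterior-node-weighted score sums); σ is optimized
directly on [0, 10]. No installed mixed-model routine accepts the
floor/ceiling-modified link, hence the in-package implementation; the
c = 0, d = 1, σ = 0 limiting case is pinned against an ordinary logistic
regression to 1e-4 in the tests, and the gradient against finite
differences. Joint standard errors come from the inverse numerical Hessian
at the optimum. Participant effects are reported as posterior means (used
for within-sample prediction in cross-validation). Non-convergence is
flagged on the result object, never silent; all-identical responses raise.

Around the core fit:

* **Asymptote search** profiles the likelihood over a (c, d) grid (default
  c ∈ {0, .05, …, .5}, d ∈ {.8, .85, …, 1}), warm-starting each fit from
  the previous optimum. Grids rather than joint gradient ascent because the
  profile surface is flat and bounded; the tests accordingly assert recovery
  to the generating grid point *or an adjacent cell*.
* **Screening** ranks candidate predictors by permutation importance of a
  random-forest classifier on a held-out 30% split — one seeded
  implementation standing in for the several forest-importance variants in
  the literature.
* **Best-subset search** enumerates all 2^k subsets (null model included)
  under a configurable budget and returns the minimal-BIC fit plus the full
  table. Per-subset asymptote re-optimization is available via
  `search_asymptotes=True` but defaults off: it multiplies each subset's
  cost by the grid size while the profile is flat enough that fixed
  asymptotes rank subsets identically in practice.
* **Cross-validated accuracy** is mean held-out 0/1 accuracy at threshold
  0.5, folds stratified on the response; `with_participant_effects`
  toggles whether the training-fold posterior-mean effect of a participant
  is added at prediction time (unseen participants get 0).

## Adaptive engine

Interim ability after each response is the Bayes modal (MAP) estimate under
a standard-Normal prior — the prior matches the difficulty-scaling
convention that one difficulty unit is one ability SD. Item selection is
Urry's rule: the unused item with difficulty nearest the interim estimate,
exact ties broken uniformly with the session generator; with no responses
the MAP is the prior mode 0, so the first item is the unused item nearest
b = 0. No exposure control or content balancing is imposed. The default
session length is 25 items.

The final score is Warm's weighted-likelihood estimate, implemented as the
maximizer of log L(θ) + ½·log I(θ) on [−4, 4] — for constant-discrimination
models this coincides with the root of the bias-corrected score equation,
and the maximizer form remains well-defined for all-correct/all-wrong
patterns where the score equation has no interior root (the estimate is
then the clamped boundary value, flagged `at_boundary`). Both MAP and WLE
use a coarse bracketing grid (81 / 161 points) followed by bounded Brent
refinement to tolerance 1e-6; the tests pin both against 4001-point grid
oracles at 1e-3 / 2e-3. Standard errors are 1/√I from expected Fisher
information at the estimate (MAP adds the prior precision).

## Simulator and what passing tests show

Simulated respondents have Normal latent abilities and answer with the 4PL
probability at their true ability — stationary by construction: no
learning, fatigue, warm-up, or retest effects, and no covariates such as
musical training. Test–retest reliability is simulated as two independent
adaptive sessions per respondent from independent streams over the same
bank. Passing recovery and reliability tests therefore demonstrate the
internal consistency of the measurement chain (generator → features →
difficulty model → CAT → scoring), not robustness to the practice effects,
attention lapses, or construct drift real respondents exhibit; the observed
simulated mean standard errors (≈ 0.6–0.7 at 25 items) should be read as a
lower bound on real-data measurement error.

Problem sizes used in the shipped experiments: coefficient recovery refits
20 replicates of 200 participants × 30 items (6 per level, quasi-random
order); reliability curves use 200-respondent cohorts at test lengths
5–25; asymptote checks use 10,000 Bernoulli draws per extreme. These sizes
give sampling noise comfortably below the tolerances asserted.

## Numerical and degenerate-input choices

* Seeds: every randomized function takes an explicit seed or Generator;
  identical config + seed reproduces banks byte-for-byte.
* Empty response sets: MAP returns the prior mode; WLE raises (no
  information to weight).
* Tie-breaks in item selection use a 1e-12 absolute tolerance on the
  difficulty distance before uniform choice.
* The likelihood is finite on any bounded ability interval whenever
  0 < c and d < 1; with c = 0 or d = 1 the bounded search domain keeps the
  optimizers safe.
* BIC is −2·logL + k·log(n_obs) with k the free parameters of the fit;
  a profiled asymptote search adds 2 to k for its result.

## Known limitations

* Difficulty is wholly model-implied (explanatory IRT): per-item
  discrimination/guessing estimation is out of scope, so item misfit is
  invisible to the engine.
* The published asymptotes of the final calibration model and the numeric
  ability-SD used for difficulty scaling are not public; defaults are
  c = 0.3, d = 0.95, s = 1, all config-exposed.
* The generated bank's difficulty distribution is bounded (roughly −0.2 to
  3.3 at default coefficients), so very low abilities are measured with
  larger standard errors than mid-range ones.
* Audio/video stimulus rendering and test delivery are out of scope; items
  are symbolic (key, walk, probe, schedule).
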