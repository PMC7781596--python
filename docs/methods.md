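# Methods

This document records the models implemented by `flexgoal`, the assumptions
behind them, the default parameters, what the synthetic-session generator can
and cannot claim about realism, and the numerical choices made in the
analysis battery.  Problem sizes throughout (trial counts, cell counts,
seed counts) are the package's own defaults, chosen so that every analysis
has adequate statistical power while the full test suite and the summary
battery each run in minutes on a single CPU.

## 1. Task model

### 1.1 Trial structure

A session is a sequence of trials of a flexible spatial working-memory task
with three start ports, three goal locations and three routes
(multi-start / multi-goal / multi-route, MSMGMR).  Each trial has:

* a **sample phase** — the animal is shown the trial's goal and returns to
  the center;
* a **delay** — a nose poke at one of three start ports, 3 s by default;
* a **test phase** — on route availability the animal runs one of three
  routes toward its chosen goal.

Event times per trial (`ALIGNMENT_EVENTS`): `sample_goal_arrival`,
`center_arrival`, `delay_on`, `route_available` (= delay off),
`choice_entry`, `test_goal_arrival`.

### 1.2 Pseudorandom balanced sequences

`generate_trial_sequence(n_blocks, ...)` produces blocks of 27 trials in
which every (start, goal, route) combination appears exactly once.  The
block is built from the algebraic partition of the 27 combinations into
three 9-trial subblocks by `(start + goal + route) mod 3`; each subblock is
itself balanced (each start, goal and route appears three times).  Within
this structure the generator enforces, by rejection sampling with
per-subblock shuffles (up to `max_retries = 50` resamples):

* **no three consecutive same-goal trials**, including across subblock and
  block boundaries;
* **per-subblock sample-route coverage**: within each 9-trial subblock,
  each goal's three trials use three different sample routes.

Choices are correct with probability `accuracy = 0.7737` (independent
Bernoulli); errors pick one of the two wrong goals uniformly.  The test
suite verifies the constraints hold for 1000 consecutive seeds.

Default session size is `n_blocks = 4` (108 trials): the smallest size at
which leave-one-out decoding with per-(start × goal) stratification is
always well posed (≥ 12 trials per cell of the 3 × 3 design, see §4.3) and
binomial chance bands are usefully narrow (95 % band ≈ 0.24–0.43 for a
3-class problem at n = 108).

## 2. Neural data generator

### 2.1 Spike trains

Each unit is an inhomogeneous Poisson process.  A unit's rate function is
a baseline (`base_rate = 3 Hz` for principal cells) multiplied by
selectivity gains (`gain = 3`) over smooth trial-epoch envelopes
(Gaussian-bump onsets/offsets, principal width 0.65 s).  Cell classes,
assigned by `SelectivityConfig` fractions:

* **goal cells** — gain when the trial's goal matches the cell's preferred
  goal; optionally restricted to a window after goal arrival
  (`goal_arrival_window = 3 s`);
* **start cells** — gain keyed to the start port, active through the delay;
* **egocentric cells** — keyed to the start→goal relation (invariant to
  joint rotation of start and goal), with configurable angular offset;
* **conjunctive cells** — keyed to a specific (start, goal) pair;
* **sequence cells** — a Gaussian field (σ configurable) at a fixed latency
  within the delay, giving a population sweep;
* **drift cells** — rate ramps across the session, used to exercise the
  stability screen;
* **interneurons** — high rate (25 Hz), narrow waveform (0.22 ms), no
  task selectivity.

Every generated session returns a ground-truth record (`cell_class`,
preferred conditions), so analyses are tested as recover-the-injection
properties.

### 2.2 LFP and phase coding

LFP is synthesized per channel (16 channels, 2-channel spacing by default,
`lfp_fs = 2500 Hz`) as a sum of band-limited oscillations — slow (3.5 Hz),
theta (8 Hz), beta (22 Hz) — plus pink noise.  Phase-locked units
(`phase_lock` entries `(cell, band, kappa, pref_phase, goal_specific)`)
emit spikes whose phases are von Mises around the preferred phase; with
`goal_specific = True` the preferred phase rotates by 2π/3 per goal,
creating a pure phase code with no rate information — the construction the
phase battery is validated against.

Band phase offsets are seeded from a CRC32 of the band name (not Python's
process-salted `hash`), so sessions are bit-reproducible across processes.

### 2.3 Tracking

Two-LED head tracking at 30 Hz with Gaussian positional noise (0.1 of a
port radius).  During the delay the animal is stationary at the start port
(jittered around it), so tracking is start-informative and goal-free by
construction; after route availability the trajectory moves toward the
chosen goal, so goal identity becomes readable from position within tens of
milliseconds.  This is the positive/negative control pair for the
behavioral-confound analysis (§4.6).

### 2.4 Realism and limits

The generator is a *statistical* model adequate for validating analysis
code, not a biophysical one:

* Poisson spiking — no refractoriness, bursting or spike-history effects;
  count variance is exactly Poisson, so real overdispersion would widen
  empirical null bands slightly.
* LFP is a low-dimensional oscillation mixture; no current-source
  geometry, volume conduction model or spike leakage into the LFP.
* Spike–LFP coupling is imposed directly on spike phases rather than
  emerging from a network model.
* Tracking kinematics are piecewise-smooth interpolations, not a
  locomotor model; there is no micro-behavior (head sweeps, whisking)
  beyond optional vicarious-trial-and-error-like slow-downs used by the
  VTE detector tests.
* Behavioral accuracy is i.i.d. Bernoulli; no learning curves,
  perseveration or win-stay/lose-shift structure.

## 3. Cell selection

`select_cells` applies, in order:

1. **interneuron filter** — waveform width and mean-rate thresholds
   (narrow, fast-spiking units are excluded);
2. **activity filter** — a minimum number of active trials (a cell must
   fire in more than 1/6 of trials, i.e. ≥ 18 of 108);
3. **stability filter** — a session-halves rate comparison; cells whose
   standardized first-half/second-half rate difference exceeds the
   threshold (drifting cells) are excluded.  A flat cell scores exactly
   z = 0 and always survives.

The suite checks each filter against analytic constructions (exact
boundary counts, ramps with known fit differences).

## 4. Analysis battery

### 4.1 Behavior

`performance_summary` reports overall accuracy and splits by goal and by
sample/test route congruence, with percentile-bootstrap CIs (2000
resamples).  `detect_vte` flags trials with slow, multi-directional
choice-point passes.

### 4.2 Population-vector correlation decoding

Trial-wise population vectors are delay-period spike counts (per-bin or
whole-delay, binwidths 0.1–3 s).  A held-out trial is assigned the class
whose leave-one-out template (mean PV excluding the held-out trial)
has the highest Pearson correlation with it; `mode="mean"` averages
per-bin correlations, `mode="majority"` takes a per-bin vote.  The
correlation and decision primitives are tested for exact agreement with
`scipy.stats.pearsonr` and brute-force argmax over random micro-instances.

### 4.3 Classifier decoding and the crossed-design correction

`delay_decoding` / `time_resolved_decoding` run leave-one-out CV with
logistic regression, RBF SVM, Gaussian naive Bayes, or random forest
(1000 trees, all features by default; configurable).  Features are
z-scored with statistics fit on the training fold only.

**Anti-learning in crossed designs.**  With plain per-class balancing,
LOO deletion of the held-out trial leaves its class under-represented
*within its start group*.  If the population carries a strong start code
and no goal code, a deterministic classifier keys on start and
systematically votes against the held-out trial's goal — measured at
0.15–0.20 accuracy where chance is 1/3.  The fix: training folds are
balanced per (nuisance-group × class) cell — starts are the nuisance for
goal/egocentric decoding, goals for start decoding.  After the fix,
null-session goal decoding is unbiased: across 50 held-out sessions the
mean accuracy was 0.332 against a chance of 1/3 (t = −0.17).  When a
session is too small to populate every (group, class) cell twice, the
decoder warns and falls back to plain class balancing.

**Chance bands.**  Per-session LOO accuracies have a standard deviation
of ≈ 0.08 at n = 108 — about 1.6× the binomial σ = 0.052 — because LOO
folds share training data and cells share the session's trial sequence.
Pooling trials across sessions therefore *understates* the variance of
the pooled accuracy.  Calibration checks consequently compare the
**across-seed mean** of per-session accuracies against the central 95 %
binomial band for a single session (n = 108), rather than treating pooled
trials as independent.  This reading still rejects genuinely biased
decoders by a wide margin (a deliberately unstratified SVM scores
0.15–0.20, far below the band's lower edge ≈ 0.24).

### 4.4 Single-cell statistics

Per-cell Kruskal–Wallis H on delay spike counts across the three classes,
with tie correction (verified against `scipy.stats.kruskal` to 1e-10 and a
textbook exact case, H = 7.2).  Multiple comparisons across cells are
controlled with Benjamini–Hochberg FDR (α = 0.05, via
`statsmodels.stats.multitest`, property-tested against an independent
implementation of the step-up rule).  On Poisson null data the
false-discovery fraction is verified ≤ α within Monte-Carlo error; on
sessions with injected goal cells recall exceeds 0.8.

### 4.5 Phase analysis

Band phases come from zero-phase FIR filtering (Hamming window, order
scaled to the band's low edge) plus the Hilbert analytic signal.  Per-cell
delay-spike phase distributions are tested with the Rayleigh statistic;
goal dependence of preferred phase uses a permutation test that shuffles
goal labels over trials (default 100 shuffles; type-I error verified at
0.04 over 200 null runs with 99 shuffles each).  `phase_bin_decoding`
decodes the goal from phase-histogram features (6 bins per cell) with the
same stratified LOO machinery; on a pure phase code (κ = 3, goal-specific
preferred phases) it reaches accuracy 1.0 while rate decoding of the same
session stays inside the chance band.  Von Mises concentration recovery is
accurate to < 0.01 in mean resultant length at κ = 2.

### 4.6 Pairwise synchrony (CCSI)

For each cell pair, cross-covariance of delay spike trains is corrected by
a jitter surrogate (spikes jittered within small windows), isolating
fine-timescale synchrony.  The cross-correlation synchrony index (CCSI)
contrasts corrected synchrony in each pair's *preferred-goal* trials
against the rest, aggregated over pairs with a bootstrap CI (500
resamples).  Validation uses constructed trains: shared 2 ms-jittered
events injected only in preferred windows must give CIs excluding zero
(positive arm), while events injected in all windows (exchangeable arm)
must not.

### 4.7 Tracking decoding

`time_resolved_decoding` on tracking features (position, heading) in
sliding 0.33 s windows around route availability.  Windows fully inside
the delay must decode the goal at chance (Šidák-corrected one-sided
binomial bounds across windows); windows after divergence (≥ 0.5 s)
must decode it nearly perfectly.  This quantifies how quickly overt
behavior reveals the choice and bounds what a "neural" goal code could
inherit from behavior.

### 4.8 Embedding report

Task-location population vectors (per start, goal and route-segment
occupancy) are embedded with t-SNE (multiple restarts, best
Kullback–Leibler divergence kept) and summarized with a silhouette score
over location-type labels, plus a text report of nearest-neighbor
structure.

## 5. Numerical and reproducibility choices

* **Seeding** — all randomness flows through `numpy` `SeedSequence`
  streams keyed by (seed, stream-name constant, indices).  String-derived
  keys use CRC32, never the process-salted builtin `hash`, so results are
  identical across processes and platforms.
* **Binomial bands** — chance bands use exact binomial quantiles
  (`scipy.stats.binom`), not normal approximations; family-wise bounds
  across time windows use Šidák correction.
* **Bootstrap** — percentile bootstrap throughout (2000 resamples for
  behavior, 500 for CCSI); adequate for the CI widths tested.
* **Filtering** — FIR rather than IIR for band-phase extraction to keep
  phase response exactly linear; applied forward-backward for zero phase.
* **Sizes** — defaults (108 trials, 90 cells, 16 LFP channels at 2.5 kHz,
  seed counts of 3–20 per calibration cell) are chosen so the complete
  test suite runs in ~6 minutes and the summary battery
  (`scripts/acceptance.py`) in ~2 minutes on one CPU, while keeping
  Monte-Carlo error well below every tested margin.
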