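# flexgoal

Synthetic sessions of a flexible spatial working-memory task and the
population-analysis battery used to ask one question of them: **during a
memory delay, which task variables are actually present in prefrontal-style
population activity — the remembered goal, or the current start location?**

## The problem

In a multi-start / multi-goal / multi-route (MSMGMR) task, an animal learns
a goal location in a sample phase, holds it over a 3 s nose-poke delay at
one of three start ports, and then navigates to the goal over one of three
routes.  A natural hypothesis is that delay-period spiking carries a
persistent goal code.  Testing that hypothesis fairly is mostly a problem
of *negative controls*: decoders must be demonstrably calibrated at chance
when no goal information exists, positive controls (the start port, which
the animal is physically at) must decode nearly perfectly from the same
data, and alternative carriers of the memory — firing-phase codes, transient
pairwise synchrony, behavioral cues in the tracking — need their own
dedicated statistics.

`flexgoal` provides both sides of that test:

* a **ground-truth generator** of complete sessions (balanced pseudorandom
  trial sequences, inhomogeneous-Poisson spike trains with configurable
  selectivity, multi-channel LFP, two-LED tracking), where the true encoding
  of every cell is known; and
* the **analysis battery**: population-vector correlation decoding,
  Kruskal–Wallis/FDR selectivity screening, LOO-CV classification (logistic
  regression, RBF SVM, random forest, naive Bayes), LFP phase-of-firing
  statistics with Rayleigh and shuffle tests, jitter-corrected spike
  cross-covariance with a cross-correlation synchrony index (CCSI), t-SNE
  task-structure embeddings, and cell-stability/interneuron filters.

Because the generator is ground-truthed, every analysis is validated as a
property: decoders recover injected codes and stay at chance without them.

## A methodological note: LOO cross-validation in crossed designs

The task design crosses start and goal.  When a nuisance factor (the start)
is strongly decodable and the label of interest (the goal) is not, plain
leave-one-out cross-validation with class balancing drives deterministic
classifiers *below* chance: deleting the held-out trial under-represents its
label within its start group, and a start-keyed classifier systematically
votes against it.  `flexgoal`'s decoders therefore balance training folds
per (nuisance-group × class) cell, which restores chance-level calibration
on goal-free data.  See `docs/methods.md` for the analysis.

## Worked example

The central dissociation, in a few lines — a session whose cells encode the
start port but carry no goal information:

```python
import flexgoal as fg
from flexgoal.decoding import ClassifierSpec, delay_decoding
from flexgoal.pv_analysis import correlation_decode

# a 108-trial session whose cells encode the start port but not the goal
trials = fg.generate_trial_sequence(n_blocks=4, seed=7)
config = fg.SelectivityConfig(n_cells=90, frac_start_cells=0.3, seed=7,
                              with_lfp=False)
session, truth = fg.generate_session(trials, config)
print(f"{len(trials)} trials, {len(session.units)} cells, "
      f"behavioral accuracy {trials.correct.mean():.3f}")

for target in ("start", "goal"):
    corr = correlation_decode(session, target, binwidth=0.75)
    lr = delay_decoding(session, target, binwidth=0.75,
                        spec=ClassifierSpec("lr"), seed=7)
    print(f"{target:5s}  correlation decoder: {corr.accuracy:.3f}   "
          f"logistic regression: {lr.accuracy:.3f}")
```

Output:

```
108 trials, 90 cells, behavioral accuracy 0.769
start  correlation decoder: 1.000   logistic regression: 1.000
goal   correlation decoder: 0.337   logistic regression: 0.363
```

The start is read out perfectly from delay activity; the goal sits at the
3-class chance level — the dissociation the battery is built to test.

## Command line

Every stage is also a CLI subcommand (`flexgoal --help`):

```bash
flexgoal simulate --out session/ --seed 3 --n-blocks 4
flexgoal select-cells --session session/
flexgoal behavior --session session/
flexgoal decode --session session/ --target goal
flexgoal phase --session session/
flexgoal covariance --session session/
flexgoal report --session session/ --seed 1
flexgoal all --config cfg.yaml          # the full battery, timing to stderr
```

## Reproduction

All randomness flows from named, independently seeded RNG streams, so any
session and any analysis is reproducible from its seed alone (independent
of process and platform hash state).  The summary battery used for release
checks runs end to end with:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which writes one JSON object per metric (`{"value": ..., "n": ...}`) and
logs per-stage progress to stderr (about two minutes on one CPU).  The
test suite (`tests/`) carries the full property battery: decoder
calibration bands, oracle equivalence against brute-force implementations,
filter survival against analytic theory, 1000-seed trial-design constraint
sweeps, and phase/synchrony recovery against von Mises and jitter
constructions.
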