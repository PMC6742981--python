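# revlearn

Trial-level analysis and simulation of operant spatial reversal learning.

Two-choice spatial reversal tasks are a workhorse assay for learning rate,
behavioral flexibility, impulsivity and attention in rodent models — e.g.
phenotyping mouse models of sex-chromosome aneuploidy, where perseverative
responding after a contingency reversal is a key endpoint.  A mouse first
acquires a left/right discrimination (center observing poke → two lit target
apertures → one side rewarded) to a criterion of 80% correct within a
20-trial sliding window inside a single daily session; the rewarded side
then swaps and training continues to the same criterion.

`revlearn` provides, as a reusable Python library:

* **the trial-level data model and I/O** — a tidy one-row-per-trial CSV
  format, a timestamped chamber event-log dialect, and a parser that
  reconstructs trials (choices, outcomes, three latencies, premature /
  extraneous-observing / observing-timeout counts) from raw events;
* **a generative simulator** of the task and of parameterized agents, so
  every analysis stage is exercisable without animal data;
* **the behavioral measures** computed per subject × phase;
* **long-format aggregation** crossing the study's factors, ready for any
  generalized-estimating-equations (GEE) routine, plus pre-model statistics
  (transformation selection by normality testing, Bonferroni correction,
  measure correlations).

## The measures

For a phase's response-trial sequence (omissions excluded), with cumulative
correct-response curve *C(t)*:

* **Trials to criterion** — response trials until the first 20-trial window
  (within one session) reaches 80% correct; the window-completing trial is
  counted.
* **Change point (CP)** — the trial maximizing *d(t) = L(t) − C(t)*, where
  *L(t)* is the straight line through the first and last points of *C*; it
  bisects the phase into PRE and POST fractions.
* **FS (flexibility–stability score)** — `FS = p(Lose-Shift) − p(Win-Stay)`:
  the proportion of trials correct after unrewarded trials minus the
  proportion correct after rewarded ones.  Positive FS = accuracy driven by
  shifting after losses; negative = by staying after wins.
* **MAXCI** — the maximum number of consecutive incorrect responses;
  operational index of perseveration.
* **Regress score** — a one-trial-step moving window compares each
  prior-5-trial block with the next 5 trials; accuracy *declines* are summed
  and normalized by the number of trials: an index of regressive
  (non-perseverative) error.
* Per PRE/POST fraction: error rate, premature responses per trial by side
  role (C_ACQ = correct-in-acquisition side, C_REV = its opposite),
  initiation / target-response / reward-retrieval latencies (initiation
  additionally by prior-trial outcome), extraneous observing responses,
  observing-response timeouts, and omissions per trial.

The simulated agent is a two-armed softmax Q-learner augmented with a slow
reinforcement-habit trace (perseveration), an innate side-alternation bias
that fades as the habit consolidates, a habit-scaled win-stay bonus, and an
outcome-coupled inattentive state that makes errors arrive in bouts — the
minimal structure that reproduces the task's universal effects (reversal
cost, error-dense PRE fractions, FS declining from positive PRE to negative
POST, habit-strength-dependent perseveration).  See `docs/methods.md`.

## Worked example

```sh
python examples/02_phase_metrics.py
```

prints, for one simulated subject (seed 23):

```
--- REV ---
trials to criterion : 61
change point (1st POST trial): 43
MAXCI (perseveration): 12   regress score: 0.0885
  PRE: 42 response trials, errors/trial 0.67, FS -0.241, premature/trial C_ACQ 0.64 C_REV 0.40
  POST: 19 response trials, errors/trial 0.16, FS +0.133, premature/trial C_ACQ 0.42 C_REV 0.53
  POST initiation latency: 7.9 s after losses vs 23.7 s after wins (faster restart after nonreward)
```

Reading it: this subject needed 61 response trials to re-reach criterion
after the reversal (vs 20 in acquisition), opened the phase with a 12-trial
perseverative error run, and the learning curve's change point sits at
trial 43 — 42 error-dense PRE trials (67% errors, many premature pokes to
the previously correct side C_ACQ) followed by 19 POST trials at 16% errors.
Trial-initiation latencies are roughly 3× shorter after unrewarded trials,
the task's signature motivational effect.

The other examples cover single-subject simulation and raw trial streams
(`01`), the full cohort pipeline with long-table aggregation and measure
correlations (`03`), and file-format round trips including event-log
reconstruction (`04`).  A thin CLI mirrors the pipeline:

```sh
revlearn simulate --out trials.csv --events events.log --seed 17 --n-per-group 4
revlearn analyze --trials trials.csv --out metrics.csv
revlearn summarize --trials trials.csv --out cells
revlearn stats --trials trials.csv --transforms-out transforms.csv --correlations-out corr.csv
revlearn export-gee --trials trials.csv --out-prefix gee
```

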