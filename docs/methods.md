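# Methods

## Task model

The simulated task is a two-alternative spatial discrimination with an
observing response.  A trial begins at the end of the inter-trial interval
(ITI, 3 s) with the center aperture lit; the subject must nose-poke the
center and sustain the poke for a required holding duration (RHD, drawn per
trial from {1, 10, 20} centiseconds).  A failed hold is an
observing-response timeout (ORTO, 2 s) and the trial continues with another
attempt.  A successful hold lights the two flanking target apertures; a poke
into the currently rewarded side delivers a pellet, a poke into the other
side triggers a 5-s timeout, and the absence of any target poke within 30 s
is an omission (5-s timeout).  Pokes into unlit target apertures before
target onset are premature responses, attributed to their physical side;
center pokes while the targets are lit are extraneous observing responses
(EOR).  Acquisition (ACQ) runs in daily sessions (fixed at 120 trials as a
proxy for the ~1-h session; wall-clock session length is not reproducible)
until the criterion — 80% correct within a 20-trial sliding window of
response trials inside a single session — is met; the running session is
then completed (the phase switch happens "the next day"), which overtrains
the learned response.  Reversal (REV) swaps the rewarded side and runs under
identical contingencies and criterion.  A guard of 20 sessions per phase
marks non-learners; their series are flagged rather than rejected.

Criterion detection during simulation calls the same
`trials_to_criterion` routine the analysis uses, applied incrementally to
the newest window, so simulator and analysis cannot disagree about when
criterion occurred.

## Agent model

Choice is a softmax over side logits

    z(s) = β·Q(s) + κ·H(s) + biases(s)

with, per response trial with reward r ∈ {0, 1}:

* **Values** — `Q(chosen) += α (r − Q(chosen))`, Q initialized at 0.5/0.5
  (override available for deterministic tests).
* **Habit trace** — `H(chosen) += ρ⁺ (1 − H(chosen))` on reward,
  `H(chosen) −= ρ⁻ H(chosen)` on nonreward, with build rate ρ⁺ = 0.12 far
  above decay ρ⁻ = 0.02: habits form with reinforcement and resist
  extinction.  κ (perseveration weight) scales the habit's pull.  At
  reversal H still points at the old side, producing the opening
  perseverative bout whose length MAXCI measures; because the trace decays
  slowly, the bout length grows with κ (this breaks if perseveration is
  modeled as a "last-reinforced-side" bonus, which flips instantly at the
  first reversal reward and acts as an oracle).
* **Exploration biases**, gated by `1 − max(H)` so they fade as the habit
  consolidates: an unconditional side-alternation bias (1.4) — rodents'
  spontaneous alternation, which is what puts early win-stay probability
  *below* chance and therefore makes FS positive before the change point —
  and an extra lose-shift bonus (0.4) after nonreward.
* **Win-stay bias** (2.2), scaled by `H(previous choice)`: the tendency to
  repeat a just-rewarded response tracks the habit strength of *that*
  response, so a win on a newly rewarded side earns no stay bonus until its
  habit forms.  (Scaling by the maximum habit instead lets the old side's
  habit subsidize staying on the new side right after reversal, and the FS
  decline inside the reversal phase disappears.)
* **Attention** — an outcome-coupled two-state process: a reward re-engages
  the subject; after nonreward a disengaged state is entered with
  probability 0.20 and persists with probability 0.70.  Disengaged choices
  repeat the previous response with probability 0.90, else poke at random.
  Errors therefore cluster into self-sustaining bouts, which is what drives
  accuracy after errors *below* accuracy after rewards late in learning
  (negative FS after the change point) and produces the regressive slips
  the regress score quantifies.

Defaults (α = 0.03, β = 3.0, κ = 1.0 and the figures above) were fixed once
so that the generator exhibits the task's universal within-subject effects
— reversal costs more trials than acquisition; error rates higher PRE than
POST in both phases; FS declining from positive PRE to negative POST; mean
reversal MAXCI increasing monotonically in κ — at cohort sizes of 200
subjects, verified on seed ranges disjoint from those used anywhere in the
tests.  Typical defaults yield ~25 (ACQ) and ~50 (REV) response trials to
criterion.

Ancillary behavior: omissions are Bernoulli per trial (0.03); premature
counts are gamma–Poisson (over-dispersed, mean 0.8/trial) split across
sides by the agent's current side preference, so premature pokes migrate
from the old to the new correct side across reversal; EOR is Poisson (0.3);
observing failures are Bernoulli per attempt (0.15).  Latencies are
log-normal parameterized by their arithmetic mean — initiation 12.0 s
after unrewarded vs 29.5 s after rewarded trials (the task's motivational
signature; a phase's first trial, which has no prior outcome, uses the
geometric mean of the two), target response with a mean that shrinks as the
value gap grows (capped at the 30-s window), retrieval 1.5 s.

## Analysis conventions

* Omission trials carry a trial index but are excluded from all
  choice-sequence measures (criterion, CP, FS, MAXCI, regress); they count
  toward omissions-per-presented-trial, and their premature/EOR/ORTO counts
  fold into their fraction's rates.
* Phase metrics are computed on the phase truncated at the
  criterion-completing trial, so PRE + POST response counts equal trials to
  criterion; non-criterion series are analyzed in full and flagged.
* The change point is the trial of maximal (signed) deviation between the
  cumulative correct curve and its end-to-end chord — signed, because
  acquisition curves sag below the chord before the learning step; that
  trial is the first POST trial.  Ties resolve to the earliest trial with a
  1e-9 tolerance so exact rational ties are not broken by float noise.  A
  curve whose deviation never exceeds zero (e.g. ceiling performance) is
  degenerate: the whole phase is POST.  Note that prepending trials to a
  sequence changes the chord, so change-point indices are not translation
  invariants; tests assert planted-step localization instead.
* The regress score slides its 5-trial blocks one trial at a time (a
  non-overlapping-block variant ships behind `sliding=False`; it weighs
  isolated dips more coarsely and is kept for sensitivity analysis).
* Within-split FS uses consecutive response-trial pairs lying inside the
  split; the pair straddling the PRE/POST boundary is dropped.  An FS
  component with an empty denominator makes FS absent rather than imputing
  zero; aggregation propagates absence as NaN and summaries count non-absent
  values.
* Initiation-latency-by-prior-outcome cells at the phase level recombine
  the PRE/POST fractions weighted by their trial counts, so no trial is
  touched twice.
* Male (XY vs XXY) and female (XX vs XO) cohorts are never pooled; the long
  table is emitted per sex model.  Premature counts are exported raw — the
  log10(y+1) display transform belongs to plotting, never to the data
  layer.

## Pre-model statistics

Transformation selection tests each candidate (identity, log, sqrt; the
latter two applied to x+1 when zeros are present) for normality with the
Lilliefors-corrected Kolmogorov–Smirnov test (parameters estimated from the
sample; a plain standardized KS is available via `exact_ks=True`) and keeps
the candidate with the highest p-value; when every candidate rejects at
0.05 on non-negative right-skewed data — typical for premature-response and
omission counts — a gamma distribution with log link is recommended
instead of a transform.  Post hoc families use Bonferroni (`min(1, p·m)`).
Measure correlations default to Pearson (Spearman available); groups with
fewer than 4 complete observations return absence with a reason.  GEE
fitting itself is deliberately out of scope: `export_gee` writes the long
table untransformed plus a JSON sidecar naming the chosen link per measure,
which any standard GEE implementation (e.g. `statsmodels.GEE`, SPSS, R
`geepack`) consumes directly.

## What the generator does and does not emulate

The simulator reproduces the statistical structure the analysis assumes:
criterion-terminated phases with session boundaries, perseverative and
regressive error regimes, win-stay/lose-shift dynamics, outcome-dependent
initiation latencies, over-dispersed premature counts with side structure,
and group-parameterized cohorts with counterbalanced acquisition sides.  It
does not emulate: shaping (habituation, magazine training, RHD progression),
within-session satiety or circadian drift, wall-clock session termination,
body-weight/food-restriction dynamics, or any genuine group differences —
groups differ only where the user configures different agent parameters.
Passing tests therefore demonstrate that the *pipeline* measures what it
claims on data with realistic structure, not that real mice of any genotype
behave like the default agent.

## Problem sizes

Property tests compare against brute-force oracles on 1000 random sequences
(lengths 10–400, accuracies 0.2–0.95).  Cohort-level checks use 200
subjects per arm with fixed master seeds (seeds derived via
`numpy.random.SeedSequence`, kept below 2^31); change-point recovery uses
500 planted-step replicates.  The acceptance script simulates 12 subjects
per group (96 total), enough to pin every reported mean to within a few
percent while completing in seconds.
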