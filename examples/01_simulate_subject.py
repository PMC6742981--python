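"""Simulate one mouse through acquisition and reversal, and look at the raw
trial stream.

The agent acquires a left/right discrimination to an 80%-correct criterion
(20-trial sliding window within one session), then the rewarded side swaps
and it must reverse.  The printout shows the per-phase trial counts and the
accuracy profile around the reversal — the hallmark of the task is the
error-dense start of the reversal phase.
"""

import numpy as np

from revlearn import (
    AgentParams,
    Outcome,
    SexModel,
    Side,
    SubjectProfile,
    simulate_subject,
)

profile = SubjectProfile(
    subject_id="demo-01",
    sex_model=SexModel.KS,
    x_dose="1X",
    gdx="SHAM",
    assigned_acq_side=Side.LEFT,
)
sim = simulate_subject(profile, agent=AgentParams(rng_seed=11))

for series in (sim.acq, sim.rev):
    resp = series.response_trials()
    correct = np.array([t.outcome is Outcome.REWARDED for t in resp])
    first20 = correct[:20].mean()
    last20 = correct[-20:].mean()
    print(
        f"{series.phase.value}: {len(series.trials)} trials "
        f"({len(resp)} responses, {len(series.trials) - len(resp)} omissions), "
        f"criterion reached: {series.reached_criterion}; "
        f"accuracy first 20 = {first20:.2f}, last 20 = {last20:.2f}"
    )

# accuracy dips back to near zero right after the contingency swap:
rev_first10 = [
    "+" if t.outcome is Outcome.REWARDED else "-"
    for t in sim.rev.response_trials()[:10]
]
print("first 10 reversal outcomes:", "".join(rev_first10), "(perseveration)")
print(f"event log: {sim.event_log.count(chr(10))} chamber events recorded")
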