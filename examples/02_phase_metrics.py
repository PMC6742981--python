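"""Compute every phase-level learning measure for one simulated subject.

Each phase is truncated at the criterion trial and bisected at the learning
curve's change point (maximum deviation of the cumulative record from its
end-to-end chord).  PRE/POST then split every rate and latency; MAXCI (the
longest error run) indexes perseveration and the regress score indexes
transient slips back toward chance after learning.
"""

from revlearn import (
    AgentParams,
    SexModel,
    Side,
    SubjectProfile,
    compute_phase_metrics,
    role_map_for,
    simulate_subject,
)

profile = SubjectProfile("demo-02", SexModel.KS, "2X", "SHAM", Side.RIGHT)
sim = simulate_subject(profile, agent=AgentParams(rng_seed=23))
roles = role_map_for(profile)

for series in (sim.acq, sim.rev):
    pm = compute_phase_metrics(series, roles)
    print(f"\n--- {pm.phase} ---")
    print(f"trials to criterion : {pm.trials_to_criterion}")
    print(f"change point (1st POST trial): {pm.cp_index}")
    print(f"MAXCI (perseveration): {pm.maxci}   regress score: {pm.regress:.4f}")
    for name, split in (("PRE", pm.pre), ("POST", pm.post)):
        fs = "absent" if split.fs is None else f"{split.fs:+.3f}"
        print(
            f"  {name}: {split.n_trials} response trials, "
            f"errors/trial {split.errors_per_trial:.2f}, FS {fs}, "
            f"premature/trial C_ACQ {split.premature_per_trial['C_ACQ']:.2f} "
            f"C_REV {split.premature_per_trial['C_REV']:.2f}"
        )
    win = pm.post.init_latency_after_win
    loss = pm.post.init_latency_after_loss
    if win and loss:
        print(
            f"  POST initiation latency: {loss:.1f} s after losses vs "
            f"{win:.1f} s after wins (faster restart after nonreward)"
        )
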