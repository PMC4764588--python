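"""Generate a probabilistic reversal-learning schedule and inspect it.

Builds the standard 20-epochs-of-20-trials task with an 80%/20% reward
schedule that reverses at trial 200, then prints the exact per-epoch
reward counts — the schedule delivers round(p * 20) rewards per epoch
per (stimulus, action), so the printed rates hold exactly in every epoch.
"""

from striatan import TaskConfig, feedback, make_schedule

config = TaskConfig(p_opt=0.8, p_sub=0.2, seed=42)
schedule = make_schedule(config)

print(f"trials per stimulus: {config.n_trials}, reversal at trial {config.reversal_trial}")
for epoch in (0, 9, 10, 19):
    lo, hi = epoch * 20, (epoch + 1) * 20
    counts = schedule.outcomes[lo:hi, 0, :].sum(axis=0)
    print(f"epoch {epoch:2d}: rewards for (action 0, action 1) = {tuple(counts)}")

r = feedback(schedule, trial=0, stimulus=0, action=0)
print(f"single-trial lookup (trial 0, stimulus 0, action 0) -> reward {r}")
print("Before the reversal action 0 earns ~16/20, after it ~4/20 — the")
print("contingencies exchange exactly at trial 200.")
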