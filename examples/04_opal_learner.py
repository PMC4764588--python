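"""Opponent actor-critic (OpAL) with weight decay toward the naive prior.

Runs OpAL on the 85%/15% reversal task with fast, slow, and
entropy-annealed decay of the G/N actor weights and prints the
flexibility-stability pattern plus the G-weight divergence just before
the reversal (larger divergence = more entrenched policy).
"""

from striatan import OpalParams, TaskConfig, run_opal_session

conditions = {
    "fast  (gamma=1)": OpalParams(decay_mode="fixed", gamma=1.0),
    "slow  (gamma=7)": OpalParams(decay_mode="fixed", gamma=7.0),
    "adaptive": OpalParams(decay_mode="adaptive"),
}

for name, params in conditions.items():
    df = run_opal_session(TaskConfig(p_opt=0.85, p_sub=0.15, seed=5), params, seed=13)
    pre = df[(df.epoch >= 7) & (df.epoch < 10)]["correct"].mean()
    dip = df[df.epoch == 10]["correct"].mean()
    total = df["correct"].mean()
    last_pre = df[(df.trial == 199) & (df.stimulus == 0)]
    div = float(last_pre["G_opt"].iloc[0] - last_pre["G_sub"].iloc[0])
    print(f"{name:17s} late-acq {pre:.2f}  reversal-epoch {dip:.2f}  "
          f"overall {total:.2f}  G divergence at reversal {div:+.3f}")

print("Slow decay accumulates a large G(optimal)-G(suboptimal) divergence")
print("that must be unlearned after the reversal (deep accuracy dip);")
print("the adaptive decay plateaus the divergence once the policy is")
print("confident and recovers faster.")
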