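"""Close the loop: TAN pause duration driven by striatal uncertainty.

Runs the network with the entropy-feedback law (minus-phase Go
population entropy commands the accommodation time constant, hence the
pause duration) on an 85%/15% reversal task and prints how the realized
pause tracks the network's own uncertainty across learning.
"""

from striatan import (
    NetworkParams,
    PauseCalibration,
    TanMode,
    TaskConfig,
    run_network_session,
)

params = NetworkParams()
cal = PauseCalibration(params)
df = run_network_session(
    TaskConfig(p_opt=0.85, p_sub=0.15, seed=7),
    TanMode("entropy"),
    params=params,
    seed=8,
    calibration=cal,
)

windows = [("early acquisition", 0, 40), ("late acquisition", 160, 200),
           ("just after reversal", 200, 240), ("end of training", 360, 400)]
for name, lo, hi in windows:
    seg = df[(df.trial >= lo) & (df.trial < hi)]
    print(f"{name:22s}: H = {seg['H'].mean():5.1f} bits, "
          f"pause = {seg['pause_ms'].mean():3.0f} ms, "
          f"accuracy = {seg['correct'].mean():.2f}")
print("High uncertainty (early, and again right after the reversal) commands")
print("long pauses — a high effective learning rate — while confident")
print("behavior shortens the pause and protects the learned policy.")
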