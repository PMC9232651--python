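"""The three nested observer models on one stimulus sequence.

Simulates a duration-like i.i.d. stimulus sequence and runs the static,
simple-iterative and two-state observers on it.  Prints each model's
steady-state Kalman gains and the central tendency of its deterministic
responses: k1 weights the current measurement (1 - k1 is the compression
toward the prior), k2 is how fast the believed distribution mean drifts
after each trial (0 for the static belief).
"""

import magest as mg

stimuli = mg.gen_iid_sequence(400, mean=1150, sd=300, bounds=(400, 1900), seed=1)

observers = [
    mg.ObserverParams("static", v_over_r=1.0),
    mg.ObserverParams("iterative", q_over_r=0.5),
    mg.ObserverParams("two_state", v_over_r=1.0, q_over_r=0.3),
]

print(f"{'model':<12} {'k1':>6} {'k2':>6} {'central tendency':>17}")
for params in observers:
    k1, k2 = mg.steady_state_gains(params)
    responses = mg.simulate_response_timecourse(stimuli.values, params)
    trials = mg.TrialSequence("demo", "iid", stimuli, responses)
    c = mg.central_tendency(trials)
    print(f"{params.model_kind:<12} {k1:6.3f} {k2:6.3f} {c:17.3f}")

print()
print("All three are one Kalman filter: q=0 freezes the believed mean "
      "(static), v=0 collapses it onto exponential smoothing (iterative).")
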