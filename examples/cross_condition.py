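"""Predicting a new condition from parameters fitted on another.

Builds a small synthetic cohort in the two-condition design: each subject
reproduces the same 400 magnitudes once in random-walk order and once
scrambled.  Parameters fitted on the scrambled ("randomized") condition are
applied unchanged to the walk ordering — a zero-free-parameter prediction.
If observers carry a fixed belief about temporal continuity across
conditions, the central tendency should collapse and the serial dependence
should flip sign.
"""

import numpy as np

import magest as mg

trials, _ = mg.make_synthetic_study({"seed": 11})
by = {}
for t in trials:
    by.setdefault(t.subject_id, {})[t.condition] = t

print(f"{'subject':<8} {'c randomized':>13} {'c walk (pred)':>14} {'s walk (pred)':>14}")
c_fit, c_pred, s_pred = [], [], []
for subject, conds in sorted(by.items()):
    fit = mg.fit_model(conds["randomized"], "two_state", compute_ci=False)
    _, pred = mg.predict_condition(fit.params, conds["random_walk"])
    c = mg.central_tendency(conds["randomized"])
    print(f"{subject:<8} {c:13.3f} {pred.c:14.3f} {pred.s:14.3f}")
    c_fit.append(c); c_pred.append(pred.c); s_pred.append(pred.s)

print(f"{'mean':<8} {np.mean(c_fit):13.3f} {np.mean(c_pred):14.3f} "
      f"{np.mean(s_pred):14.3f}")
print()
print("Central tendency shrinks sharply in the walk condition and the mean "
      "predicted serial dependence turns negative — the same qualitative "
      "reversal the two-condition experiment shows.")
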