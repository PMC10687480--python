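"""Sequentially adaptive congruency detection.

Runs of congruent trials push the discrimination threshold up (incongruence
gets easier to miss); runs of incongruent trials pull it down (false alarms
on congruent trials get likelier).  This single mechanism generates the
congruency-sequence effects in the behavioural simulator.
"""

from scipy.stats import norm

from arcsim import PerceptionParams, ThresholdState, sensitivity, threshold_fixed_point, update_threshold

p = PerceptionParams()  # V0=0, V1=1, threshold starts at 0.5
state = ThresholdState.initial(p)

print("ten congruent trials in a row:")
for k in range(10):
    state = update_threshold(state, 0, p)
miss = norm.cdf(state.vth, loc=p.V1, scale=p.sigma1)
print(f"  threshold {p.vth_init:.2f} -> {state.vth:.3f}, "
      f"miss probability for a following incongruent signal: {miss:.3f}")
print(f"  (limit of an endless congruent run: {threshold_fixed_point(0, p):.3f})")

print("two incongruent trials next:")
for k in range(2):
    state = update_threshold(state, 1, p)
fa = 1 - norm.cdf(state.vth, loc=p.V0, scale=p.sigma0)
print(f"  threshold now {state.vth:.3f}, "
      f"false-alarm probability on a following congruent trial: {fa:.3f}")

s1 = sensitivity(1, state.vth, p)
s0 = sensitivity(0, state.vth, p)
print(f"sensitivity scores at this threshold: incongruence {s1:.3f}, congruence {s0:.3f}")
print("-> lower threshold trades congruent reliability for incongruence sensitivity.")
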