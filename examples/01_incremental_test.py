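"""Ramp-test analysis: VO2peak, gas exchange threshold, workload prescription.

Simulates a 25 W/min incremental test for one synthetic participant, then
extracts the quantities every later trial is prescribed from.
"""

from anacap import (
    analyze_incremental,
    delta_target,
    make_participant,
    power_for_target,
    simulate_incremental,
)

truth = make_participant(seed=7)
series = simulate_incremental(truth, start_power=50.0, ramp=25.0, seed=1)
res = analyze_incremental(series)

print(f"VO2peak        : {res.vo2peak:.2f} L/min   (truth {truth.vo2peak:.2f})")
print(f"GET            : {res.get_vo2:.2f} L/min at {res.get_power:.0f} W "
      f"(truth {truth.get_vo2:.2f} at {truth.get_power:.0f} W)")
print(f"max ramp power : {res.max_power:.0f} W")
print(f"VO2-power line : {res.vo2_power_line[0]*1000:.1f} mL/min/W, "
      f"intercept {res.vo2_power_line[1]:.2f} L/min")

# Delta workloads sit between GET and VO2peak; the supramaximal bout at 120%
# of VO2peak is what the oxygen-deficit methods exhaust.
for frac, label in ((0.1, "D10"), (0.8, "D80")):
    tgt = delta_target(res.get_vo2, res.vo2peak, frac)
    print(f"{label}: target {tgt:.2f} L/min -> {power_for_target(res, tgt):.0f} W")
tgt120 = 1.2 * res.vo2peak
print(f"120%VO2peak: target {tgt120:.2f} L/min -> {power_for_target(res, tgt120):.0f} W")
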