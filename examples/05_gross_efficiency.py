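"""Gross-efficiency method: warm-up efficiency, then anaerobic work.

Gross efficiency (external / metabolic power) is measured over the last
30 s of a 5-min warm-up at 90% of GET power (valid only while RER < 1).
During the 120% VO2peak bout, metabolic power assumes RER = 1; anaerobic
mechanical power = external - GE x metabolic, integrated to kJ.
"""

from anacap import (
    PLACEBO,
    anaerobic_work,
    gross_efficiency_from_warmup,
    make_participant,
    simulate_constant_load,
    simulate_warmup,
    workload_power,
)

truth = make_participant(seed=7)
warmup = simulate_warmup(truth, seed=5)
eff = gross_efficiency_from_warmup(warmup.breaths, warmup.power)
print(f"warm-up: {warmup.power:.0f} W, VO2 {eff.warmup_vo2:.2f} L/min, "
      f"RER {eff.warmup_rer:.2f} (valid: {eff.rer_valid})")
print(f"gross efficiency: {eff.ge:.3f} (truth {truth.ge_true:.3f})")

supra = simulate_constant_load(
    truth, PLACEBO, workload_power(truth, "p120"), to_exhaustion=True, seed=6
)
est = anaerobic_work(supra.breaths, supra.power, eff, t_end=supra.time_to_exhaustion)
print(f"\n120% bout: {supra.power:.0f} W for {supra.time_to_exhaustion:.0f} s "
      f"(external work {est.extras['external_work_kj']:.1f} kJ)")
print(f"aerobic work {est.extras['aerobic_kj']:.1f} kJ -> anaerobic capacity "
      f"{est.total_kj:.1f} kJ")
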