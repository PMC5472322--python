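"""Critical power and W' from three power-duration points.

The D80, 100% and 120% VO2peak bouts and their times to exhaustion are
fitted with the three two-parameter models; the one with the lowest
standard error of W' is kept.  W'/1000 is the critical-power estimate of
anaerobic capacity in kJ.
"""

import numpy as np

from anacap import PowerDurationPoint, fit_all_cp_models, select_cp_model, w_prime_energy

CP_TRUE, WP_TRUE = 165.0, 19300.0
rng = np.random.default_rng(2)
points = [
    PowerDurationPoint(p, WP_TRUE / (p - CP_TRUE) * (1 + 0.03 * rng.standard_normal()))
    for p in (231.0, 260.0, 300.0)
]
print("points (W, s):", [(p.power, round(p.t_lim, 1)) for p in points])

fits = fit_all_cp_models(points)
for fit in fits.values():
    print(f"{fit.model:22s} CP {fit.cp:6.1f} W  W' {fit.w_prime/1000:5.2f} kJ  "
          f"SEE(W') {fit.see_w_prime:7.1f} J")

best = select_cp_model(fits.values())
est = w_prime_energy(best)
print(f"\nselected: {best.model} (lowest SEE of W') -> anaerobic capacity "
      f"{est.total_kj:.2f} kJ (truth {WP_TRUE/1000:.1f} kJ, CP truth {CP_TRUE:.0f} W)")
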