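"""Traditional MAOD for one crossover participant.

Fits the submaximal VO2-power demand line (D10-D80, the D80 point at
isotime), extrapolates the oxygen demand of the exhaustive 120% VO2peak
bout, subtracts the measured accumulated VO2, and converts the store-
corrected deficit to kJ.  The three variants differ in which arm supplied
the demand line and the supramaximal bout.
"""

from anacap import group_trials, maod_matrix, simulate_crossover_study

trials = simulate_crossover_study(n_participants=2, seed=11)
participant = group_trials(trials)[0]

for label, est in maod_matrix(participant).items():
    x = est.extras
    print(
        f"MAOD_{label}: demand {x['total_demand_l']:.2f} L - accumulated "
        f"{x['accumulated_l']:.2f} L -> deficit {x['deficit_l']:.2f} L "
        f"-> {est.total_kj:.1f} kJ"
    )
print(
    "\nDeficit x 0.9 (body O2 stores) x 20.9 kJ/L; CAF-PLA uses the placebo\n"
    "demand line under the caffeine supramaximal bout."
)
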