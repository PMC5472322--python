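"""Traditional maximal accumulated oxygen deficit (MAOD).

The supramaximal oxygen demand is extrapolated from an ordinary
least-squares regression of steady-state submaximal VO₂ on power; the
accumulated VO₂ actually measured during the exhaustive supramaximal bout is
subtracted; the deficit is reduced by 10% for body oxygen stores
(lung/venous O₂ and myoglobin) and converted to energy at 20.9 kJ per litre
of O₂.

For a two-arm crossover the demand line and the supramaximal bout can come
from different arms, giving the three standard variants: demand and bout
both under treatment (CAF-CAF), bout under treatment with control demand
(CAF-PLA), and both under control (PLA-PLA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .energy import EnergyEstimate, O2_ENERGY_EQUIV_KJ_PER_L
from .gas_exchange import accumulated_vo2, isotime, mean_last_window, truncate

__all__ = [
    "DemandLine",
    "fit_demand_line",
    "supramaximal_demand",
    "compute_maod",
    "maod_matrix",
    "SUBMAX_WORKLOADS",
    "SUPRA_WORKLOAD",
]

#: Submaximal workloads entering the demand regression (Δ-fractions of the
#: GET→VO₂peak reserve); the Δ80 point is taken at isotime.
SUBMAX_WORKLOADS = ("d10", "d20", "d40", "d50", "d80")
#: Supramaximal workload whose accumulated VO₂ defines the deficit.
SUPRA_WORKLOAD = "p120"


@dataclass(frozen=True)
class DemandLine:
    """Linear submaximal VO₂–power relationship used for extrapolation."""

    slope: float  # L·min⁻¹·W⁻¹
    intercept: float  # L·min⁻¹
    r2: float
    n_points: int
    condition_of_submax: str = "n/a"

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("a demand line needs at least 2 points")
        if not -1e-9 <= self.r2 <= 1 + 1e-9:
            raise ValueError("r2 must lie in [0, 1]")

    def demand_at(self, power: float) -> float:
        """Predicted steady-state oxygen cost at ``power``, L·min⁻¹."""
        return self.slope * power + self.intercept


def fit_demand_line(
    points: Sequence[tuple[float, float]], condition: str = "n/a"
) -> DemandLine:
    """Ordinary least squares of steady-state VO₂ (L·min⁻¹) on power (W)."""
    pts = [(float(p), float(v)) for p, v in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 (power, vo2) points")
    x = np.array([p for p, _ in pts])
    y = np.array([v for _, v in pts])
    if np.ptp(x) == 0:
        raise ValueError("all powers are equal; demand line is undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    return DemandLine(
        slope=float(slope),
        intercept=float(intercept),
        r2=min(max(r2, 0.0), 1.0),
        n_points=len(pts),
        condition_of_submax=condition,
    )


def supramaximal_demand(line: DemandLine, power: float, duration: float) -> float:
    """Total extrapolated O₂ demand of a supramaximal bout, in litres."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return line.demand_at(power) * duration / 60.0


def compute_maod(
    total_demand: float,
    accumulated: float,
    store_correction: float = 0.10,
    energy_equiv: float = O2_ENERGY_EQUIV_KJ_PER_L,
    condition: str = "n/a",
    demand_condition: str = "n/a",
) -> EnergyEstimate:
    """MAOD in kJ from total demand and accumulated VO₂ (both litres).

    ``total_kj = (demand − accumulated) · (1 − store_correction) · energy_equiv``.
    The store correction is applied to the deficit, not to the demand.
    """
    if accumulated < 0:
        raise ValueError("accumulated VO2 must be non-negative")
    if accumulated > total_demand + 1e-12:
        raise ValueError(
            "negative deficit: accumulated VO2 exceeds estimated demand "
            "(mis-specified demand line?)"
        )
    deficit_l = total_demand - accumulated
    total_kj = deficit_l * (1.0 - store_correction) * energy_equiv
    return EnergyEstimate(
        method="MAOD",
        total_kj=total_kj,
        components={"deficit_kj": total_kj},
        condition=condition,
        demand_condition=demand_condition,
        extras={
            "deficit_l": deficit_l,
            "corrected_deficit_l": deficit_l * (1.0 - store_correction),
            "total_demand_l": total_demand,
            "accumulated_l": accumulated,
        },
    )


def _require(trials: Mapping, keys) -> None:
    missing = [k for k in keys if k not in trials]
    if missing:
        raise ValueError(f"missing required bouts: {missing}")


def maod_matrix(
    trials: Mapping[tuple[str, str], "object"],
    store_correction: float = 0.10,
    energy_equiv: float = O2_ENERGY_EQUIV_KJ_PER_L,
    window: float = 30.0,
) -> dict[str, EnergyEstimate]:
    """The three crossover MAOD variants for one participant.

    ``trials`` maps (workload, condition) — workloads ``d10..d80, p120``,
    conditions ``caffeine``/``placebo`` — to objects exposing ``breaths``
    (a :class:`~anacap.gas_exchange.BreathSeries`), ``power`` (W) and, for
    exhaustive bouts, ``time_to_exhaustion`` (s).

    The Δ10–Δ50 VO₂ is the last-30-s average of each 10-min bout; the Δ80
    VO₂ is averaged at isotime (the shorter of the two arms' Δ80 exhaustion
    times) so exhaustion effects cannot leak into the regression.  The
    demand condition varies by variant; the accumulated VO₂ and duration
    always come from the stated supramaximal arm.
    """
    conditions = ("caffeine", "placebo")
    needed = [(w, c) for w in SUBMAX_WORKLOADS for c in conditions]
    needed += [(SUPRA_WORKLOAD, c) for c in conditions]
    _require(trials, needed)

    t_iso = isotime(
        trials[("d80", "caffeine")].time_to_exhaustion,
        trials[("d80", "placebo")].time_to_exhaustion,
    )

    lines: dict[str, DemandLine] = {}
    for cond in conditions:
        pts = []
        for wl in SUBMAX_WORKLOADS:
            tr = trials[(wl, cond)]
            series = tr.breaths
            if wl == "d80":
                series = truncate(series, t_iso)
            pts.append((tr.power, mean_last_window(series, window)))
        lines[cond] = fit_demand_line(pts, condition=cond)

    out: dict[str, EnergyEstimate] = {}
    for label, supra_cond, demand_cond in (
        ("CAF-CAF", "caffeine", "caffeine"),
        ("CAF-PLA", "caffeine", "placebo"),
        ("PLA-PLA", "placebo", "placebo"),
    ):
        tr = trials[(SUPRA_WORKLOAD, supra_cond)]
        duration = tr.time_to_exhaustion
        if duration is None:
            raise ValueError(f"supramaximal bout {(SUPRA_WORKLOAD, supra_cond)} has no time to exhaustion")
        demand_l = supramaximal_demand(lines[demand_cond], tr.power, duration)
        acc_l = accumulated_vo2(tr.breaths, tr.breaths.t[0], tr.breaths.t[-1])
        out[label] = compute_maod(
            demand_l,
            acc_l,
            store_correction=store_correction,
            energy_equiv=energy_equiv,
            condition=supra_cond,
            demand_condition=demand_cond,
        )
    return out
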