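"""Gross-efficiency method: metabolic power, warm-up efficiency, anaerobic work.

Metabolic power is computed from VO₂ and the respiratory exchange ratio
(RER = VCO₂/VO₂) with the caloric-equivalent relationship

    MetP (W) = VO₂ (L·min⁻¹) × (4940·RER + 16040) / 60.

Gross efficiency (GE) is external power divided by metabolic power over the
last 30 s of a moderate warm-up; the relationship is only energetically valid
while RER < 1.00 (no net CO₂ from bicarbonate buffering), so estimates taken
above that carry ``rer_valid=False``.  During the supramaximal bout RER is
fixed at 1.00 and the anaerobic mechanical power — external power minus
GE-scaled metabolic power — is integrated over the bout to yield an
anaerobic-capacity analogue in kJ (assuming GE carries over unchanged to the
severe domain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .energy import EnergyEstimate
from .gas_exchange import BreathSeries, mean_last_window

__all__ = [
    "EfficiencyEstimate",
    "metabolic_power",
    "gross_efficiency_from_warmup",
    "anaerobic_work",
]


@dataclass(frozen=True)
class EfficiencyEstimate:
    ge: float  # dimensionless, external / metabolic power
    warmup_vo2: float  # L·min⁻¹, last-30-s mean
    warmup_rer: float  # dimensionless, last-30-s mean
    warmup_power: float  # W, external
    rer_valid: bool  # True when warm-up RER < 1.00

    def __post_init__(self):
        if self.warmup_rer <= 0:
            raise ValueError("warmup_rer must be positive")
        if self.rer_valid and not 0 < self.ge < 1:
            raise ValueError("gross efficiency must lie in (0, 1)")


def metabolic_power(vo2, rer: float, rer_bounds: tuple[float, float] = (0.6, 1.3)):
    """Metabolic power in W from VO₂ (L·min⁻¹, scalar or array) and RER.

    ``rer_bounds`` is a physiological guard; values outside it indicate a
    measurement problem rather than a metabolic state.
    """
    lo, hi = rer_bounds
    if not lo <= rer <= hi:
        raise ValueError(f"RER {rer:g} outside physiological guard [{lo:g}, {hi:g}]")
    vo2 = np.asarray(vo2, dtype=float)
    if np.any(vo2 < 0):
        raise ValueError("vo2 must be non-negative")
    out = vo2 * (4940.0 * rer + 16040.0) / 60.0
    return float(out) if out.ndim == 0 else out


def gross_efficiency_from_warmup(
    warmup: BreathSeries, external_power: float, window: float = 30.0
) -> EfficiencyEstimate:
    """GE from the final ``window`` seconds of a sub-GET warm-up.

    VO₂ and VCO₂ are window-averaged separately and RER taken as their
    ratio.  When the mean RER reaches 1.00 the estimate is returned with
    ``rer_valid=False`` (plus a warning) instead of raising, so pipelines
    can log and skip rather than crash.
    """
    if external_power <= 0:
        raise ValueError("external power must be positive")
    vo2 = mean_last_window(warmup, window, channel="vo2")
    vco2 = mean_last_window(warmup, window, channel="vco2")
    if vo2 <= 0:
        raise ValueError("warm-up VO2 must be positive")
    rer = vco2 / vo2
    ge = external_power / metabolic_power(vo2, rer)
    rer_valid = rer < 1.0
    if not rer_valid:
        warnings.warn(
            f"warm-up RER {rer:.2f} >= 1.00; gross efficiency is not interpretable",
            stacklevel=2,
        )
    return EfficiencyEstimate(
        ge=float(ge), warmup_vo2=vo2, warmup_rer=float(rer),
        warmup_power=float(external_power), rer_valid=rer_valid,
    )


def anaerobic_work(
    supra: BreathSeries,
    external_power: float,
    efficiency: EfficiencyEstimate | float,
    rer_supra: float = 1.00,
    force: bool = False,
    condition: str = "n/a",
    t_start: float = 0.0,
    t_end: float | None = None,
) -> EnergyEstimate:
    """Total anaerobic work of a supramaximal bout, kJ.

    Aerobic mechanical power at each grid point is GE × MetP(VO₂(t), RER=1);
    the anaerobic remainder (external − aerobic, negatives kept as-is) is
    trapezoid-integrated over [``t_start``, ``t_end``].  Integration starts
    at bout onset (t = 0) by default — the first breaths are almost purely
    anaerobic and belong in the total — with VO₂ held at the nearest
    recorded breath outside the sampled span; ``t_end`` defaults to the last
    breath but should be the time to exhaustion when known.  A GE estimate
    flagged ``rer_valid=False`` is refused unless ``force=True``.
    """
    if isinstance(efficiency, EfficiencyEstimate):
        if not efficiency.rer_valid and not force:
            raise ValueError(
                "gross efficiency was measured at RER >= 1.00; pass force=True to use it anyway"
            )
        ge = efficiency.ge
    else:
        ge = float(efficiency)
    if not 0 < ge < 1:
        raise ValueError("gross efficiency must lie in (0, 1)")
    if external_power <= 0:
        raise ValueError("external power must be positive")
    if t_end is None:
        t_end = float(supra.t[-1])
    if not t_start < t_end:
        raise ValueError("t_start must be before t_end")
    grid = np.arange(t_start, t_end, 1.0)
    if grid[-1] < t_end:
        grid = np.append(grid, t_end)
    vo2 = np.interp(grid, supra.t, supra.vo2)  # edge-hold outside the breaths
    aerobic_w = ge * metabolic_power(vo2, rer_supra)
    anaerobic_w = external_power - aerobic_w
    total_kj = float(np.trapezoid(anaerobic_w, grid) / 1000.0)
    duration = t_end - t_start
    return EnergyEstimate(
        method="GE_WORK",
        total_kj=total_kj,
        components={"anaerobic_kj": total_kj},
        condition=condition,
        extras={
            "aerobic_kj": float(np.trapezoid(aerobic_w, grid) / 1000.0),
            "external_work_kj": float(external_power * duration / 1000.0),
            "ge": ge,
        },
    )
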