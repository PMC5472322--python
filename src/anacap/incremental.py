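"""Incremental (ramp) test analysis: VO₂peak, gas exchange threshold, workload prescription.

The gas exchange threshold (GET) is located with the v-slope criterion: a
continuous two-segment linear regression of VCO₂ on VO₂, scanning every
interior candidate breakpoint and keeping the one with the lowest total sum
of squared errors.  A threshold is only declared when the upper segment is
distinctly steeper than the lower one — the "disproportionate increase in
VCO₂" that marks the onset of bicarbonate buffering of lactic acid.

This is a single-criterion automation of what is usually done by eye
(often cross-checked against ventilatory equivalents and end-tidal
pressures); results carry a ``confidence`` score so callers can flag
low-quality detections for review.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gas_exchange import BreathSeries, mean_last_window, resample_uniform

__all__ = [
    "GETNotDetected",
    "GETResult",
    "IncrementalResult",
    "compute_vo2peak",
    "detect_get",
    "analyze_incremental",
    "delta_target",
    "power_for_target",
]


class GETNotDetected(ValueError):
    """Raised when no disproportionate VCO₂ rise is found (v-slope failure)."""


@dataclass(frozen=True)
class GETResult:
    get_vo2: float  # L·min⁻¹ at the breakpoint
    get_power: float  # W read from the power trace at the breakpoint time
    confidence: float  # 1 − SSE(two-segment)/SSE(one-segment)


@dataclass(frozen=True)
class IncrementalResult:
    """Summary of one ramp test used to prescribe constant-load workloads."""

    vo2peak: float  # L·min⁻¹, last-30-s average
    get_vo2: float  # L·min⁻¹
    get_power: float  # W
    max_power: float  # W, highest power reached
    vo2_power_line: tuple[float, float]  # (slope L·min⁻¹·W⁻¹, intercept L·min⁻¹)

    def __post_init__(self):
        if not self.get_vo2 < self.vo2peak:
            raise ValueError("get_vo2 must be below vo2peak")
        if not self.get_power < self.max_power:
            raise ValueError("get_power must be below max_power")


def compute_vo2peak(series: BreathSeries) -> float:
    """Peak oxygen uptake: average VO₂ over the last 30 s of the ramp."""
    return mean_last_window(series, 30.0, channel="vo2")


def _two_segment_sse(x: np.ndarray, y: np.ndarray, xb: float):
    """Continuous piecewise-linear fit y = a + b₁·x + b₂·(x − xb)₊."""
    X = np.column_stack([np.ones_like(x), x, np.clip(x - xb, 0.0, None)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def detect_get(
    series: BreathSeries,
    edge_exclude: float = 0.10,
    min_slope_rise: float = 0.05,
) -> GETResult:
    """Locate the gas exchange threshold on the VCO₂-vs-VO₂ plane.

    Parameters
    ----------
    series:
        Ramp-test breaths (≥ 60 s); a ``power`` channel is required to read
        off the threshold power.
    edge_exclude:
        Fraction of the VO₂ span excluded at each end of the candidate
        range, so the breakpoint cannot sit on a boundary artifact.
    min_slope_rise:
        Minimal relative slope increase (b₂ ≥ min_slope_rise·b₁) for the
        break to count as disproportionate; below it the data are treated as
        single-sloped and :class:`GETNotDetected` is raised.
    """
    if series.duration < 60.0:
        raise ValueError("need at least 60 s of ramp data to detect the GET")
    rs = resample_uniform(series, 1.0)
    order = np.argsort(rs.vo2, kind="stable")
    x, y, tt = rs.vo2[order], rs.vco2[order], rs.t[order]
    n = len(x)
    span = x[-1] - x[0]
    x_lo, x_hi = x[0] + edge_exclude * span, x[-1] - edge_exclude * span
    lo = max(2, int(np.searchsorted(x, x_lo)))
    hi = min(n - 2, int(np.searchsorted(x, x_hi)))
    if hi <= lo:
        raise ValueError("too few samples for a breakpoint scan")

    # one-segment reference
    sse1, _ = _two_segment_sse(x, y, x[-1] + 1.0)

    # best candidate among those exhibiting a genuine disproportionate rise
    best = None
    for i in range(lo, hi):
        xb = x[i]
        sse, coef = _two_segment_sse(x, y, xb)
        b1, b2 = coef[1], coef[2]
        if b2 <= max(min_slope_rise * abs(b1), 1e-12):
            continue
        if best is None or sse < best[0]:
            best = (sse, coef, i)
    if best is None:
        raise GETNotDetected("no GET detected: VCO2 slope does not rise above VO2 slope")
    sse2, coef, i_best = best
    xb = float(x[i_best])
    t_break = float(tt[i_best])
    if rs.power is None:
        raise ValueError("series has no power channel; cannot report get_power")
    get_power = float(np.interp(t_break, rs.t, rs.power))
    confidence = 1.0 - sse2 / sse1 if sse1 > 0 else 1.0
    return GETResult(get_vo2=xb, get_power=get_power, confidence=float(confidence))


def analyze_incremental(series: BreathSeries) -> IncrementalResult:
    """Full ramp-test summary: VO₂peak, GET and the VO₂–power line.

    The line is an ordinary least-squares fit of VO₂ on power over the part
    of the ramp where VO₂ is still below 90% of VO₂peak (the quasi-linear
    region, before the plateau flattens the relationship).
    """
    vo2peak = compute_vo2peak(series)
    get = detect_get(series)
    rs = resample_uniform(series, 1.0)
    if rs.power is None:
        raise ValueError("series has no power channel")
    mask = rs.vo2 < 0.90 * vo2peak
    if mask.sum() < 10:
        raise ValueError("too little sub-plateau data to fit the VO2-power line")
    slope, intercept = np.polyfit(rs.power[mask], rs.vo2[mask], 1)
    return IncrementalResult(
        vo2peak=vo2peak,
        get_vo2=get.get_vo2,
        get_power=get.get_power,
        max_power=float(np.max(rs.power)),
        vo2_power_line=(float(slope), float(intercept)),
    )


def delta_target(get_vo2: float, vo2peak: float, fraction: float) -> float:
    """Δ-intensity target: GET VO₂ plus ``fraction`` of the GET→peak reserve."""
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    if not get_vo2 < vo2peak:
        raise ValueError("get_vo2 must be below vo2peak")
    return get_vo2 + fraction * (vo2peak - get_vo2)


def power_for_target(result: IncrementalResult, target_vo2: float) -> float:
    """Invert the incremental VO₂–power line to prescribe a workload (nearest W)."""
    slope, intercept = result.vo2_power_line
    if slope <= 0:
        raise ValueError("VO2-power line slope must be positive")
    return float(round((target_vo2 - intercept) / slope))
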