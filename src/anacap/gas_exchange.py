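"""Breath-by-breath gas-exchange series: containers, I/O, resampling and integration.

All downstream anaerobic-capacity methods consume a :class:`BreathSeries`
(time-stamped oxygen uptake, carbon-dioxide output, optional ventilation and
power).  Conventions used throughout the package:

* time in seconds, ``t = 0`` at bout onset (recovery series restart at the
  end of exercise);
* gas volumes as rates in L·min⁻¹ (STPD), power in W;
* every averaging/integration step happens on a 1-Hz linearly interpolated
  grid, so 30-s windows and trapezoidal integrals are well defined regardless
  of the irregular breath spacing of the raw signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BreathSeries",
    "LactateSeries",
    "read_breaths",
    "write_breaths",
    "read_lactate",
    "write_lactate",
    "resample_uniform",
    "truncate",
    "mean_last_window",
    "accumulated_vo2",
    "isotime",
]

#: CSV schema (order is the canonical write order)
REQUIRED_COLUMNS = ("t_s", "vo2_l_min", "vco2_l_min")
OPTIONAL_COLUMNS = ("ve_l_min", "power_w")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class BreathSeries:
    """One bout's breath-by-breath record.

    Channels are parallel arrays indexed by breath; ``ve`` and ``power`` are
    optional because recovery (off-transient) recordings carry no load and
    some analyzers do not export ventilation.
    """

    t: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    ve: np.ndarray | None = None
    power: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "t", _as_float_array(self.t, "t"))
        object.__setattr__(self, "vo2", _as_float_array(self.vo2, "vo2"))
        object.__setattr__(self, "vco2", _as_float_array(self.vco2, "vco2"))
        for name in ("ve", "power"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, _as_float_array(v, name))
        n = len(self.t)
        if n == 0:
            raise ValueError("no breaths")
        for name in ("vo2", "vco2", "ve", "power"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"channel {name!r} has length {len(v)}, expected {n}")
        bad = np.where(np.diff(self.t) <= 0)[0]
        if bad.size:
            rows = ", ".join(str(i + 1) for i in bad[:10])
            raise ValueError(f"breath times must be strictly increasing; offending rows: {rows}")
        if np.any(self.vo2 < 0) or np.any(self.vco2 < 0):
            raise ValueError("vo2 and vco2 must be non-negative")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Elapsed time between the first and last breath, s."""
        return float(self.t[-1] - self.t[0])

    def channel(self, name: str) -> np.ndarray:
        v = getattr(self, name, None)
        if v is None:
            raise ValueError(f"series has no {name!r} channel")
        return v


@dataclass(frozen=True)
class LactateSeries:
    """Plasma lactate samples around one supramaximal bout.

    ``samples`` holds post-exercise measurements as (time since exercise end
    in s, concentration in mmol·L⁻¹); ``pre_exercise`` is the resting value.
    """

    samples: tuple[tuple[float, float], ...]
    pre_exercise: float

    def __post_init__(self):
        object.__setattr__(
            self, "samples", tuple((float(t), float(la)) for t, la in self.samples)
        )
        object.__setattr__(self, "pre_exercise", float(self.pre_exercise))
        if self.pre_exercise < 0 or any(la < 0 for _, la in self.samples):
            raise ValueError("lactate concentrations must be non-negative")

    @property
    def post_values(self) -> np.ndarray:
        return np.array([la for _, la in self.samples], dtype=float)


# ---------------------------------------------------------------------------
# CSV I/O


def read_breaths(path: str | Path) -> BreathSeries:
    """Read a breath-by-breath CSV (columns ``t_s, vo2_l_min, vco2_l_min``
    plus optional ``ve_l_min, power_w``; extra columns and ``#`` comment
    lines are tolerated)."""
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"no breaths in {path}")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    kwargs = {}
    for col, name in (("ve_l_min", "ve"), ("power_w", "power")):
        if col in df.columns:
            kwargs[name] = df[col].to_numpy()
    return BreathSeries(
        t=df["t_s"].to_numpy(),
        vo2=df["vo2_l_min"].to_numpy(),
        vco2=df["vco2_l_min"].to_numpy(),
        **kwargs,
    )


def write_breaths(series: BreathSeries, path: str | Path) -> None:
    data = {"t_s": series.t, "vo2_l_min": series.vo2, "vco2_l_min": series.vco2}
    if series.ve is not None:
        data["ve_l_min"] = series.ve
    if series.power is not None:
        data["power_w"] = series.power
    pd.DataFrame(data).to_csv(path, index=False)


def read_lactate(path: str | Path) -> LactateSeries:
    """Read a lactate CSV with columns ``t_s, la_mmol_l``; the row with
    ``t_s < 0`` (or the first row) is taken as the pre-exercise sample."""
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"no lactate samples in {path}")
    for col in ("t_s", "la_mmol_l"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    pre_mask = df["t_s"] < 0
    if pre_mask.any():
        pre = float(df.loc[pre_mask, "la_mmol_l"].iloc[0])
        post = df.loc[~pre_mask]
    else:
        pre = float(df["la_mmol_l"].iloc[0])
        post = df.iloc[1:]
    return LactateSeries(
        samples=tuple(zip(post["t_s"].tolist(), post["la_mmol_l"].tolist())),
        pre_exercise=pre,
    )


def write_lactate(series: LactateSeries, path: str | Path) -> None:
    rows = [(-60.0, series.pre_exercise)] + list(series.samples)
    pd.DataFrame(rows, columns=["t_s", "la_mmol_l"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Resampling / windowing / integration


def _grid(t0: float, t1: float, dt: float) -> np.ndarray:
    n = int(math.floor((t1 - t0) / dt + 1e-9))
    g = t0 + dt * np.arange(n + 1)
    if g[-1] < t1 - 1e-9 * max(1.0, abs(t1)):
        g = np.append(g, t1)
    else:
        g[-1] = t1  # guard against floating-point shortfall
    return g


def resample_uniform(series: BreathSeries, dt: float = 1.0) -> BreathSeries:
    """Linearly interpolate every channel onto a uniform grid of step ``dt``
    spanning [t₀, t_end]; both endpoints are preserved exactly."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(series) < 2:
        raise ValueError("need at least 2 breaths to resample")
    g = _grid(series.t[0], series.t[-1], dt)

    def interp(v):
        return None if v is None else np.interp(g, series.t, v)

    return BreathSeries(
        t=g,
        vo2=np.interp(g, series.t, series.vo2),
        vco2=np.interp(g, series.t, series.vco2),
        ve=interp(series.ve),
        power=interp(series.power),
    )


def truncate(series: BreathSeries, t_end: float) -> BreathSeries:
    """Return the sub-series with t ≤ ``t_end``, appending an interpolated
    breath exactly at ``t_end`` when it falls between samples."""
    if t_end <= series.t[0]:
        raise ValueError("t_end precedes the first breath")
    if t_end >= series.t[-1]:
        return series
    keep = series.t <= t_end

    def cut(v):
        if v is None:
            return None
        return np.append(v[keep], np.interp(t_end, series.t, v))

    return BreathSeries(
        t=np.append(series.t[keep], t_end),
        vo2=cut(series.vo2),
        vco2=cut(series.vco2),
        ve=cut(series.ve),
        power=cut(series.power),
    )


def mean_last_window(
    series: BreathSeries, window: float = 30.0, channel: str = "vo2"
) -> float:
    """Time-weighted mean of a channel over the final ``window`` seconds.

    This is the windowed summary used for steady-state VO₂ values and for
    the peak VO₂ of an incremental test.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if series.duration < window - 1e-9:
        raise ValueError(
            f"series duration {series.duration:.1f} s is shorter than window {window:g} s"
        )
    v = series.channel(channel)
    t1 = series.t[-1]
    g = _grid(t1 - window, t1, 1.0)
    y = np.interp(g, series.t, v)
    return float(np.trapezoid(y, g) / (g[-1] - g[0]))


def accumulated_vo2(series: BreathSeries, t_start: float, t_end: float) -> float:
    """Accumulated oxygen uptake over [t_start, t_end], in litres.

    The linearly interpolated VO₂ signal (L·min⁻¹) is trapezoid-integrated
    exactly — the breath nodes inside the window plus interpolated endpoint
    values — over seconds, then divided by 60.  Exact integration of the
    piecewise-linear signal makes the result strictly additive over
    adjacent windows.
    """
    eps = 1e-9
    if not t_start < t_end:
        raise ValueError("t_start must be strictly before t_end")
    if t_start < series.t[0] - eps or t_end > series.t[-1] + eps:
        raise ValueError(
            f"integration window [{t_start:g}, {t_end:g}] outside series span "
            f"[{series.t[0]:g}, {series.t[-1]:g}]"
        )
    inside = (series.t > t_start) & (series.t < t_end)
    nodes = np.concatenate([[t_start], series.t[inside], [t_end]])
    y = np.interp(nodes, series.t, series.vo2)
    return float(np.trapezoid(y, nodes) / 60.0)


def isotime(t_a: float, t_b: float) -> float:
    """Shorter of two matched times to exhaustion (s), so paired conditions
    are compared over the same elapsed time."""
    if t_a <= 0 or t_b <= 0:
        raise ValueError("times to exhaustion must be positive")
    return float(min(t_a, t_b))
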