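"""Two-parameter critical-power models over (power, time-to-exhaustion) points.

Three algebraically equivalent parameterizations of the hyperbolic
power–duration relationship are fitted:

* hyperbolic:            t = W′ / (P − CP)        (nonlinear in t)
* linear work–time:      W = W′ + CP·t            (OLS of work on time)
* linear power–1/t:      P = W′·(1/t) + CP        (OLS of power on 1/t)

On exact hyperbolic data all three return identical (CP, W′); under noise
they differ because each minimizes a different residual.  Model selection
follows the convention of keeping the parameterization with the lowest
standard error of the W′ estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .energy import EnergyEstimate

__all__ = [
    "PowerDurationPoint",
    "CPModelFit",
    "CP_MODELS",
    "fit_cp",
    "select_cp_model",
    "w_prime_energy",
]

CP_MODELS = ("hyperbolic", "linear_work_time", "linear_power_inv_time")

#: fixed tie-break priority for model selection (lowest wins)
_TIE_ORDER = {"linear_power_inv_time": 0, "linear_work_time": 1, "hyperbolic": 2}


@dataclass(frozen=True)
class PowerDurationPoint:
    power: float  # W
    t_lim: float  # s

    def __post_init__(self):
        if self.power <= 0 or self.t_lim <= 0:
            raise ValueError("power and t_lim must be positive")

    @property
    def work(self) -> float:
        """Total work of the bout, J."""
        return self.power * self.t_lim


@dataclass(frozen=True)
class CPModelFit:
    model: str
    cp: float  # W
    w_prime: float  # J
    see_w_prime: float  # J
    see_cp: float  # W
    rss: float  # in the model's own residual units squared

    @property
    def valid(self) -> bool:
        return (
            self.cp > 0
            and self.w_prime > 0
            and np.isfinite(self.see_w_prime)
            and self.see_w_prime >= 0
        )


def _as_points(points: Iterable) -> list[PowerDurationPoint]:
    out = []
    for p in points:
        if isinstance(p, PowerDurationPoint):
            out.append(p)
        else:
            power, t_lim = p
            out.append(PowerDurationPoint(float(power), float(t_lim)))
    return out


def _ols(x: np.ndarray, y: np.ndarray):
    """Two-parameter OLS with classical standard errors.

    Returns (slope, intercept, se_slope, se_intercept, rss).
    """
    n = len(x)
    xb, yb = x.mean(), y.mean()
    sxx = float(((x - xb) ** 2).sum())
    if sxx < 1e-12 * max(1.0, xb * xb):
        raise ValueError("degenerate predictor: no variance in x")
    slope = float(((x - xb) * (y - yb)).sum() / sxx)
    intercept = float(yb - slope * xb)
    resid = y - (intercept + slope * x)
    rss = float(resid @ resid)
    s2 = rss / (n - 2)
    se_slope = float(np.sqrt(s2 / sxx))
    se_intercept = float(np.sqrt(s2 * (1.0 / n + xb * xb / sxx)))
    return slope, intercept, se_slope, se_intercept, rss


def _fit_hyperbolic(P: np.ndarray, t: np.ndarray) -> CPModelFit:
    # start from the work-time rearrangement, which is exact on clean data
    cp0, wp0, *_ = _work_time_params(P, t)
    cp_hi = float(P.min()) - 1e-6
    p0 = np.array([np.clip(cp0, 1e-3, cp_hi - 1e-3), max(wp0, 1.0)])

    def resid(q):
        cp, wp = q
        return wp / (P - cp) - t

    res = least_squares(
        resid, p0, bounds=([1e-6, 1e-6], [cp_hi, np.inf]), xtol=1e-12, ftol=1e-12,
        gtol=1e-12, max_nfev=5000,
    )
    cp, wp = res.x
    rss = float(2.0 * res.cost)
    n = len(P)
    dof = n - 2
    J = res.jac
    # linearized covariance at the optimum: (JᵀJ)⁻¹ · rss/dof
    JTJ = J.T @ J
    try:
        cov = np.linalg.pinv(JTJ) * (rss / dof)
        se_cp = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_wp = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_cp = se_wp = float("inf")
    return CPModelFit(
        model="hyperbolic", cp=float(cp), w_prime=float(wp),
        see_w_prime=se_wp, see_cp=se_cp, rss=rss,
    )


def _work_time_params(P: np.ndarray, t: np.ndarray):
    W = P * t
    slope, intercept, se_slope, se_intercept, rss = _ols(t, W)
    return slope, intercept, se_slope, se_intercept, rss


def fit_cp(points: Sequence, model: str) -> CPModelFit:
    """Fit one critical-power model to ≥ 3 power–duration points."""
    if model not in CP_MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {CP_MODELS}")
    pts = _as_points(points)
    if len(pts) == 2:
        raise ValueError("SEE undefined with 2 points; need at least 3")
    if len(pts) < 3:
        raise ValueError("need at least 3 power-duration points")
    t = np.array([p.t_lim for p in pts])
    P = np.array([p.power for p in pts])
    if len(np.unique(t)) < len(t):
        raise ValueError("durations must be distinct")

    if model == "hyperbolic":
        return _fit_hyperbolic(P, t)
    if model == "linear_work_time":
        cp, wp, se_cp, se_wp, rss = _work_time_params(P, t)
        return CPModelFit(
            model=model, cp=cp, w_prime=wp, see_w_prime=se_wp, see_cp=se_cp, rss=rss
        )
    # linear_power_inv_time: P = W'/t + CP
    wp, cp, se_wp, se_cp, rss = _ols(1.0 / t, P)
    return CPModelFit(
        model=model, cp=cp, w_prime=wp, see_w_prime=se_wp, see_cp=se_cp, rss=rss
    )


def fit_all_cp_models(points: Sequence) -> dict[str, CPModelFit]:
    return {m: fit_cp(points, m) for m in CP_MODELS}


def select_cp_model(fits: Iterable[CPModelFit]) -> CPModelFit:
    """Keep the fit with the lowest standard error of W′.

    Invalid fits (non-positive parameters or undefined SEE) are excluded
    with a warning; exact ties fall back to a fixed parameterization order
    (power–1/t, then work–time, then hyperbolic).
    """
    fits = list(fits)
    valid = [f for f in fits if f.valid]
    for f in fits:
        if not f.valid:
            warnings.warn(f"excluding invalid CP fit ({f.model})", stacklevel=2)
    if not valid:
        raise ValueError("no valid CP model fit to select from")
    return min(valid, key=lambda f: (f.see_w_prime, _TIE_ORDER[f.model]))


def w_prime_energy(fit: CPModelFit, condition: str = "n/a") -> EnergyEstimate:
    """W′ of a CP fit expressed as an anaerobic-capacity estimate in kJ."""
    return EnergyEstimate(
        method="CP_WPRIME",
        total_kj=fit.w_prime / 1000.0,
        components={"w_prime_kj": fit.w_prime / 1000.0},
        condition=condition,
        extras={"cp_w": fit.cp, "see_w_prime_j": fit.see_w_prime},
    )
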