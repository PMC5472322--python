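"""Synthetic breath-by-breath physiology for a caffeine/placebo crossover.

Generates everything the analysis pipeline consumes — ramp tests,
constant-load trials with exhaustion times, recovery off-transients and
plasma lactate samples — from a known :class:`ParticipantTruth`, so each
estimation stage can be validated by parameter recovery.

The generative model:

* steady-state oxygen cost is linear in power (``demand_intercept +
  demand_slope·P``), with an additional slow-component ramp above the gas
  exchange threshold saturating after 180 s;
* the on-transient is mono-exponential with time constant ``tau_on`` and the
  attained VO₂ is capped at ``vo2peak``;
* exhaustion above critical power follows the two-parameter hyperbola
  exactly: t_lim = W′ / (P − CP);
* the recovery off-transient is the biexponential curve evaluated exactly at
  the participant's own off-kinetics parameters;
* peak post-exercise lactate rises linearly with the mechanical work done
  above critical power (``lactate_per_kj``);
* measurement noise is i.i.d. Gaussian per breath on VO₂ and VCO₂, with
  breath timestamps jittered uniformly around a mean breath interval.

The treatment arm enters only as additive shifts to CP and W′ — submaximal
gas exchange is deliberately condition-independent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .gas_exchange import BreathSeries, LactateSeries
from .maod_alt import off_kinetics_model

__all__ = [
    "ParticipantTruth",
    "Condition",
    "SimulatedTrial",
    "PLACEBO",
    "default_caffeine",
    "make_participant",
    "workload_power",
    "simulate_incremental",
    "simulate_constant_load",
    "simulate_warmup",
    "simulate_crossover_study",
    "WORKLOADS",
]

#: Study workloads: Δ-fraction intensities (fixed 10-min) and %VO₂peak
#: intensities (to exhaustion).  p120 is the supramaximal MAOD bout with
#: recovery gas exchange and lactate sampling.
WORKLOADS = ("d10", "d20", "d40", "d50", "d80", "p100", "p120")
_EXHAUSTIVE = ("d80", "p100", "p120")
_DELTA_FRACTION = {"d10": 0.10, "d20": 0.20, "d40": 0.40, "d50": 0.50, "d80": 0.80}
_PEAK_FRACTION = {"p100": 1.00, "p120": 1.20}

# VCO₂-vs-VO₂ v-slope shape: sub-threshold slope and the steeper
# supra-threshold slope driven by bicarbonate buffering.
_VCO2_SLOPE_BELOW = 0.85
_VCO2_SLOPE_ABOVE = 1.30


@dataclass(frozen=True)
class Condition:
    """A treatment arm, encoded purely as additive CP/W′ shifts."""

    label: str
    cp_shift: float = 0.0  # W, additive
    w_prime_shift: float = 0.0  # J, additive

    def __post_init__(self):
        if self.label not in ("caffeine", "placebo"):
            raise ValueError("label must be 'caffeine' or 'placebo'")


PLACEBO = Condition("placebo", 0.0, 0.0)


def default_caffeine(cp_shift: float = 25.0, w_prime_shift: float = -3000.0) -> Condition:
    """The default treatment arm: CP raised 25 W, W′ lowered 3 kJ."""
    return Condition("caffeine", cp_shift, w_prime_shift)


@dataclass(frozen=True)
class ParticipantTruth:
    """Ground-truth physiology of one synthetic participant."""

    body_mass: float  # kg
    vo2peak: float  # L·min⁻¹
    get_vo2: float  # L·min⁻¹
    get_power: float  # W
    demand_slope: float  # L·min⁻¹·W⁻¹
    demand_intercept: float  # L·min⁻¹
    tau_on: float  # s, on-transient time constant
    slow_amp: float  # L·min⁻¹, extra demand above GET after 180 s
    cp: float  # W
    w_prime: float  # J
    ge_true: float  # dimensionless gross efficiency
    off_params: tuple[float, float, float, float, float, float]  # (vo2base, A1, tau1, A2, tau2, delta)
    lactate_rest: float  # mmol·L⁻¹
    lactate_per_kj: float  # mmol·L⁻¹ per kJ of supra-CP work
    noise_sd: float = 0.05  # L·min⁻¹ per breath
    breath_interval_mean: float = 2.0  # s

    def __post_init__(self):
        checks = {
            "body_mass": self.body_mass > 0,
            "vo2peak": self.vo2peak > 0,
            "get_vo2": 0 < self.get_vo2 < self.vo2peak,
            "get_power": self.get_power > 0,
            "demand_slope": self.demand_slope > 0,
            "tau_on": self.tau_on > 0,
            "slow_amp": self.slow_amp >= 0,
            "cp": self.cp > 0,
            "w_prime": self.w_prime > 0,
            "ge_true": 0 < self.ge_true < 1,
            "lactate_rest": self.lactate_rest >= 0,
            "lactate_per_kj": self.lactate_per_kj >= 0,
            "noise_sd": self.noise_sd >= 0,
            "breath_interval_mean": self.breath_interval_mean > 0,
        }
        for name, ok in checks.items():
            if not ok:
                raise ValueError(f"invalid value for field {name!r}: {getattr(self, name)}")
        vo2base, a1, tau1, a2, tau2, delta = self.off_params
        if tau1 <= 0 or not tau1 < tau2:
            raise ValueError("invalid value for field 'off_params': need 0 < tau1 < tau2")
        if min(vo2base, a1, a2) < 0 or delta < 0:
            raise ValueError(
                "invalid value for field 'off_params': amplitudes, baseline and delay must be >= 0"
            )

    def demand(self, power: float) -> float:
        """Steady-state primary-component oxygen cost at ``power``, L·min⁻¹."""
        return self.demand_intercept + self.demand_slope * power


@dataclass(frozen=True)
class SimulatedTrial:
    """One constant-load bout plus its optional recovery and lactate data."""

    breaths: BreathSeries
    truth: ParticipantTruth
    condition: Condition
    power: float  # W
    time_to_exhaustion: float | None = None  # s; None for fixed-duration bouts
    off_breaths: BreathSeries | None = None
    lactate: LactateSeries | None = None
    workload: str = ""
    participant_id: int | None = None


# ---------------------------------------------------------------------------
# participant sampling


def _trial_rng(*keys: int) -> np.random.Generator:
    """Stable per-trial stream: hashing the key tuple through SeedSequence
    keeps streams independent of how many other trials are generated."""
    return np.random.default_rng(np.random.SeedSequence(list(keys)))


def make_participant(seed: int, overrides: dict | None = None) -> ParticipantTruth:
    """Draw one participant from the study population.

    Defaults are centred on the group means of a recreationally active male
    cohort (body mass ≈ 74 kg, VO₂peak ≈ 3.0 L·min⁻¹, GET ≈ 55% of peak,
    CP ≈ 165 W, W′ ≈ 19 kJ).  Draws are truncated to physiological ranges,
    and CP is constrained relative to the Δ80 power so that all exhaustive
    workloads sit in the severe domain (roughly 110–170% of CP) for either
    treatment arm.  Deterministic for a given seed.
    """
    if not (isinstance(seed, (int, np.integer)) and seed >= 0):
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(int(seed))

    def draw(mean, sd, lo, hi):
        return float(np.clip(rng.normal(mean, sd), lo, hi))

    body_mass = draw(74.1, 7.0, 55.0, 95.0)
    vo2peak = draw(2.99, 0.39, 2.0, 4.2)
    get_frac = draw(0.55, 0.04, 0.45, 0.68)
    get_vo2 = get_frac * vo2peak
    demand_slope = draw(0.0103, 0.0006, 0.0085, 0.0120)
    demand_intercept = draw(0.50, 0.05, 0.35, 0.65)
    get_power = (get_vo2 - demand_intercept) / demand_slope
    tau_on = draw(32.0, 4.0, 22.0, 45.0)
    slow_amp = draw(0.25, 0.05, 0.10, 0.40)
    # Δ80 power anchors the CP range: CP sits 70-110 W below the Δ80 power,
    # placing Δ80 deep in the severe domain while the 120% VO₂peak bout lies
    # ~120-160 W above CP, where a +25 W / −3 kJ arm shift leaves the time to
    # exhaustion nearly unchanged (the study-condition pattern).
    p_d80 = (get_vo2 + 0.8 * (vo2peak - get_vo2) - demand_intercept) / demand_slope
    cp = draw(165.0, 25.0, p_d80 - 110.0, p_d80 - 70.0)
    w_prime = draw(19300.0, 3500.0, 13500.0, 27000.0)
    # recreationally active (untrained) cyclists: gross efficiency ~18%
    ge_true = draw(0.18, 0.012, 0.15, 0.22)
    off_params = (
        draw(0.38, 0.04, 0.28, 0.50),  # vo2base
        draw(1.05, 0.10, 0.70, 1.40),  # a1
        draw(52.0, 8.0, 30.0, 80.0),   # tau1
        draw(0.28, 0.05, 0.10, 0.50),  # a2
        draw(420.0, 60.0, 250.0, 700.0),  # tau2
        draw(5.0, 1.5, 0.5, 12.0),     # delta
    )
    lactate_rest = draw(1.4, 0.4, 0.5, 3.0)
    lactate_per_kj = draw(0.47, 0.05, 0.30, 0.65)

    values = dict(
        body_mass=body_mass, vo2peak=vo2peak, get_vo2=get_vo2, get_power=get_power,
        demand_slope=demand_slope, demand_intercept=demand_intercept, tau_on=tau_on,
        slow_amp=slow_amp, cp=cp, w_prime=w_prime, ge_true=ge_true,
        off_params=off_params, lactate_rest=lactate_rest, lactate_per_kj=lactate_per_kj,
    )
    if overrides:
        valid = {f.name for f in dataclasses.fields(ParticipantTruth)}
        unknown = set(overrides) - valid
        if unknown:
            raise ValueError(f"unknown override field(s): {sorted(unknown)}")
        values.update(overrides)
    return ParticipantTruth(**values)


def workload_power(truth: ParticipantTruth, workload: str) -> float:
    """Prescribed power (nearest W) for a named study workload, obtained by
    inverting the participant's demand line at the target VO₂."""
    if workload in _DELTA_FRACTION:
        target = truth.get_vo2 + _DELTA_FRACTION[workload] * (truth.vo2peak - truth.get_vo2)
    elif workload in _PEAK_FRACTION:
        target = _PEAK_FRACTION[workload] * truth.vo2peak
    else:
        raise ValueError(f"unknown workload {workload!r}; expected one of {WORKLOADS}")
    return float(round((target - truth.demand_intercept) / truth.demand_slope))


# ---------------------------------------------------------------------------
# breath machinery


def _breath_times(rng: np.random.Generator, duration: float, interval: float) -> np.ndarray:
    n = max(int(np.ceil(duration / max(interval - 0.5, 0.5))) + 4, 3)
    gaps = interval + rng.uniform(-0.5, 0.5, size=n) * min(1.0, interval / 2.0)
    t = np.cumsum(gaps)
    t = t[t <= duration]
    if len(t) < 2:
        t = np.array([interval / 2.0, duration])
    elif t[-1] < duration - 1e-9:
        # the final breath is stamped at bout end (exhaustion / protocol stop)
        t = np.append(t, duration)
    return t


def _vco2_of_vo2(v: np.ndarray, get_vo2: float) -> np.ndarray:
    """Piecewise v-slope map: VCO₂ rises disproportionately above the GET."""
    below = _VCO2_SLOPE_BELOW * np.minimum(v, get_vo2)
    above = _VCO2_SLOPE_ABOVE * np.clip(v - get_vo2, 0.0, None)
    return below + above


def _emit(
    rng, t, vo2_clean, vco2_clean, noise_sd, power=None
) -> BreathSeries:
    vo2 = np.clip(vo2_clean + rng.normal(0.0, noise_sd, len(t)), 0.0, None)
    vco2 = np.clip(vco2_clean + rng.normal(0.0, noise_sd, len(t)), 0.0, None)
    ve = 24.0 * vco2_clean + rng.normal(0.0, 2.0 * noise_sd, len(t))
    return BreathSeries(t=t, vo2=vo2, vco2=vco2, ve=np.clip(ve, 0.0, None), power=power)


# ---------------------------------------------------------------------------
# protocols


def simulate_incremental(
    truth: ParticipantTruth,
    start_power: float = 50.0,
    ramp: float = 25.0,
    seed: int = 0,
    dwell: float = 120.0,
) -> BreathSeries:
    """A ramp test: power rises ``ramp`` W·min⁻¹ from ``start_power``.

    VO₂ tracks the (peak-capped) instantaneous demand through the
    first-order on-transient, solved in closed form; the test ends ``dwell``
    seconds after demand first reaches VO₂peak, emulating the brief plateau
    before volitional exhaustion.
    """
    if ramp <= 0:
        raise ValueError("ramp must be positive")
    rng = _trial_rng(int(seed), 101)
    k = truth.demand_slope * ramp / 60.0  # L·min⁻¹ per s of ramp
    d0 = truth.demand(start_power)
    t_cap = max(((truth.vo2peak - truth.demand_intercept) / truth.demand_slope - start_power)
                / (ramp / 60.0), 0.0)
    t_end = t_cap + dwell
    t = _breath_times(rng, t_end, truth.breath_interval_mean)
    tau = truth.tau_on

    # closed-form first-order response: linear ramp input, then constant
    v = np.empty_like(t)
    ramp_phase = t <= t_cap
    # V(0) = d0 (warmed-up start)
    v[ramp_phase] = d0 + k * (t[ramp_phase] - tau) + k * tau * np.exp(-t[ramp_phase] / tau)
    v1 = d0 + k * (t_cap - tau) + k * tau * np.exp(-t_cap / tau)
    v[~ramp_phase] = truth.vo2peak + (v1 - truth.vo2peak) * np.exp(-(t[~ramp_phase] - t_cap) / tau)
    v = np.minimum(v, truth.vo2peak)

    vco2 = _vco2_of_vo2(v, truth.get_vo2)
    power = start_power + ramp * t / 60.0
    return _emit(rng, t, v, vco2, truth.noise_sd, power=power)


def _constant_load_vo2(truth: ParticipantTruth, power: float, t: np.ndarray) -> np.ndarray:
    target = np.full_like(t, truth.demand(power))
    if power > truth.get_power:
        target = target + truth.slow_amp * np.minimum(t, 180.0) / 180.0
    target = np.minimum(target, truth.vo2peak)
    return target * (1.0 - np.exp(-t / truth.tau_on))


def simulate_constant_load(
    truth: ParticipantTruth,
    condition: Condition,
    power: float,
    max_duration: float = 600.0,
    to_exhaustion: bool = False,
    seed: int = 0,
    with_recovery: bool = False,
    with_lactate: bool = False,
    recovery_duration: float = 600.0,
    workload: str = "",
    participant_id: int | None = None,
) -> SimulatedTrial:
    """One constant-load bout under a treatment arm.

    With ``to_exhaustion=True`` the bout must lie above the arm-shifted
    critical power; its duration is then exactly W′_eff / (P − CP_eff).
    ``with_recovery`` adds the biexponential off-transient (t = 0 at exercise
    end) and ``with_lactate`` the pre/post plasma lactate samples, both of
    which only the supramaximal protocol records.
    """
    if power <= 0:
        raise ValueError("power must be positive")
    cp_eff = truth.cp + condition.cp_shift
    wp_eff = truth.w_prime + condition.w_prime_shift
    if to_exhaustion:
        if power <= cp_eff:
            raise ValueError(
                f"power {power:g} W is not above effective CP {cp_eff:g} W: "
                "no finite time to exhaustion"
            )
        tte = wp_eff / (power - cp_eff)
        duration = tte
    else:
        tte = None
        duration = max_duration

    rng = _trial_rng(int(seed), 202)
    t = _breath_times(rng, duration, truth.breath_interval_mean)
    v = _constant_load_vo2(truth, power, t)
    vco2 = _vco2_of_vo2(v, truth.get_vo2)
    breaths = _emit(rng, t, v, vco2, truth.noise_sd, power=np.full_like(t, float(power)))

    off = None
    if with_recovery:
        t_off = _breath_times(rng, recovery_duration, truth.breath_interval_mean)
        v_off = off_kinetics_model(t_off, *truth.off_params)
        off = _emit(rng, t_off, v_off, 0.9 * v_off, truth.noise_sd)

    lact = None
    if with_lactate:
        supra_work_kj = max(power - cp_eff, 0.0) * duration / 1000.0
        peak = truth.lactate_rest + truth.lactate_per_kj * supra_work_kj
        # deterministic sampling profile: peak at 3 min, slightly lower at 1 and 5
        lact = LactateSeries(
            samples=((60.0, 0.94 * peak), (180.0, peak), (300.0, 0.97 * peak)),
            pre_exercise=truth.lactate_rest,
        )

    return SimulatedTrial(
        breaths=breaths, truth=truth, condition=condition, power=float(power),
        time_to_exhaustion=tte, off_breaths=off, lactate=lact,
        workload=workload, participant_id=participant_id,
    )


def simulate_warmup(
    truth: ParticipantTruth,
    condition: Condition = PLACEBO,
    duration: float = 300.0,
    seed: int = 0,
    rer: float = 0.88,
    power_fraction_of_get: float = 0.90,
) -> SimulatedTrial:
    """The 5-min moderate warm-up (90% of GET power) used to measure gross
    efficiency.

    Here the steady VO₂ is derived from the participant's true gross
    efficiency (VO₂ such that external power / metabolic power = GE), and
    VCO₂ from the target RER, so the efficiency estimator can be validated
    by round trip.
    """
    power = round(power_fraction_of_get * truth.get_power)
    steady = power * 60.0 / (truth.ge_true * (4940.0 * rer + 16040.0))
    rng = _trial_rng(int(seed), 303)
    t = _breath_times(rng, duration, truth.breath_interval_mean)
    v = steady * (1.0 - np.exp(-t / truth.tau_on))
    vco2 = rer * v
    breaths = _emit(rng, t, v, vco2, truth.noise_sd, power=np.full_like(t, float(power)))
    return SimulatedTrial(
        breaths=breaths, truth=truth, condition=condition, power=float(power),
        workload="warmup",
    )


def simulate_crossover_study(
    n_participants: int,
    seed: int,
    caffeine: Condition | None = None,
    noise_sd: float | None = None,
) -> list[SimulatedTrial]:
    """A full two-arm crossover: 7 workloads × 2 conditions per participant.

    Δ10–Δ50 are fixed 10-min bouts; Δ80, 100% and 120% VO₂peak go to
    exhaustion; the 120% bout carries recovery gas exchange and lactate.
    Each trial draws from its own random stream keyed by (master seed,
    participant, workload, condition), so trials are reproducible
    independently of each other.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    caffeine = caffeine if caffeine is not None else default_caffeine()
    conditions = (caffeine, PLACEBO)
    trials: list[SimulatedTrial] = []
    for pid in range(n_participants):
        pseed = int(np.random.SeedSequence([int(seed), pid]).generate_state(1)[0] % (2**31))
        truth = make_participant(pseed)
        if noise_sd is not None:
            truth = dataclasses.replace(truth, noise_sd=noise_sd)
        for wi, wl in enumerate(WORKLOADS):
            power = workload_power(truth, wl)
            for ci, cond in enumerate(conditions):
                tseed = int(
                    np.random.SeedSequence([int(seed), pid, wi, ci]).generate_state(1)[0]
                    % (2**31)
                )
                trials.append(
                    simulate_constant_load(
                        truth, cond, power,
                        to_exhaustion=wl in _EXHAUSTIVE,
                        with_recovery=wl == "p120",
                        with_lactate=wl == "p120",
                        seed=tseed, workload=wl, participant_id=pid,
                    )
                )
    return trials
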