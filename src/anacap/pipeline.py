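"""Study-level orchestration: per-participant and per-study analysis tables."""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .critical_power import fit_all_cp_models, select_cp_model, w_prime_energy
from .energy import EnergyEstimate
from .gross_efficiency import anaerobic_work, gross_efficiency_from_warmup
from .maod import maod_matrix
from .maod_alt import compute_maod_alt, fit_off_kinetics
from .synthetic import SimulatedTrial

__all__ = ["group_trials", "analyze_participant", "analyze_study"]

_CONDITIONS = ("caffeine", "placebo")
_CP_WORKLOADS = ("d80", "p100", "p120")


def group_trials(trials: Iterable[SimulatedTrial]) -> dict[int, dict[tuple[str, str], SimulatedTrial]]:
    """Index a flat trial list by participant, then by (workload, condition)."""
    out: dict[int, dict[tuple[str, str], SimulatedTrial]] = {}
    for tr in trials:
        out.setdefault(tr.participant_id, {})[(tr.workload, tr.condition.label)] = tr
    return out


def analyze_participant(
    trial_map: Mapping[tuple[str, str], SimulatedTrial],
    warmups: Mapping[str, SimulatedTrial] | None = None,
    fit_recovery: bool = True,
) -> dict:
    """All four anaerobic-capacity estimates for one participant.

    Returns a dict with keys ``maod`` (the three crossover variants),
    ``maod_alt`` and ``cp``/``w_prime`` per condition, and — when warm-up
    bouts are supplied — ``ge`` per condition.  ``fit_recovery=False`` skips
    the (comparatively slow) off-kinetics fit.
    """
    result: dict = {"maod": maod_matrix(trial_map)}

    if fit_recovery:
        result["maod_alt"] = {}
        for cond in _CONDITIONS:
            tr = trial_map[("p120", cond)]
            if tr.off_breaths is None or tr.lactate is None:
                raise ValueError(f"supramaximal bout ({cond}) lacks recovery or lactate data")
            fit = fit_off_kinetics(tr.off_breaths)
            result["maod_alt"][cond] = compute_maod_alt(
                fit, tr.lactate, tr.truth.body_mass, condition=cond
            )

    result["cp"], result["w_prime"] = {}, {}
    for cond in _CONDITIONS:
        pts = []
        for wl in _CP_WORKLOADS:
            tr = trial_map[(wl, cond)]
            if tr.time_to_exhaustion is None:
                raise ValueError(f"bout {(wl, cond)} has no time to exhaustion")
            pts.append((tr.power, tr.time_to_exhaustion))
        best = select_cp_model(fit_all_cp_models(pts).values())
        result["cp"][cond] = best
        result["w_prime"][cond] = w_prime_energy(best, condition=cond)

    if warmups is not None:
        result["ge"] = {}
        for cond in _CONDITIONS:
            wu = warmups[cond]
            eff = gross_efficiency_from_warmup(wu.breaths, wu.power)
            supra = trial_map[("p120", cond)]
            result["ge"][cond] = (
                eff,
                anaerobic_work(
                    supra.breaths, supra.power, eff, condition=cond,
                    t_end=supra.time_to_exhaustion,
                ),
            )
    return result


def analyze_study(
    trials: Iterable[SimulatedTrial],
    warmups: Mapping[int, Mapping[str, SimulatedTrial]] | None = None,
    fit_recovery: bool = True,
) -> pd.DataFrame:
    """Tidy per-participant results table for a whole crossover study.

    One row per (participant, method, condition) with the estimate in kJ
    (plus CP in W for the critical-power rows).
    """
    rows = []
    for pid, tmap in sorted(group_trials(trials).items()):
        res = analyze_participant(
            tmap,
            warmups=None if warmups is None else warmups[pid],
            fit_recovery=fit_recovery,
        )
        for label, est in res["maod"].items():
            rows.append((pid, "MAOD_" + label.replace("-", "_"), est.condition, est.total_kj, None))
        if fit_recovery:
            for cond, est in res["maod_alt"].items():
                rows.append((pid, "MAOD_ALT", cond, est.total_kj, None))
        for cond, fitsel in res["cp"].items():
            rows.append((pid, "CP_WPRIME", cond, fitsel.w_prime / 1000.0, fitsel.cp))
        if "ge" in res:
            for cond, (_eff, est) in res["ge"].items():
                rows.append((pid, "GE_WORK", cond, est.total_kj, None))
    return pd.DataFrame(rows, columns=["participant", "method", "condition", "value_kj", "cp_w"])
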