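"""Shared result container for anaerobic-capacity estimates."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["EnergyEstimate", "O2_ENERGY_EQUIV_KJ_PER_L"]

#: Energy released per litre of O₂ consumed, kJ·L⁻¹ (standard aerobic equivalent).
O2_ENERGY_EQUIV_KJ_PER_L = 20.9

_METHODS = ("MAOD", "MAOD_ALT", "CP_WPRIME", "GE_WORK")


@dataclass(frozen=True)
class EnergyEstimate:
    """An anaerobic-capacity value in kJ with its method tag.

    ``components`` holds named energy parts in kJ that sum to ``total_kj``
    (e.g. alactic/lactic for the alternative oxygen-deficit method);
    ``extras`` carries diagnostic quantities in other units that are not part
    of the sum (litres of deficit, aerobic work, ...).  ``condition`` is the
    treatment arm of the supramaximal bout; ``demand_condition`` the arm of
    the submaximal bouts behind the demand regression (``"n/a"`` for methods
    that need none).
    """

    method: str
    total_kj: float
    components: dict[str, float] = field(default_factory=dict)
    condition: str = "n/a"
    demand_condition: str = "n/a"
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {_METHODS}")
        if self.components:
            s = sum(self.components.values())
            tol = 1e-9 * max(1.0, abs(self.total_kj))
            if abs(s - self.total_kj) > tol:
                raise ValueError(
                    f"components sum to {s:.6g} kJ but total_kj is {self.total_kj:.6g} kJ"
                )
        if self.method in ("MAOD", "MAOD_ALT") and self.total_kj < -1e-9:
            raise ValueError(f"{self.method} total must be non-negative")
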