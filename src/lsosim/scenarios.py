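"""Inhibition-loss scenarios and synaptic amplitude compensation.

Age-related loss of glycinergic MNTB fibers is modeled by reducing the
number of inhibitory inputs ``m_inh`` from its default of 8.  Three static
compensation rules set the unitary amplitude of the remaining inhibitory
synapses:

* ``uncompensated`` — amplitude stays at the default 12 nS; total inhibitory
  conductance shrinks in proportion to the fibers lost.
* ``compensated`` — amplitude is scaled by 8/m_inh so the total conductance
  (96 nS) is conserved exactly.
* ``overcompensated`` — on top of the compensated scaling, the amplitude is
  multiplied by (2 − m_inh/8), making the total conductance a linearly
  *decreasing* function of m_inh (150% of default at m_inh = 4, zero at 16).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

CompensationMode = Literal["uncompensated", "compensated", "overcompensated"]

_MODES = ("uncompensated", "compensated", "overcompensated")


@dataclass(frozen=True)
class ScenarioSpec:
    """Number of inhibitory inputs plus compensation mode."""

    m_inh: int
    mode: CompensationMode = "uncompensated"
    a_inh_default: float = 12.0   # nS, unitary inhibitory amplitude
    m_inh_default: int = 8        # healthy fiber count

    def __post_init__(self) -> None:
        if not 0 <= self.m_inh <= 16:
            raise ValueError(f"m_inh must be in [0, 16], got {self.m_inh}")
        if self.mode not in _MODES:
            raise ValueError(f"unknown compensation mode {self.mode!r}")
        if self.mode != "uncompensated" and self.m_inh == 0:
            raise ValueError(
                "compensated/overcompensated modes require m_inh >= 1: "
                "no fibers remain to potentiate"
            )

    @property
    def a_inh(self) -> float:
        return effective_inhibitory_amplitude(self)

    @property
    def total_inhibitory_conductance(self) -> float:
        """m_inh × unitary amplitude, in nS (the quantity compensation acts on)."""
        return self.m_inh * self.a_inh


def effective_inhibitory_amplitude(spec: ScenarioSpec) -> float:
    """Unitary inhibitory conductance amplitude (nS) under the scenario's rule."""
    a0, m0 = spec.a_inh_default, spec.m_inh_default
    if spec.mode == "uncompensated":
        return a0
    scaled = a0 * m0 / spec.m_inh
    if spec.mode == "compensated":
        return scaled
    # overcompensated: applied on top of the compensated amplitude
    return scaled * (2.0 - spec.m_inh / m0)
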