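"""Recording-solution conditions, reversal potentials and open-channel current.

Conventions used throughout the package: voltages in mV, time in ms at the
interface (seconds internally where rates are involved), K+ concentrations in
mM, blocker concentrations in M.  Outward current is positive, inward current
negative.  The thermal voltage defaults to 25 mV exactly, the convention used
in every rate-voltage expression in this line of work (not RT/F = 25.7 mV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError

__all__ = ["SolutionCondition", "nernst_potential", "open_channel_current"]


@dataclass(frozen=True)
class SolutionCondition:
    """K+ concentrations on each membrane side plus intracellular blockers.

    Parameters
    ----------
    k_in, k_out:
        Internal / external K+ concentration (mM).
    blockers:
        Mapping from blocker id (e.g. ``"Mg"``, ``"SPM"``) to its free
        intracellular concentration in molar.
    vt:
        Thermal voltage in mV.
    """

    k_in: float
    k_out: float
    blockers: Mapping[str, float] = field(default_factory=dict)
    vt: float = 25.0

    def __post_init__(self) -> None:
        if not (self.k_in > 0 and self.k_out > 0):
            raise ValueError(
                f"K+ concentrations must be positive, got k_in={self.k_in}, "
                f"k_out={self.k_out}"
            )
        if self.vt <= 0:
            raise ValueError(f"thermal voltage must be positive, got {self.vt}")
        for name, conc in self.blockers.items():
            if conc < 0:
                raise ValueError(f"negative concentration for blocker {name!r}: {conc}")
        # freeze the mapping so conditions are safely hashable/shareable
        object.__setattr__(self, "blockers", dict(self.blockers))

    @property
    def ek(self) -> float:
        """K+ reversal potential (mV)."""
        return nernst_potential(self)

    def concentration(self, blocker_id: str) -> float:
        """Free concentration (M) of a blocker; 0 M must be listed explicitly
        only when the blocker participates in the state model."""
        try:
            return self.blockers[blocker_id]
        except KeyError:
            raise ConfigurationError(
                f"blocker {blocker_id!r} not present in condition "
                f"(have {sorted(self.blockers)})"
            ) from None

    def with_blocker(self, blocker_id: str, conc: float) -> "SolutionCondition":
        """Copy of this condition with one blocker concentration replaced."""
        blockers = dict(self.blockers)
        blockers[blocker_id] = conc
        return SolutionCondition(self.k_in, self.k_out, blockers, self.vt)


def nernst_potential(cond: SolutionCondition) -> float:
    """K+ reversal potential E_K = vt * ln([K]out/[K]in), in mV."""
    return cond.vt * math.log(cond.k_out / cond.k_in)


def open_channel_current(V, cond: SolutionCondition, permeability: float = 0.01):
    """Goldman-Hodgkin-Katz open-channel current of a monovalent cation (pA).

    ``permeability`` is a lumped scale in pA/mM; it sets the unitary current
    amplitude without modelling the pore's true permeability.  Outward current
    is positive.  Accepts scalar or array voltage.

    For u = V/vt the GHK current is

        i = P * u * ([K]in - [K]out * exp(-u)) / (1 - exp(-u))

    which reverses exactly at E_K and is linear in V near 0 for symmetric K+.
    """
    if permeability <= 0:
        raise ValueError(f"permeability must be positive, got {permeability}")
    V = np.asarray(V, dtype=float)
    u = V / cond.vt
    small = np.abs(u) < 1e-8
    # u / (1 - e^{-u}) -> 1 + u/2 + O(u^2) as u -> 0
    with np.errstate(over="ignore"):
        ratio = np.where(small, 1.0 + u / 2.0, u / np.where(small, 1.0, -np.expm1(-u)))
    i = permeability * ratio * (cond.k_in - cond.k_out * np.exp(-u))
    return i if i.ndim else float(i)
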