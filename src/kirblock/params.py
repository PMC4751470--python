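"""Blocker kinetic parameters, genotype multipliers, and shipped presets.

A :class:`BlockerSpec` holds the voltage-dependent rate parameters of one
intracellular blocker; a :class:`GenotypeSpec` is a named set of positive
multipliers applied to those parameters (mutations are modelled purely as
barrier-height / coupling-strength scalings, never structurally).

The default parameter values live in ``data/presets.json`` (versioned). The
WT/E224G/M183W/E224G-M183W unblocking pairs follow the published Woodhull
parameters for Mg2+ block of Kir2.1; the flux-coupling strengths are
calibrated so the closed-form inward-rectification index (Kd(-30)/Kd(+30) in
symmetric 100 mM K+) equals ~95 for Mg2+ and ~1.02e5 for spermine. See
docs/methods.md for provenance of every number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import ConfigurationError

__all__ = [
    "BlockerSpec",
    "GenotypeSpec",
    "load_presets",
    "blocker_preset",
    "genotype_preset",
    "PRESET_VERSION",
]

PRESET_VERSION = "1.0"

# BlockerSpec fields a genotype multiplier may scale
_SCALABLE = (
    "kon0",
    "delta_on",
    "koff0",
    "zdelta_off",
    "theta",
    "vs",
    "kexit0",
    "zdelta_exit",
)


@dataclass(frozen=True)
class BlockerSpec:
    """Kinetic parameters of one intracellular pore blocker.

    Attributes
    ----------
    id:
        Label ("Mg", "SPM", or custom).
    valence:
        Effective charge Z carried through rate-voltage expressions
        (2 for Mg2+, 4 for spermine).
    kon0:
        Second-order blocking rate constant at 0 mV (M^-1 s^-1).
    delta_on:
        Electrical distance of the entry barrier; the blocking rate scales as
        exp(Z * delta_on * V / vt).
    koff0:
        Unblocking rate to the intracellular side at 0 mV (s^-1).
    zdelta_off:
        Z*delta of unbinding; the unblocking rate scales as
        exp(-zdelta_off * V / vt).
    theta, vs:
        Flux-coupling strength (dimensionless) and saturation scale (mV):
        net outward K+ flux retards unblocking by
        exp(-theta * max(tanh((V - E_K)/vs), 0)).
    kexit0, zdelta_exit:
        Punch-through (outward exit through the selectivity filter) rate at
        0 mV (s^-1) and its voltage sensitivity; 0 for Mg2+, which cannot
        traverse the filter.
    """

    id: str
    valence: int
    kon0: float
    delta_on: float
    koff0: float
    zdelta_off: float
    theta: float = 0.0
    vs: float = 15.0
    kexit0: float = 0.0
    zdelta_exit: float = 0.0

    def __post_init__(self) -> None:
        if self.valence not in (1, 2, 3, 4):
            raise ValueError(f"valence must be in 1..4, got {self.valence}")
        if self.kon0 <= 0 or self.koff0 <= 0:
            raise ValueError("kon0 and koff0 must be positive")
        if self.kexit0 < 0:
            raise ValueError("kexit0 must be non-negative")
        if self.id == "Mg" and self.kexit0 != 0:
            raise ValueError("Mg2+ cannot punch through the filter: kexit0 must be 0")
        if self.vs <= 0:
            raise ValueError("vs must be positive")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")


@dataclass(frozen=True)
class GenotypeSpec:
    """Named set of positive multipliers on :class:`BlockerSpec` fields."""

    name: str
    multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.multipliers.items():
            if key not in _SCALABLE:
                raise ValueError(f"unknown multiplier target {key!r}")
            if value < 0:
                raise ValueError(f"multiplier for {key!r} must be >= 0, got {value}")
        object.__setattr__(self, "multipliers", dict(self.multipliers))

    def apply(self, spec: BlockerSpec) -> BlockerSpec:
        """Return the blocker spec with this genotype's scalings applied."""
        changes = {
            key: getattr(spec, key) * mult for key, mult in self.multipliers.items()
        }
        return replace(spec, **changes)


def _presets_raw(path: str | Path | None = None) -> dict:
    if path is None:
        text = (
            resources.files("kirblock").joinpath("data/presets.json").read_text()
        )
    else:
        text = Path(path).read_text()
    return json.loads(text)


def load_presets(path: str | Path | None = None) -> dict:
    """Load the shipped (or a user-supplied) preset file.

    Returns a dict with keys ``version``, ``blockers`` (id -> BlockerSpec) and
    ``genotypes`` (name -> GenotypeSpec).
    """
    raw = _presets_raw(path)
    blockers = {
        bid: BlockerSpec(id=bid, **params) for bid, params in raw["blockers"].items()
    }
    genotypes = {
        name: GenotypeSpec(name=name, multipliers=mult)
        for name, mult in raw["genotypes"].items()
    }
    return {"version": raw["version"], "blockers": blockers, "genotypes": genotypes}


_CACHE: dict | None = None


def _default_presets() -> dict:
    global _CACHE
    if _CACHE is None:
        _CACHE = load_presets()
    return _CACHE


def blocker_preset(blocker_id: str, genotype: str = "WT") -> BlockerSpec:
    """Shipped blocker parameters, with a genotype's multipliers applied."""
    presets = _default_presets()
    try:
        spec = presets["blockers"][blocker_id]
    except KeyError:
        raise ConfigurationError(f"no preset for blocker {blocker_id!r}") from None
    return genotype_preset(genotype).apply(spec)


def genotype_preset(name: str) -> GenotypeSpec:
    presets = _default_presets()
    try:
        return presets["genotypes"][name]
    except KeyError:
        raise ConfigurationError(f"no preset for genotype {name!r}") from None


def list_genotypes() -> list[str]:
    return sorted(_default_presets()["genotypes"])


# re-export for callers composing overrides
def override(spec: BlockerSpec, **changes) -> BlockerSpec:
    """Copy of a blocker spec with explicit field overrides."""
    valid = {f.name for f in fields(BlockerSpec)}
    unknown = set(changes) - valid
    if unknown:
        raise ValueError(f"unknown BlockerSpec fields: {sorted(unknown)}")
    return replace(spec, **changes)
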