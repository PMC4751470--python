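"""Synthetic voltage-clamp sweeps from the kinetic state model.

A sweep is the macroscopic current of ``n_channels`` identical, independent
channels: I(t) = N * P_open(t) * i_open(V) + Gaussian noise.  Occupancy is
propagated continuously across segment boundaries (starting from the steady
state of the first segment), so relaxations and tails are exact solutions of
the master equation sampled on the protocol's grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .conditions import SolutionCondition, open_channel_current
from .errors import DesignError
from .markov import StateModel, relax_occupancy, steady_state
from .protocols import VoltageProtocol

__all__ = [
    "Sweep",
    "Experiment",
    "simulate_sweep",
    "generate_experiment",
    "average_experiments",
]


@dataclass
class Sweep:
    """One simulated sweep: sampled time (ms), current (pA), voltage (mV)."""

    time: np.ndarray
    current: np.ndarray
    voltage: np.ndarray
    protocol: VoltageProtocol
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if not (self.time.shape == self.current.shape == self.voltage.shape):
            raise ValueError("time, current and voltage must have equal length")
        if not (
            np.all(np.isfinite(self.time))
            and np.all(np.isfinite(self.current))
            and np.all(np.isfinite(self.voltage))
        ):
            raise ValueError("sweep arrays must be finite")

    def segment_slice(self, index: int) -> slice:
        bounds = self.protocol.segment_bounds()
        if not 0 <= index < len(bounds):
            raise IndexError(
                f"segment {index} out of range for protocol with "
                f"{len(bounds)} segments"
            )
        i0, i1 = bounds[index]
        return slice(i0, i1)

    def segment_level(self, index: int) -> float:
        return self.protocol.segments[index][0]

    def condition(self) -> SolutionCondition:
        m = self.meta
        return SolutionCondition(
            m["k_in"], m["k_out"], m.get("blockers", {}), m.get("vt", 25.0)
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Sweep):
            return NotImplemented
        return (
            np.array_equal(self.time, other.time)
            and np.array_equal(self.current, other.current)
            and np.array_equal(self.voltage, other.voltage)
            and self.protocol == other.protocol
            and self.meta == other.meta
        )


@dataclass
class Experiment:
    """A set of sweeps plus the factor table that generated them."""

    sweeps: list
    design: pd.DataFrame
    name: str = ""

    def select(self, **criteria) -> list:
        """Sweeps whose meta matches all given key=value criteria."""
        out = []
        for sw in self.sweeps:
            if all(sw.meta.get(k) == v for k, v in criteria.items()):
                out.append(sw)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, Experiment):
            return NotImplemented
        return (
            self.name == other.name
            and len(self.sweeps) == len(other.sweeps)
            and all(a == b for a, b in zip(self.sweeps, other.sweeps))
            and self.design.equals(other.design)
        )


def simulate_sweep(
    model: StateModel,
    protocol: VoltageProtocol,
    cond: SolutionCondition,
    n_channels: int = 200,
    permeability: float = 0.01,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    meta: dict | None = None,
) -> Sweep:
    """Simulate one sweep.  Identical inputs and seed give identical output.

    The initial occupancy is the steady state at the first segment's level;
    each later segment starts from the exact end-of-segment occupancy of the
    previous one.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    dt = protocol.sample_interval
    p = steady_state(model, protocol.segments[0][0], cond)
    po = np.empty(protocol.n_samples)
    current = np.empty(protocol.n_samples)
    for (level, dur), (i0, i1) in zip(protocol.segments, protocol.segment_bounds()):
        n = i1 - i0
        # sample times within the segment, plus the boundary for hand-off
        t_s = np.append(np.arange(n) * dt, dur) / 1e3
        occ = relax_occupancy(model, level, cond, p, t_s)
        po[i0:i1] = occ[:-1, 0]
        p = occ[-1]
        current[i0:i1] = (
            n_channels * po[i0:i1] * open_channel_current(level, cond, permeability)
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd, current.size)
    full_meta = {
        "k_in": cond.k_in,
        "k_out": cond.k_out,
        "vt": cond.vt,
        "blockers": dict(cond.blockers),
        "n_channels": n_channels,
        "permeability": permeability,
        "noise_sd": noise_sd,
        "seed": seed,
        "protocol": protocol.name,
    }
    if meta:
        full_meta.update(meta)
    return Sweep(
        time=protocol.times(),
        current=current,
        voltage=protocol.voltage_trace(),
        protocol=protocol,
        meta=full_meta,
    )


def generate_experiment(cells: Iterable, seed: int, name: str = "") -> Experiment:
    """Simulate every cell of a design, with per-sweep seeds derived from the
    master seed by stable enumeration order.

    ``cells`` is an iterable of :class:`kirblock.designs.DesignCell`.
    """
    cells = list(cells)
    if not cells:
        raise DesignError("empty design")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(cells))
    sweeps = []
    records = []
    for i, cell in enumerate(cells):
        sw = simulate_sweep(
            model=cell.model(),
            protocol=cell.protocol,
            cond=cell.condition(),
            n_channels=cell.n_channels,
            permeability=cell.permeability,
            noise_sd=cell.noise_sd,
            seed=int(child_seeds[i]),
            meta={
                "genotype": cell.genotype,
                "group": cell.group,
                "label": cell.label,
                **cell.extra_meta,
            },
        )
        sweeps.append(sw)
        rec = {
            "label": cell.label,
            "genotype": cell.genotype,
            "group": cell.group,
            "protocol": cell.protocol.name,
            "k_in": cell.k_in,
            "k_out": cell.k_out,
            "seed": int(child_seeds[i]),
        }
        rec.update({f"conc_{b}": c for b, c in cell.blockers.items()})
        records.append(rec)
    return Experiment(sweeps=sweeps, design=pd.DataFrame(records), name=name)


def average_experiments(experiments: Sequence[Experiment]) -> Experiment:
    """Ensemble average of repeated runs of the same design.

    Mirrors averaging repeated sweeps from several patches: currents are
    averaged sample-wise per design cell and the recorded noise level is
    reduced by sqrt(n).  All experiments must share the design (same cells in
    the same order); seeds may differ.
    """
    experiments = list(experiments)
    if not experiments:
        raise DesignError("no experiments to average")
    first = experiments[0]
    for other in experiments[1:]:
        if len(other.sweeps) != len(first.sweeps):
            raise DesignError("experiments have different numbers of sweeps")
    n = len(experiments)
    sweeps = []
    for i, sw in enumerate(first.sweeps):
        mates = [e.sweeps[i] for e in experiments]
        if any(m.protocol != sw.protocol for m in mates):
            raise DesignError(f"sweep {i}: protocols differ across experiments")
        mean_current = np.mean([m.current for m in mates], axis=0)
        meta = dict(sw.meta)
        meta["noise_sd"] = float(meta.get("noise_sd", 0.0)) / math.sqrt(n)
        meta["n_averaged"] = n
        sweeps.append(
            Sweep(
                time=sw.time.copy(),
                current=mean_current,
                voltage=sw.voltage.copy(),
                protocol=sw.protocol,
                meta=meta,
            )
        )
    return Experiment(sweeps=sweeps, design=first.design.copy(), name=first.name)
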