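"""Factorial experiment designs mirroring the study's figure designs.

Each factory returns a list of :class:`DesignCell` to feed to
:func:`kirblock.simulate.generate_experiment`.  Defaults reproduce the study
conditions: symmetric 100 mM K+ unless stated, Mg2+ doses up to 3 mM, SPM in
the 0.01-10 uM range, the step-family and two-pulse protocols.

Sampling intervals: the dose-response designs keep the 0.1 ms (10 kHz)
default; tail-kinetics designs sample at 2-10 us because the fastest
unblocking relaxations (WT Mg2+ at -100 mV) have time constants of tens of
microseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .conditions import SolutionCondition
from .markov import StateModel
from .params import blocker_preset
from .protocols import VoltageProtocol, make_protocol

__all__ = [
    "DesignCell",
    "dose_response_design",
    "woodhull_tail_design",
    "variable_depol_design",
    "onset_rate_design",
    "synergy_design",
]

# default instrument/patch scale
N_CHANNELS = 1000
PERMEABILITY = 0.01  # pA/mM
NOISE_SD = 5.0  # pA


@dataclass
class DesignCell:
    """One cell of a factorial design: genotype x condition x protocol."""

    label: str
    genotype: str
    blockers: dict
    protocol: VoltageProtocol
    k_in: float = 100.0
    k_out: float = 100.0
    group: str = ""
    n_channels: int = N_CHANNELS
    permeability: float = PERMEABILITY
    noise_sd: float = NOISE_SD
    blocker_specs: tuple | None = None  # explicit specs override presets
    ms_blocks_exit: bool = True
    extra_meta: dict = field(default_factory=dict)

    def condition(self) -> SolutionCondition:
        return SolutionCondition(self.k_in, self.k_out, self.blockers)

    def model(self) -> StateModel:
        if self.blocker_specs is not None:
            specs = self.blocker_specs
        else:
            specs = tuple(
                blocker_preset(bid, self.genotype) for bid in sorted(self.blockers)
            )
        return StateModel(specs, ms_blocks_exit=self.ms_blocks_exit)


def dose_response_design(
    genotype: str = "WT",
    blocker: str = "Mg",
    doses: Sequence[float] = (0.0, 1e-5, 3e-5, 1e-4, 3e-4, 3e-3),
    k_in: float = 100.0,
    k_out: float = 100.0,
    test_levels: Sequence[float] = tuple(range(-150, 101, 10)),
    noise_sd: float = NOISE_SD,
    sample_interval: float = 0.1,
    test_ms: float = 150.0,
) -> list[DesignCell]:
    """Step-family dose series (one sweep per dose x test level).

    The default six Mg2+ doses (control plus 10 uM - 3 mM) with 26 test levels
    give 156 sweeps, the full-figure design for one K+ condition.
    """
    protocols = make_protocol(
        "step-family",
        test_levels=tuple(test_levels),
        sample_interval=sample_interval,
        test_ms=test_ms,
    )
    cells = []
    for dose in doses:
        for prot in protocols:
            cells.append(
                DesignCell(
                    label=f"{genotype}_{blocker}{dose:g}_{prot.name}",
                    genotype=genotype,
                    blockers={blocker: dose},
                    protocol=prot,
                    k_in=k_in,
                    k_out=k_out,
                    group=f"{blocker}:{dose:g}",
                    noise_sd=noise_sd,
                )
            )
    return cells


def woodhull_tail_design(
    genotypes: Sequence[str] = ("WT", "E224G", "M183W", "E224G/M183W"),
    blocker: str = "Mg",
    conc: float = 1e-4,
    tail_levels: Sequence[float] = tuple(range(-100, -19, 10)),
    depol_ms: float = 50.0,
    test_ms: float = 20.0,
    sample_interval: float = 0.005,
    noise_sd: float = 0.0,
    include_control: bool = True,
) -> list[DesignCell]:
    """Two-pulse tails at several negative test voltages per genotype.

    Supplies the inputs of the Woodhull off-rate analysis: the tail at each
    negative voltage plus (by default) a blocker-free control used to convert
    tail relaxation rates into unblocking rates.
    """
    cells = []
    for geno in genotypes:
        doses = ([0.0] if include_control else []) + [conc]
        for dose in doses:
            for vtest in tail_levels:
                prot = make_protocol(
                    "two-pulse",
                    depol_ms=depol_ms,
                    test_mv=vtest,
                    test_ms=test_ms,
                    sample_interval=sample_interval,
                )
                cells.append(
                    DesignCell(
                        label=f"{geno}_{blocker}{dose:g}_{prot.name}",
                        genotype=geno,
                        blockers={blocker: dose},
                        protocol=prot,
                        group=f"{blocker}:{dose:g}",
                        noise_sd=noise_sd,
                    )
                )
    return cells


def variable_depol_design(
    genotype: str = "E224G",
    blocker: str = "Mg",
    conc: float = 1e-4,
    depol_lengths: Sequence[float] = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0),
    depol_mv: float = 100.0,
    tail_mv: float = -100.0,
    test_ms: float = 30.0,
    sample_interval: float = 0.01,
    noise_sd: float = 0.0,
    include_control: bool = True,
) -> list[DesignCell]:
    """Two-pulse protocol with variable depolarization length.

    The growth of the tail amplitude with the +100 mV pulse length measures
    the blocking course at +100 mV (tau_on,1); the decay of the outward
    current during the longest pulse gives tau_on,2.
    """
    cells = []
    doses = ([0.0] if include_control else []) + [conc]
    for dose in doses:
        for length in depol_lengths:
            prot = make_protocol(
                "two-pulse",
                depol_mv=depol_mv,
                depol_ms=length,
                test_mv=tail_mv,
                test_ms=test_ms,
                sample_interval=sample_interval,
            )
            cells.append(
                DesignCell(
                    label=f"{genotype}_{blocker}{dose:g}_depol{length:g}ms",
                    genotype=genotype,
                    blockers={blocker: dose},
                    protocol=prot,
                    group=f"{blocker}:{dose:g}",
                    noise_sd=noise_sd,
                    extra_meta={"depol_ms": length},
                )
            )
    return cells


def onset_rate_design(
    genotype: str = "E224G",
    blocker: str = "Mg",
    doses: Sequence[float] = (1e-5, 3e-5, 1e-4, 3e-4),
    depol_levels: Sequence[float] = (70.0, 80.0, 90.0, 100.0, 110.0),
    test_ms: float = 150.0,
    sample_interval: float = 0.05,
    noise_sd: float = 0.0,
) -> list[DesignCell]:
    """Outward-current decays for the 1/tau-vs-concentration regressions."""
    return dose_response_design(
        genotype=genotype,
        blocker=blocker,
        doses=tuple(doses),
        test_levels=tuple(depol_levels),
        noise_sd=noise_sd,
        sample_interval=sample_interval,
        test_ms=test_ms,
    )


def synergy_design(
    mg_conc: float = 1e-7,
    spm_conc: float = 1e-8,
    voltages: Sequence[float] = tuple(range(20, 101, 20)),
    k_in: float = 100.0,
    k_out: float = 100.0,
    genotype: str = "WT",
    test_ms: float = 150.0,
    sample_interval: float = 0.1,
    noise_sd: float = NOISE_SD,
    ms_blocks_exit: bool = True,
) -> list[DesignCell]:
    """Four-group two-blocker design: control, Mg alone, SPM alone, both.

    Defaults are the low-concentration kinetics condition (0.1 uM Mg2+ with
    0.01 uM SPM); pass ``mg_conc=1e-3, spm_conc=1e-5`` for the steady-state
    block comparison at the physiological concentrations.
    """
    groups = {
        "control": {"Mg": 0.0, "SPM": 0.0},
        "A": {"Mg": mg_conc, "SPM": 0.0},
        "B": {"Mg": 0.0, "SPM": spm_conc},
        "AB": {"Mg": mg_conc, "SPM": spm_conc},
    }
    protocols = make_protocol(
        "step-family",
        test_levels=tuple(voltages),
        test_ms=test_ms,
        sample_interval=sample_interval,
    )
    cells = []
    for group, blockers in groups.items():
        for prot in protocols:
            cells.append(
                DesignCell(
                    label=f"{genotype}_{group}_{prot.name}",
                    genotype=genotype,
                    blockers=dict(blockers),
                    protocol=prot,
                    k_in=k_in,
                    k_out=k_out,
                    group=group,
                    noise_sd=noise_sd,
                    ms_blocks_exit=ms_blocks_exit,
                )
            )
    return cells
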