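"""Double-mutant cycle analysis and two-blocker synergy metrics.

The coupling coefficient of a mutant cycle compares the Kd fold-changes of two
single mutants with that of their double mutant:

    Omega = [(Kd_A/Kd_WT) * (Kd_B/Kd_WT)] / (Kd_AB/Kd_WT)

Omega ~ 1 means energetically independent (additive) mutations; Omega < 1 a
negative cooperative effect.

For two blockers applied together, two standard steady-state null models
bracket "no synergy":

* independent sites:      f_pred = f_A * f_B
* competition (mutually
  exclusive binding):     f_pred = 1 / (1 + [A]/Kd_A + [B]/Kd_B)

The steady-state synergy flag is set only when the measured two-blocker
relative current falls below both nulls.  Kinetically, the macroscopic binding
rates are compared: the onset rate of block with both blockers should be the
sum of the single-blocker binding rates when the blockers enter the pore
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DesignError
from .relaxation import fit_relaxation, relative_current, steady_state_current
from .simulate import Experiment

__all__ = [
    "CycleResult",
    "coupling_coefficient",
    "cycle_scan",
    "SynergyResult",
    "synergy_steady_state",
    "synergy_kinetics",
]


@dataclass(frozen=True)
class CycleResult:
    """Double-mutant cycle at one voltage."""

    pair: tuple
    v: float
    kd_wt: float
    kd_a: float
    kd_b: float
    kd_ab: float
    omega: float
    verdict: str  # "additive", "negative-cooperative", "positive-cooperative"


def coupling_coefficient(
    kd_wt: float,
    kd_a: float,
    kd_b: float,
    kd_ab: float,
    pair: tuple = ("A", "B"),
    v: float = np.nan,
    additive_band: tuple = (0.5, 2.0),
) -> CycleResult:
    """Coupling coefficient Omega of a double-mutant cycle.

    ``additive_band`` is the (configurable) Omega interval called additive.
    """
    for name, kd in (("kd_wt", kd_wt), ("kd_a", kd_a), ("kd_b", kd_b), ("kd_ab", kd_ab)):
        if not kd > 0:
            raise ValueError(f"{name} must be positive, got {kd}")
    omega = (kd_a / kd_wt) * (kd_b / kd_wt) / (kd_ab / kd_wt)
    lo, hi = additive_band
    if omega < lo:
        verdict = "negative-cooperative"
    elif omega > hi:
        verdict = "positive-cooperative"
    else:
        verdict = "additive"
    return CycleResult(
        pair=tuple(pair),
        v=v,
        kd_wt=kd_wt,
        kd_a=kd_a,
        kd_b=kd_b,
        kd_ab=kd_ab,
        omega=float(omega),
        verdict=verdict,
    )


def cycle_scan(
    kd_table: Mapping[str, float],
    pairs: Sequence[tuple],
    v: float = np.nan,
    wt: str = "WT",
    double_name=None,
) -> tuple[list, list]:
    """Coupling coefficients for a list of mutation pairs.

    ``kd_table`` maps genotype name -> Kd (M) at the analysis voltage.  The
    double mutant of pair (A, B) is looked up as ``"A/B"`` (or via
    ``double_name(a, b)``).  Returns (results sorted by Omega, skipped pairs
    with reasons).
    """
    if double_name is None:
        double_name = lambda a, b: f"{a}/{b}"  # noqa: E731
    results, skipped = [], []
    for a, b in pairs:
        names = {"wt": wt, "a": a, "b": b, "ab": double_name(a, b)}
        missing = [n for n in names.values() if n not in kd_table]
        if missing:
            skipped.append(((a, b), f"missing Kd for {missing}"))
            continue
        results.append(
            coupling_coefficient(
                kd_table[wt],
                kd_table[a],
                kd_table[b],
                kd_table[names["ab"]],
                pair=(a, b),
                v=v,
            )
        )
    results.sort(key=lambda r: r.omega)
    return results, skipped


@dataclass
class SynergyResult:
    """Steady-state and/or kinetic two-blocker comparison at one voltage."""

    v: float
    f_a: float = np.nan
    f_b: float = np.nan
    f_both: float = np.nan
    f_pred_independent: float = np.nan
    f_pred_competition: float = np.nan
    rate_a: float = np.nan  # fitted relaxation rates 1/tau, s^-1
    rate_b: float = np.nan
    rate_both: float = np.nan
    binding_rate_a: float = np.nan  # macroscopic binding rates (1/tau)*(1-f)
    binding_rate_b: float = np.nan
    binding_rate_both: float = np.nan
    rate_pred_additive: float = np.nan
    flags: dict = field(default_factory=dict)


def _group_sweeps(exp: Experiment, v: float, segment: int) -> dict:
    groups: dict = {}
    for sw in exp.sweeps:
        if sw.segment_level(segment) == v:
            groups.setdefault(sw.meta.get("group", ""), []).append(sw)
    missing = {"control", "A", "B", "AB"} - set(groups)
    if missing:
        raise DesignError(
            f"synergy design needs groups control/A/B/AB at {v} mV; missing "
            f"{sorted(missing)}"
        )
    return groups


def synergy_steady_state(
    exp: Experiment, v: float, segment: int = 2, margin: float = 0.0
) -> SynergyResult:
    """Steady-state synergy at one voltage from a four-group design.

    Sets ``flags['steady_state_synergy']`` when the measured two-blocker
    relative current is below both the independent-sites product f_A*f_B and
    the competition null 1/(1 + [A]/Kd_A + [B]/Kd_B), each by more than
    ``margin`` (absolute on f).
    """
    groups = _group_sweeps(exp, v, segment)
    ctrl = groups["control"][0]
    f = {}
    for g in ("A", "B", "AB"):
        f[g] = relative_current(groups[g][0], ctrl, segment).f
    pred_ind = f["A"] * f["B"]
    # single-blocker Kds implied by the one-to-one binding law: Kd = c*f/(1-f)
    terms = 0.0
    for g in ("A", "B"):
        conc = sum(groups[g][0].meta.get("blockers", {}).values())
        fx = min(max(f[g], 1e-12), 1 - 1e-12)
        if conc > 0:
            terms += conc / (conc * fx / (1 - fx))
    pred_comp = 1.0 / (1.0 + terms)
    synergy = f["AB"] < min(pred_ind, pred_comp) - margin
    return SynergyResult(
        v=v,
        f_a=f["A"],
        f_b=f["B"],
        f_both=f["AB"],
        f_pred_independent=pred_ind,
        f_pred_competition=pred_comp,
        flags={"steady_state_synergy": bool(synergy)},
    )


def synergy_kinetics(
    exp: Experiment,
    v: float,
    segment: int = 2,
    blank_ms: float = 1.0,
    additive_rtol: float = 0.2,
) -> SynergyResult:
    """Kinetic additivity of block onset at one voltage.

    Fits the outward-current decay of each group (1 vs 2 exponentials by
    BIC); the raw relaxation rates 1/tau are reported, but the additivity flag
    compares macroscopic binding rates estimated from the initial slope of the
    normalized decay,

        a_x = sum_i(amplitude_i / tau_i) / I_control,

    which equals k_on*[B] exactly for a two-state scheme (the fitted 1/tau
    also contains the unbinding rate, which must not be double-counted when
    summing rates).  ``flags['kinetic_additivity']`` is set when the
    two-blocker binding rate is within ``additive_rtol`` of the sum of the
    single-blocker binding rates.
    """
    groups = _group_sweeps(exp, v, segment)
    ctrl = groups["control"][0]
    i_ctrl = steady_state_current(ctrl, segment)
    if i_ctrl == 0:
        raise DesignError("control current is zero; cannot normalize onset rates")
    rates, binding = {}, {}
    for g in ("A", "B", "AB"):
        sw = groups[g][0]
        conc = sum(sw.meta.get("blockers", {}).values())
        if conc == 0:
            rates[g] = 0.0
            binding[g] = 0.0
            continue
        fit = fit_relaxation(sw, segment, n_components="auto", blank_ms=blank_ms)
        rates[g] = 1e3 / fit.tau
        binding[g] = abs(
            1e3 * sum(a / tau for a, tau in zip(fit.amplitudes, fit.taus)) / i_ctrl
        )
    pred = binding["A"] + binding["B"]
    additive = (
        abs(binding["AB"] - pred) / pred < additive_rtol if pred > 0 else False
    )
    f = {
        g: relative_current(groups[g][0], ctrl, segment).f for g in ("A", "B", "AB")
    }
    return SynergyResult(
        v=v,
        f_a=f["A"],
        f_b=f["B"],
        f_both=f["AB"],
        rate_a=rates["A"],
        rate_b=rates["B"],
        rate_both=rates["AB"],
        binding_rate_a=binding["A"],
        binding_rate_b=binding["B"],
        binding_rate_both=binding["AB"],
        rate_pred_additive=pred,
        flags={"kinetic_additivity": bool(additive)},
    )
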