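"""Hill dose-response fits, Kd-voltage curves, IR index and Kd-V shift.

The block is treated as a one-to-one binding reaction, so the relative
current at blocker concentration [B] is f = 1/(1 + [B]/Kd) and a single
parameter (Kd, fitted in log space) describes each voltage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .errors import DesignError, UnidentifiableError, UndefinedRatioError
from .relaxation import RelativeCurrent, relative_current
from .simulate import Experiment

__all__ = [
    "hill_relative_current",
    "HillFit",
    "fit_hill",
    "KdVoltageCurve",
    "kd_curve",
    "ir_index",
    "kd_shift",
]


def hill_relative_current(conc, kd):
    """Relative current f = 1/(1 + conc/Kd) for one-to-one binding."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    if np.any(np.asarray(kd) <= 0):
        raise ValueError("Kd must be positive")
    f = 1.0 / (1.0 + conc / kd)
    return f if f.ndim else float(f)


@dataclass(frozen=True)
class HillFit:
    """One-voltage Hill fit: Kd (M) with its Jacobian-based standard error."""

    v: float
    kd: float
    stderr: float
    n_points: int


def fit_hill(points: Sequence, hill_coefficient: float = 1.0) -> HillFit:
    """Least-squares Kd from (conc, f) points at one voltage.

    ``points`` are :class:`RelativeCurrent` records or (conc, f) pairs.  The
    fit is on log Kd with unweighted residuals on f.  ``hill_coefficient`` is
    an off-pipeline utility (fixed, not fitted); the pipeline always uses 1.
    """
    recs = [
        p if isinstance(p, RelativeCurrent) else RelativeCurrent(np.nan, p[0], p[1])
        for p in points
    ]
    conc = np.array([r.conc for r in recs], dtype=float)
    f = np.array([r.f for r in recs], dtype=float)
    keep = conc > 0
    conc, f = conc[keep], f[keep]
    if conc.size < 3:
        raise ValueError(f"need >= 3 non-zero concentrations, have {conc.size}")
    if np.all(f > 0.95) or np.all(f < 0.05):
        raise UnidentifiableError(
            "relative currents carry no Kd information (all ~1 or all ~0)"
        )
    if not (f.min() < 0.5 < f.max()):
        warnings.warn(
            "dose series does not span f = 0.5; Kd is weakly constrained",
            stacklevel=2,
        )
    nh = float(hill_coefficient)

    def resid(log_kd):
        return 1.0 / (1.0 + (conc / np.exp(log_kd[0])) ** nh) - f

    # Start from the interpolated half-block concentration
    f_clip = np.clip(f, 1e-6, 1 - 1e-6)
    kd0 = np.median(conc * (f_clip / (1 - f_clip)) ** (1.0 / nh))
    res = least_squares(
        resid, x0=[np.log(kd0)], xtol=1e-15, ftol=1e-15, gtol=1e-15, method="lm"
    )
    log_kd = res.x[0]
    # standard error of Kd from the Jacobian: var(logKd) = s^2 * (J^T J)^-1
    dof = max(conc.size - 1, 1)
    s2 = float(np.sum(res.fun**2)) / dof
    jtj = float(np.sum(res.jac**2))
    var_log = s2 / jtj if jtj > 0 else np.inf
    kd = float(np.exp(log_kd))
    v = recs[0].v if recs else np.nan
    return HillFit(v=v, kd=kd, stderr=kd * float(np.sqrt(var_log)), n_points=conc.size)


@dataclass
class KdVoltageCurve:
    """Ordered Kd(V) table for one condition/genotype, with skip reasons."""

    entries: dict  # V -> HillFit, voltages strictly increasing
    genotype: str = ""
    k_in: float = np.nan
    k_out: float = np.nan
    skipped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vs = list(self.entries)
        if any(b <= a for a, b in zip(vs, vs[1:])):
            self.entries = dict(sorted(self.entries.items()))

    @property
    def voltages(self) -> np.ndarray:
        return np.array(list(self.entries), dtype=float)

    @property
    def kds(self) -> np.ndarray:
        return np.array([h.kd for h in self.entries.values()], dtype=float)

    def log_kd_at(self, v: float) -> float:
        """log Kd at voltage v, log-linearly interpolated."""
        vs, kds = self.voltages, self.kds
        if not (vs.min() - 1e-9 <= v <= vs.max() + 1e-9):
            raise ValueError(f"voltage {v} mV outside curve range [{vs.min()}, {vs.max()}]")
        return float(np.interp(v, vs, np.log(kds)))


def kd_curve(
    exp: Experiment,
    genotype: str | None = None,
    segment: int = 2,
    v_min: float | None = -60.0,
    v_max: float | None = 60.0,
) -> KdVoltageCurve:
    """Hill fit per test voltage from a dose-response experiment.

    The experiment must contain, at each analysed voltage, a blocker-free
    control sweep and >= 3 non-zero doses.  Voltages outside [v_min, v_max]
    (the identifiable window near/above E_K) are excluded and reported in
    ``skipped``, as are voltages where the fit fails.
    """
    sweeps = exp.select(genotype=genotype) if genotype else list(exp.sweeps)
    if not sweeps:
        raise DesignError(f"no sweeps for genotype {genotype!r}")
    by_v: dict = {}
    for sw in sweeps:
        by_v.setdefault(sw.segment_level(segment), []).append(sw)
    entries, skipped = {}, {}
    for v in sorted(by_v):
        if v_min is not None and v < v_min:
            skipped[v] = f"below analysis window ({v_min} mV)"
            continue
        if v_max is not None and v > v_max:
            skipped[v] = f"above analysis window ({v_max} mV)"
            continue
        group = by_v[v]
        controls = [
            s for s in group if sum(s.meta.get("blockers", {}).values()) == 0
        ]
        doses = [s for s in group if sum(s.meta.get("blockers", {}).values()) > 0]
        if not controls:
            skipped[v] = "no control sweep"
            continue
        try:
            points = [
                relative_current(s, controls[0], segment) for s in doses
            ]
            entries[v] = fit_hill(points)
        except (UnidentifiableError, UndefinedRatioError, ValueError) as err:
            skipped[v] = str(err)
    meta = sweeps[0].meta
    return KdVoltageCurve(
        entries=entries,
        genotype=genotype or meta.get("genotype", ""),
        k_in=meta.get("k_in", np.nan),
        k_out=meta.get("k_out", np.nan),
        skipped=skipped,
    )


def ir_index(curve: KdVoltageCurve) -> float:
    """Inward-rectification index Kd(-30 mV) / Kd(+30 mV).

    If +-30 mV are not tabulated, log Kd is interpolated between neighbours
    (with a warning).
    """
    out = []
    for v in (-30.0, 30.0):
        if v in curve.entries:
            out.append(np.log(curve.entries[v].kd))
        else:
            warnings.warn(
                f"{v:+g} mV not in curve; interpolating log Kd", stacklevel=2
            )
            out.append(curve.log_kd_at(v))
    return float(np.exp(out[0] - out[1]))


def kd_shift(
    curve_a: KdVoltageCurve,
    curve_b: KdVoltageCurve,
    bracket: tuple = (-60.0, 60.0),
    grid_mv: float = 0.05,
) -> float:
    """Voltage shift Delta (mV) minimizing sum[(logKd_a(V) - logKd_b(V-Delta))^2].

    Delta is the displacement of curve_a relative to curve_b along the voltage
    axis: if curve_a equals curve_b displaced by -20 mV (toward negative
    voltages), the result is -20.  Evaluated on the overlapping support at
    each candidate shift; coarse grid search then bounded local refinement.
    """
    va, la = curve_a.voltages, np.log(curve_a.kds)
    vb, lb = curve_b.voltages, np.log(curve_b.kds)
    if va.size < 2 or vb.size < 2:
        raise ValueError("both curves need >= 2 voltages")

    def sse(delta: float) -> float:
        lo = max(va.min(), vb.min() + delta)
        hi = min(va.max(), vb.max() + delta)
        if hi - lo < 1e-9:
            return np.inf
        grid = np.linspace(lo, hi, 101)
        fa = np.interp(grid, va, la)
        fb = np.interp(grid - delta, vb, lb)
        return float(np.mean((fa - fb) ** 2))

    deltas = np.arange(bracket[0], bracket[1] + grid_mv / 2, grid_mv)
    scores = np.array([sse(d) for d in deltas])
    if not np.any(np.isfinite(scores)):
        raise ValueError("curves have no overlapping voltage support")
    i = int(np.argmin(scores))
    lo = deltas[max(i - 1, 0)]
    hi = deltas[min(i + 1, deltas.size - 1)]
    if lo == hi:
        return float(deltas[i])
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x) if res.fun <= scores[i] else float(deltas[i])
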