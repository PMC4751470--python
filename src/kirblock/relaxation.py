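"""Steady-state currents, relative currents and exponential relaxation fits.

The observables extracted here are the raw material of every downstream
analysis: steady-state block (-> Hill fits), decay of outward currents during
a depolarizing step (-> blocking kinetics) and the slowly developing inward
tail on repolarization (-> unblocking kinetics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DesignError, FitFailureError, UndefinedRatioError
from .simulate import Experiment, Sweep

__all__ = [
    "ExpFit",
    "RelativeCurrent",
    "steady_state_current",
    "relative_current",
    "fit_relaxation",
    "tail_kinetics",
    "unblock_rates",
]


@dataclass(frozen=True)
class ExpFit:
    """Multi-exponential relaxation fit I(t) = baseline + sum a_i exp(-t/tau_i).

    ``taus`` are in ms, sorted ascending; ``window`` is the fitted (t0, t1) in
    sweep time (ms).
    """

    n_components: int
    taus: tuple
    amplitudes: tuple
    baseline: float
    rss: float
    window: tuple
    bic: float = float("nan")

    @property
    def tau(self) -> float:
        """Dominant (largest-|amplitude|) time constant, ms."""
        i = int(np.argmax(np.abs(self.amplitudes)))
        return self.taus[i]

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.baseline)
        for a, tau in zip(self.amplitudes, self.taus):
            out = out + a * np.exp(-(t - self.window[0]) / tau)
        return out


@dataclass(frozen=True)
class RelativeCurrent:
    """Steady-state current in blocker relative to control at one voltage."""

    v: float
    conc: float
    f: float


def steady_state_current(
    sweep: Sweep, segment: int, tail_fraction: float = 0.1
) -> float:
    """Mean current over the final ``tail_fraction`` of a segment (pA).

    Warns when the segment does not look stationary over its final fifth
    (mean drift beyond three standard errors of the window mean).
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    sl = sweep.segment_slice(segment)
    seg = sweep.current[sl]
    n = max(1, int(round(seg.size * tail_fraction)))
    window = seg[-n:]
    value = float(window.mean())
    if n >= 8 and seg.size >= 2 * n:
        prev = seg[-2 * n : -n]
        se = window.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        drift = abs(prev.mean() - value)
        material = 1e-4 * max(abs(value), 1.0)  # ignore numerically tiny drifts
        if drift > 3 * se + material:
            warnings.warn(
                f"segment {segment} may not have reached steady state "
                f"(drift {prev.mean() - value:.3g} pA vs SE {se:.3g} pA)",
                stacklevel=2,
            )
    return value


def relative_current(
    test: Sweep, control: Sweep, segment: int, tail_fraction: float = 0.1
) -> RelativeCurrent:
    """Ratio of steady-state currents, test / control, at one voltage."""
    if test.protocol.segments != control.protocol.segments:
        raise DesignError("test and control sweeps have different protocols")
    i_test = steady_state_current(test, segment, tail_fraction)
    i_ctrl = steady_state_current(control, segment, tail_fraction)
    noise = max(
        float(test.meta.get("noise_sd", 0.0)), float(control.meta.get("noise_sd", 0.0))
    )
    if abs(i_ctrl) < 5 * noise or i_ctrl == 0:
        raise UndefinedRatioError(
            f"control current {i_ctrl:.3g} pA is indistinguishable from zero "
            f"(noise sd {noise:.3g} pA)"
        )
    v = test.segment_level(segment)
    conc = sum(test.meta.get("blockers", {}).values())
    return RelativeCurrent(v=v, conc=conc, f=i_test / i_ctrl)


def _exp_model(params: np.ndarray, t: np.ndarray, k: int) -> np.ndarray:
    baseline = params[0]
    out = np.full_like(t, baseline)
    for j in range(k):
        a, log_tau = params[1 + 2 * j], params[2 + 2 * j]
        out = out + a * np.exp(-t / np.exp(log_tau))
    return out


def _fit_k_components(t, y, k: int):
    """Deterministic multistart NLS for a k-exponential decay."""
    span = t[-1] if t[-1] > 0 else 1.0
    dt = t[1] - t[0] if t.size > 1 else span
    lo, hi = max(5 * dt, 1e-6), max(span / 2, 10 * dt)
    grid = np.geomspace(lo, hi, 4)
    starts = []
    amp0 = y[0] - y[-1]
    base0 = y[-1]
    if k == 1:
        for tau in grid:
            starts.append([base0, amp0, np.log(tau)])
    else:
        for i in range(len(grid)):
            for j in range(i + 1, len(grid)):
                starts.append(
                    [base0, amp0 * 0.5, np.log(grid[i]), amp0 * 0.5, np.log(grid[j])]
                )
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                lambda p: _exp_model(p, t, k) - y,
                x0=np.asarray(x0, dtype=float),
                method="lm" if t.size > len(x0) else "trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=4000,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if res.x[1::2].size and not np.all(np.isfinite(res.x)):
            continue
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        raise FitFailureError(
            f"{k}-exponential fit failed to converge from all "
            f"{len(starts)} starts"
        )
    return best


def fit_relaxation(
    sweep: Sweep,
    segment: int,
    n_components="auto",
    blank_ms: float = 1.0,
    window_ms: float | None = None,
) -> ExpFit:
    """Fit 1 or 2 decaying exponentials to one protocol segment.

    ``blank_ms`` skips the settling instant at the segment start; with
    ``n_components='auto'`` the 1- vs 2-component choice is by BIC.
    ``window_ms`` optionally truncates the fitted window (from segment start).
    """
    sl = sweep.segment_slice(segment)
    t_abs = sweep.time[sl]
    y_all = sweep.current[sl]
    t0 = t_abs[0]
    t_rel = t_abs - t0
    mask = t_rel >= blank_ms - 1e-12
    if window_ms is not None:
        mask &= t_rel <= window_ms + 1e-12
    t = t_rel[mask] - (t_rel[mask][0] if mask.any() else 0.0)
    y = y_all[mask]
    if t.size < 20:
        raise ValueError(
            f"need >= 20 samples in the fit window, have {t.size}; "
            "reduce blank_ms or sample faster"
        )
    window = (t0 + t_rel[mask][0], t0 + t_rel[mask][-1])

    def make_fit(k: int) -> ExpFit:
        rss, x = _fit_k_components(t, y, k)
        n = t.size
        n_par = 1 + 2 * k
        bic = n * np.log(max(rss, 1e-300) / n) + n_par * np.log(n)
        taus = tuple(np.exp(x[2::2]))
        amps = tuple(x[1::2])
        order = np.argsort(taus)
        return ExpFit(
            n_components=k,
            taus=tuple(float(taus[i]) for i in order),
            amplitudes=tuple(float(amps[i]) for i in order),
            baseline=float(x[0]),
            rss=rss,
            window=window,
            bic=float(bic),
        )

    if n_components in (1, 2):
        return make_fit(int(n_components))
    if n_components != "auto":
        raise ValueError("n_components must be 1, 2 or 'auto'")
    fit1 = make_fit(1)
    try:
        fit2 = make_fit(2)
    except FitFailureError:
        return fit1
    return fit2 if fit2.bic < fit1.bic else fit1


def _tail_amplitude(fit: ExpFit) -> float:
    """Magnitude of the relaxing component, extrapolated to segment start."""
    return float(np.sum(np.abs(fit.amplitudes)))


def tail_kinetics(
    exp: Experiment,
    genotype: str,
    depol_segment: int = 2,
    tail_segment: int = 3,
    blank_ms: float = 0.05,
) -> dict:
    """Blocking/unblocking kinetics from a variable-depolarization design.

    Returns a dict with

    * ``table``: DataFrame (depol_ms, tail_amplitude, tau_off) per pulse length
    * ``tau_on_1``: time constant (ms) of tail-amplitude growth vs pulse length
    * ``tau_on_2``: decay time constant (ms) of the outward current during the
      longest depolarizing pulse
    * ``tau_off``: mean tail decay time constant (ms)

    Requires >= 3 depolarization lengths.
    """
    sweeps = [
        sw
        for sw in exp.select(genotype=genotype)
        if sum(sw.meta.get("blockers", {}).values()) > 0 and "depol_ms" in sw.meta
    ]
    lengths = sorted({sw.meta["depol_ms"] for sw in sweeps})
    if len(lengths) < 3:
        raise DesignError(
            f"variable-depolarization analysis needs >= 3 pulse lengths, "
            f"found {len(lengths)}"
        )
    rows = []
    for sw in sorted(sweeps, key=lambda s: s.meta["depol_ms"]):
        tail_fit = fit_relaxation(sw, tail_segment, n_components=1, blank_ms=blank_ms)
        rows.append(
            {
                "depol_ms": sw.meta["depol_ms"],
                "tail_amplitude": _tail_amplitude(tail_fit),
                "tau_off": tail_fit.tau,
            }
        )
    table = pd.DataFrame(rows)

    # growth of tail amplitude with depolarization length:
    # A(L) = A_inf + (A_0 - A_inf) exp(-L/tau); A_0 > 0 allows for the small
    # resting block present before the depolarizing pulse
    L = table["depol_ms"].to_numpy()
    A = table["tail_amplitude"].to_numpy()

    def resid(p):
        a_inf, a0, log_tau = p
        return a_inf + (a0 - a_inf) * np.exp(-L / np.exp(log_tau)) - A

    best = None
    for tau0 in np.geomspace(max(L[0], 1e-3), L[-1], 5):
        res = least_squares(
            resid, x0=[A[-1], A[0], np.log(tau0)], xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        raise FitFailureError("tail-growth fit failed")
    tau_on_1 = float(np.exp(best[1][2]))

    longest = max(sweeps, key=lambda s: s.meta["depol_ms"])
    decay_fit = fit_relaxation(
        longest, depol_segment, n_components=1, blank_ms=blank_ms
    )
    return {
        "table": table,
        "tau_on_1": tau_on_1,
        "tau_on_2": decay_fit.tau,
        "tau_off": float(table["tau_off"].mean()),
    }


def unblock_rates(
    exp: Experiment,
    genotype: str,
    tail_segment: int = 3,
    blank_ms: float = 0.02,
    noise_floor: float = 0.0,
) -> pd.DataFrame:
    """Unblocking rate (s^-1) vs tail voltage for one genotype.

    For each negative-voltage tail sweep, the relaxation rate 1/tau of the
    tail is converted into the unblocking rate via the steady relative current
    against the blocker-free control at the same voltage:

        k_off(V) = (1/tau) * I_blocked(inf)/I_control(inf)

    an exact identity for a two-state blocked/open scheme (the relaxation rate
    is kon[B] + koff and the steady relative current is koff/(kon[B] + koff)).
    Without a control sweep the raw rate is reported and flagged.

    Sweeps whose tail amplitude is below ``noise_floor`` (pA) are excluded
    with a reason (e.g. blocker-free cells produce no tail).
    """
    rows = []
    for sw in exp.select(genotype=genotype):
        if sum(sw.meta.get("blockers", {}).values()) == 0:
            continue
        v = sw.segment_level(tail_segment)
        fit = fit_relaxation(sw, tail_segment, n_components=1, blank_ms=blank_ms)
        amp = _tail_amplitude(fit)
        if amp <= noise_floor:
            rows.append(
                {"v": v, "rate": np.nan, "corrected": False, "reason": "no tail"}
            )
            continue
        rate = 1e3 / fit.tau  # ms -> s^-1
        controls = [
            c
            for c in exp.select(genotype=genotype)
            if sum(c.meta.get("blockers", {}).values()) == 0
            and c.protocol.segments == sw.protocol.segments
        ]
        corrected = False
        if controls:
            try:
                rc = relative_current(sw, controls[0], tail_segment)
                rate *= rc.f
                corrected = True
            except UndefinedRatioError:
                pass
        rows.append({"v": v, "rate": rate, "corrected": corrected, "reason": ""})
    return pd.DataFrame(rows).sort_values("v", ignore_index=True)
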