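"""Continuous-time state model of a Kir2.1-like pore blocked by up to two
intracellular cations.

States (subset, depending on blockers present):

* ``O``  open, conducting
* ``M``  Mg2+-like blocker bound
* ``S``  spermine-like blocker bound
* ``MS`` both bound (Mg2+ binds behind the resident spermine or vice versa)

Transitions: ``O<->M``, ``O<->S``, ``S<->MS``, ``M<->MS``, plus punch-through
``S->O`` (the second blocker exiting outward through the selectivity filter at
strong depolarization).  By default there is no punch-through from ``MS``:
with the first blocker resident behind it, the deeper blocker cannot exit
outward -- the occlusion that makes concomitant block synergistic.  Setting
``ms_blocks_exit=False`` yields a fully independent two-site model, useful as
the no-interaction null.

Rates (V in mV, vt thermal voltage, [B] molar):

* blocking      ``kon0 * [B] * exp(Z*delta_on*V/vt)``
* unblocking    ``koff0 * exp(-zdelta_off*V/vt) * exp(-theta*max(tanh((V-EK)/vs),0))``
* punch-through ``kexit0 * exp(zdelta_exit*V/vt)``

The flux-coupling factor on the unblocking rate is rectified: a net outward
K+ flux (V > E_K) holds the blocker against the outer site and retards its
return to the cytoplasm; with inward or zero net flux the unblocking rate is
purely Woodhull.  See docs/methods.md for the rationale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .conditions import SolutionCondition
from .errors import ConfigurationError
from .params import BlockerSpec

__all__ = [
    "StateModel",
    "rate_on",
    "rate_off",
    "rate_exit",
    "build_generator",
    "steady_state",
    "apparent_kd",
    "relax_occupancy",
    "initial_block_rate",
]


def rate_on(b: BlockerSpec, V: float, cond: SolutionCondition) -> float:
    """Pseudo-first-order blocking rate kon0*[B]*exp(Z*delta_on*V/vt) (s^-1)."""
    conc = cond.concentration(b.id)
    return b.kon0 * conc * math.exp(b.valence * b.delta_on * V / cond.vt)


def rate_off(b: BlockerSpec, V: float, cond: SolutionCondition) -> float:
    """Unblocking rate to the intracellular side (s^-1), flux-coupled."""
    woodhull = b.koff0 * math.exp(-b.zdelta_off * V / cond.vt)
    drive = (V - cond.ek) / b.vs
    flux = max(math.tanh(drive), 0.0)
    return woodhull * math.exp(-b.theta * flux)


def rate_exit(b: BlockerSpec, V: float, cond: SolutionCondition) -> float:
    """Punch-through rate (outward exit through the filter, s^-1)."""
    if b.kexit0 == 0.0:
        return 0.0
    return b.kexit0 * math.exp(b.zdelta_exit * V / cond.vt)


@dataclass(frozen=True)
class StateModel:
    """Blocked/unblocked state scheme for one or two blockers.

    ``blockers`` is an ordered sequence of 1 or 2 :class:`BlockerSpec`; the
    first maps to state ``M``, the second to ``S``.  Only ``O`` conducts.
    """

    blockers: tuple[BlockerSpec, ...]
    ms_blocks_exit: bool = True

    def __init__(
        self,
        blockers: Sequence[BlockerSpec],
        ms_blocks_exit: bool = True,
    ) -> None:
        blockers = tuple(blockers)
        if not 1 <= len(blockers) <= 2:
            raise ConfigurationError("StateModel supports 1 or 2 blockers")
        if len({b.id for b in blockers}) != len(blockers):
            raise ConfigurationError("blocker ids must be distinct")
        object.__setattr__(self, "blockers", blockers)
        object.__setattr__(self, "ms_blocks_exit", bool(ms_blocks_exit))

    @property
    def states(self) -> tuple[str, ...]:
        if len(self.blockers) == 1:
            return ("O", "B")
        return ("O", "M", "S", "MS")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def conducting(self) -> np.ndarray:
        c = np.zeros(self.n_states)
        c[0] = 1.0
        return c

    def check_condition(self, cond: SolutionCondition) -> None:
        missing = [b.id for b in self.blockers if b.id not in cond.blockers]
        if missing:
            raise ConfigurationError(
                f"condition lacks concentrations for blockers {missing}"
            )


def build_generator(model: StateModel, V: float, cond: SolutionCondition) -> np.ndarray:
    """Rate matrix Q (s^-1) with Q[i, j] the i->j rate; rows sum to 0."""
    model.check_condition(cond)
    n = model.n_states
    Q = np.zeros((n, n))
    if n == 2:
        (b,) = model.blockers
        Q[0, 1] = rate_on(b, V, cond)
        Q[1, 0] = rate_off(b, V, cond) + rate_exit(b, V, cond)
    else:
        bm, bs = model.blockers
        on_m, off_m = rate_on(bm, V, cond), rate_off(bm, V, cond)
        on_s, off_s = rate_on(bs, V, cond), rate_off(bs, V, cond)
        ex_m, ex_s = rate_exit(bm, V, cond), rate_exit(bs, V, cond)
        O, M, S, MS = 0, 1, 2, 3
        Q[O, M] = on_m
        Q[M, O] = off_m + ex_m
        Q[O, S] = on_s
        Q[S, O] = off_s + ex_s
        Q[S, MS] = on_m
        Q[MS, S] = off_m
        Q[M, MS] = on_s
        # exit of the deeper blocker is occluded while the other is resident
        Q[MS, M] = off_s if model.ms_blocks_exit else off_s + ex_s
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def steady_state(model: StateModel, V: float, cond: SolutionCondition) -> np.ndarray:
    """Stationary occupancy vector (sums to 1).

    Solves p^T Q = 0 with the normalization constraint appended.  Raises
    ``ConfigurationError`` if the stationary distribution is not unique
    (reducible chain).
    """
    Q = build_generator(model, V, cond)
    n = Q.shape[0]
    scale = max(1.0, float(np.abs(Q).max()))
    A = np.vstack([Q.T / scale, np.ones((1, n))])
    rhs = np.zeros(n + 1)
    rhs[-1] = 1.0
    if np.linalg.matrix_rank(A, tol=1e-12) < n:
        raise ConfigurationError(
            "stationary distribution is not unique (reducible state chain)"
        )
    p, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    if np.max(np.abs(A @ p - rhs)) > 1e-8:
        raise ConfigurationError("failed to solve for the stationary distribution")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def apparent_kd(model: StateModel, V: float, cond: SolutionCondition) -> float:
    """Blocker concentration at which steady-state open probability is 0.5 (M).

    Defined per blocker, so only single-blocker models are supported.  For the
    schemes here the closed form is

        Kd(V) = (rate_off(V) + rate_exit(V)) / (kon0 * exp(Z*delta_on*V/vt)).

    ``cond`` supplies the K+ conditions (hence E_K); its blocker concentration
    entry is ignored.
    """
    if len(model.blockers) != 1:
        raise ConfigurationError(
            "apparent Kd is defined per blocker; use a single-blocker model"
        )
    (b,) = model.blockers
    cond1 = cond.with_blocker(b.id, 0.0)
    kon_c = b.kon0 * math.exp(b.valence * b.delta_on * V / cond.vt)
    kd = (rate_off(b, V, cond1) + rate_exit(b, V, cond1)) / kon_c
    return kd


def relax_occupancy(
    model: StateModel,
    V: float,
    cond: SolutionCondition,
    p0: Sequence[float],
    t_grid,
) -> np.ndarray:
    """Occupancy time course p(t) solving dp/dt = p Q, shape (len(t), n).

    ``t_grid`` is in seconds.  Solved by eigendecomposition of the generator,
    with a matrix-exponential fallback for (near-)defective cases.
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (model.n_states,):
        raise ValueError(
            f"p0 must have length {model.n_states}, got shape {p0.shape}"
        )
    if not math.isclose(p0.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"p0 must sum to 1 (got {p0.sum()!r})")
    if np.any(p0 < -1e-12):
        raise ValueError("p0 must be non-negative")
    t = np.asarray(t_grid, dtype=float)
    Q = build_generator(model, V, cond)
    out = _propagate(Q, p0, t)
    # guard tiny eigen-solver noise; occupancies are probabilities
    out = np.clip(out, 0.0, 1.0)
    return out / out.sum(axis=1, keepdims=True)


def _propagate(Q: np.ndarray, p0: np.ndarray, t: np.ndarray) -> np.ndarray:
    n = Q.shape[0]
    try:
        w, U = np.linalg.eig(Q.T)
        Uinv = np.linalg.inv(U)
        cond_num = np.linalg.cond(U)
    except np.linalg.LinAlgError:
        cond_num = np.inf
    if np.isfinite(cond_num) and cond_num < 1e10:
        c = Uinv @ p0  # coordinates of p0 in the eigenbasis of Q^T
        # exp(w t) with w possibly complex; result is real up to round-off
        phases = np.exp(np.outer(t, w))
        out = np.real(phases * c @ U.T)
        return out
    # defective generator: fall back to expm on unique time points
    out = np.empty((t.size, n))
    order = np.argsort(t)
    ts = t[order]
    p = p0.copy()
    t_prev = 0.0
    for k, tk in enumerate(ts):
        if tk != t_prev:
            p = p0 @ scipy.linalg.expm(Q * tk)
            t_prev = tk
        out[order[k]] = p if tk != 0 else p0
    return out


def initial_block_rate(model: StateModel, V: float, cond: SolutionCondition) -> float:
    """-dP_O/dt at t=0 starting from the fully open state (s^-1).

    Equals the total macroscopic binding rate, sum of kon_i*[B_i]; exactly
    additive over blockers for any interaction scheme, since interactions only
    involve already-blocked states.
    """
    Q = build_generator(model, V, cond)
    return float(-Q[0, 0])
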