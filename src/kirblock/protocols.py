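"""Voltage-clamp protocol descriptions and the standard presets.

Two protocol families are shipped:

* ``step-family`` -- hold at 0 mV, a -100 mV pre-pulse (20 ms), then one test
  pulse per level from -150 to +100 mV in 10 mV increments (150 ms).  Used for
  dose-response/steady-state analyses.
* ``two-pulse`` -- hold at 0 mV, step to -100 mV (20 ms), depolarize to
  +100 mV for a variable length, then a negative test pulse.  The slowly
  developing inward "tail" on the final pulse reports blocker unbinding; its
  growth with the depolarization length reports the blocking course.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .errors import ConfigurationError

__all__ = ["VoltageProtocol", "make_protocol"]


@dataclass(frozen=True)
class VoltageProtocol:
    """Ordered (level mV, duration ms) segments plus the sample interval (ms).

    Segment durations must be positive multiples of the sample interval so
    segment boundaries land exactly on sample points.
    """

    name: str
    segments: tuple[tuple[float, float], ...]
    sample_interval: float = 0.1

    def __post_init__(self) -> None:
        segments = tuple((float(v), float(d)) for v, d in self.segments)
        object.__setattr__(self, "segments", segments)
        if not segments:
            raise ValueError("protocol needs at least one segment")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        for level, dur in segments:
            if dur <= 0:
                raise ValueError(f"segment duration must be positive, got {dur}")
            n = dur / self.sample_interval
            if abs(n - round(n)) > 1e-9 * max(1.0, n):
                raise ValueError(
                    f"segment duration {dur} ms is not a multiple of the "
                    f"sample interval {self.sample_interval} ms"
                )
        if self.sample_interval > min(d for _, d in segments) + 1e-12:
            raise ValueError("sample_interval exceeds the shortest segment")

    @property
    def total_duration(self) -> float:
        """Total duration in ms."""
        return sum(d for _, d in self.segments)

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration / self.sample_interval))

    def times(self) -> np.ndarray:
        """Sample times (ms), left-aligned: t_k = k * sample_interval."""
        return np.arange(self.n_samples) * self.sample_interval

    def segment_bounds(self) -> list[tuple[int, int]]:
        """Half-open sample-index ranges [i0, i1) of each segment."""
        bounds = []
        start = 0
        for _, dur in self.segments:
            n = int(round(dur / self.sample_interval))
            bounds.append((start, start + n))
            start += n
        return bounds

    def voltage_trace(self) -> np.ndarray:
        v = np.empty(self.n_samples)
        for (level, _), (i0, i1) in zip(self.segments, self.segment_bounds()):
            v[i0:i1] = level
        return v


_PRESETS = ("step-family", "two-pulse")


def make_protocol(preset: str, **overrides):
    """Build a preset protocol.

    ``step-family`` returns a list of protocols, one per test level;
    ``two-pulse`` returns a single protocol.

    Overrides (defaults in parentheses):

    step-family: ``hold_mv`` (0), ``hold_ms`` (10), ``pre_mv`` (-100),
    ``pre_ms`` (20), ``test_levels`` (-150..+100 by 10), ``test_ms`` (150),
    ``sample_interval`` (0.1).

    two-pulse: ``hold_mv`` (0), ``hold_ms`` (10), ``pre_mv`` (-100),
    ``pre_ms`` (20), ``depol_mv`` (+100), ``depol_ms`` (50), ``test_mv``
    (-100), ``test_ms`` (300), ``sample_interval`` (0.1).
    """
    if preset == "step-family":
        defaults = dict(
            hold_mv=0.0,
            hold_ms=10.0,
            pre_mv=-100.0,
            pre_ms=20.0,
            test_levels=tuple(range(-150, 101, 10)),
            test_ms=150.0,
            sample_interval=0.1,
        )
        _check_overrides(defaults, overrides, preset)
        p = {**defaults, **overrides}
        return [
            VoltageProtocol(
                name=f"step_{int(level):+d}mV",
                segments=(
                    (p["hold_mv"], p["hold_ms"]),
                    (p["pre_mv"], p["pre_ms"]),
                    (level, p["test_ms"]),
                ),
                sample_interval=p["sample_interval"],
            )
            for level in p["test_levels"]
        ]
    if preset == "two-pulse":
        defaults = dict(
            hold_mv=0.0,
            hold_ms=10.0,
            pre_mv=-100.0,
            pre_ms=20.0,
            depol_mv=100.0,
            depol_ms=50.0,
            test_mv=-100.0,
            test_ms=300.0,
            sample_interval=0.1,
        )
        _check_overrides(defaults, overrides, preset)
        p = {**defaults, **overrides}
        return VoltageProtocol(
            name=f"twopulse_{p['depol_ms']:g}ms_{int(p['test_mv']):+d}mV",
            segments=(
                (p["hold_mv"], p["hold_ms"]),
                (p["pre_mv"], p["pre_ms"]),
                (p["depol_mv"], p["depol_ms"]),
                (p["test_mv"], p["test_ms"]),
            ),
            sample_interval=p["sample_interval"],
        )
    raise ConfigurationError(
        f"unknown protocol preset {preset!r}; available: {_PRESETS}"
    )


def _check_overrides(defaults: dict, overrides: dict, preset: str) -> None:
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ConfigurationError(
            f"unknown overrides for {preset!r}: {sorted(unknown)}"
        )


# segment indices of the presets, for downstream analyses
STEP_TEST_SEGMENT = 2
TWO_PULSE_DEPOL_SEGMENT = 2
TWO_PULSE_TAIL_SEGMENT = 3
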