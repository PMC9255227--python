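"""Fast chlorophyll-a fluorescence transients and their cardinal points.

A dark-adapted leaf exposed to strong actinic light shows the OJIP rise:
minimal fluorescence O near 10 µs, inflections J (~2 ms) and I (~30 ms), and
the peak P near 1 s. Two earlier inflections carry diagnostic weight: L
(0.15 ms, antenna connectivity) and K (0.3 ms, oxygen-evolving-complex
integrity). Instruments sample the transient on a logarithmic time grid, so
every interpolation here is linear in log10(time): that keeps relative
interpolation error uniform across the five decades of the induction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.signal import medfilt

from .errors import CoverageError, InvalidCurveError

#: Cardinal times in ms: O (origin), L, K, J, I, P (peak).
DEFAULT_CARDINAL_TIMES: dict[str, float] = {
    "O": 0.01,
    "L": 0.15,
    "K": 0.3,
    "J": 2.0,
    "I": 30.0,
    "P": 1000.0,
}

CARDINAL_ORDER = ("O", "L", "K", "J", "I", "P")


@dataclass
class FluorescenceTransient:
    """One induction curve: log-spaced time (ms) and fluorescence (a.u.)."""

    time_ms: np.ndarray
    signal: np.ndarray
    sample_id: str = ""
    group: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_ms.ndim != 1 or self.time_ms.shape != self.signal.shape:
            raise InvalidCurveError("time and signal must be equal-length 1-d arrays")
        if self.time_ms.size < 2:
            raise InvalidCurveError("a transient needs at least two samples")
        dt = np.diff(self.time_ms)
        if not np.all(dt > 0):
            idx = int(np.argmax(dt <= 0)) + 1
            raise InvalidCurveError(f"time not strictly increasing at row {idx}")
        if not np.all(np.isfinite(self.signal)) or np.any(self.signal <= 0):
            raise InvalidCurveError("signal must be finite and positive")
        if np.any(self.time_ms <= 0):
            raise InvalidCurveError("time values must be positive (log axis)")

    def __len__(self) -> int:
        return int(self.time_ms.size)

    def covers(self, t_ms: float) -> bool:
        return bool(self.time_ms[0] <= t_ms <= self.time_ms[-1])

    def scaled(self, factor: float) -> "FluorescenceTransient":
        """Return a copy with the signal multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return replace(self, signal=self.signal * factor)


@dataclass(frozen=True)
class CardinalPoints:
    """Fluorescence at the six cardinal times of one transient (a.u.)."""

    f_o: float
    f_l: float
    f_k: float
    f_j: float
    f_i: float
    f_p: float
    qc_flags: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict[str, float]:
        return {
            "O": self.f_o,
            "L": self.f_l,
            "K": self.f_k,
            "J": self.f_j,
            "I": self.f_i,
            "P": self.f_p,
        }

    @property
    def ok(self) -> bool:
        return not self.qc_flags

    def scaled(self, factor: float) -> "CardinalPoints":
        return CardinalPoints(
            self.f_o * factor,
            self.f_l * factor,
            self.f_k * factor,
            self.f_j * factor,
            self.f_i * factor,
            self.f_p * factor,
            self.qc_flags,
        )


def value_at(transient: FluorescenceTransient, t_ms) -> float | np.ndarray:
    """Interpolate the signal at ``t_ms`` linearly in log10(time).

    Exact at sample times; no extrapolation outside the sampled range.
    """
    t = np.asarray(t_ms, dtype=float)
    if np.any(t <= 0):
        raise ValueError("interpolation time must be positive")
    lo, hi = transient.time_ms[0], transient.time_ms[-1]
    if np.any(t < lo) or np.any(t > hi):
        raise CoverageError(
            f"time {np.min(t) if np.any(t < lo) else np.max(t):g} ms outside the "
            f"sampled range [{lo:g}, {hi:g}] ms (no extrapolation)"
        )
    out = np.interp(np.log10(t), np.log10(transient.time_ms), transient.signal)
    return float(out) if np.isscalar(t_ms) or t.ndim == 0 else out


def extract_cardinals(
    transient: FluorescenceTransient,
    cardinal_times: Mapping[str, float] | None = None,
    fm_rule: str = "at_P_time",
    median_filter: bool = False,
) -> CardinalPoints:
    """Read F at the configured O/L/K/J/I/P times.

    ``fm_rule`` selects F_P: ``at_P_time`` (value at the P time, default) or
    ``curve_max`` (maximum of the whole curve, for transients peaking early).
    ``median_filter`` applies a 3-point median before reading (off by
    default; raw extraction matches instrument marker values).

    Raises :class:`CoverageError` naming the first cardinal point whose time
    lies outside the sampled range.
    """
    times = dict(DEFAULT_CARDINAL_TIMES if cardinal_times is None else cardinal_times)
    if fm_rule not in ("at_P_time", "curve_max"):
        raise ValueError(f"unknown fm_rule: {fm_rule!r}")
    ordered = [times[c] for c in CARDINAL_ORDER]
    if not np.all(np.diff(ordered) > 0):
        raise ValueError("cardinal times must be strictly increasing O<L<K<J<I<P")
    for name in CARDINAL_ORDER:
        if not transient.covers(times[name]):
            raise CoverageError(
                f"time range [{transient.time_ms[0]:g}, {transient.time_ms[-1]:g}] ms "
                f"does not cover {name} time ({times[name]:g} ms)"
            )
    work = transient
    if median_filter and len(transient) >= 3:
        work = replace(transient, signal=medfilt(transient.signal, 3))

    vals = {name: float(value_at(work, times[name])) for name in CARDINAL_ORDER}
    if fm_rule == "curve_max":
        vals["P"] = float(np.max(work.signal))

    flags: list[str] = []
    if vals["P"] < 1.05 * vals["O"]:
        flags.append("no variable fluorescence")
    return CardinalPoints(
        vals["O"], vals["L"], vals["K"], vals["J"], vals["I"], vals["P"],
        qc_flags=tuple(flags),
    )
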