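"""Modulated 820 nm reflection (MR820) kinetics: PSI/P700 redox activity.

Under strong illumination the 820 nm reflection of a leaf first declines as
P700 and plastocyanin are oxidized, then partially recovers once electrons
arriving from PSII re-reduce them. The headline statistic is the relative
decline amplitude

    dI/I_o = (I_o - I_min) / I_o

with I_o the maximum and I_min the minimum reflection; a flooded leaf whose
PSI is inactive shows a nearly flat curve and dI/I_o near 0. The initial
slope of the decline phase (a.u. ms^-1, <= 0) is computed and reported
separately as a kinetic proxy of PSI oxidation rate.

Extrema of a noisy curve are biased outwards by extreme order statistics,
so extrema are located on a lightly Savitzky-Golay-smoothed copy; the slope
is still fit on the raw samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .errors import InvalidCurveError

#: Fractional amplitude below which a curve counts as flat (no PSI signal).
FLAT_RATIO = 1e-3


@dataclass
class MR820Curve:
    """820 nm reflection kinetics: time (ms) and relative reflection."""

    time_ms: np.ndarray
    reflection: np.ndarray
    sample_id: str = ""
    group: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.reflection = np.asarray(self.reflection, dtype=float)
        if self.time_ms.ndim != 1 or self.time_ms.shape != self.reflection.shape:
            raise InvalidCurveError("time and reflection must be equal-length 1-d arrays")
        if self.time_ms.size < 20:
            raise InvalidCurveError("an MR820 curve needs at least 20 samples")
        if not np.all(np.diff(self.time_ms) > 0):
            raise InvalidCurveError("time not strictly increasing")
        if not np.all(np.isfinite(self.reflection)) or np.any(self.reflection <= 0):
            raise InvalidCurveError("reflection must be finite and positive")

    def __len__(self) -> int:
        return int(self.time_ms.size)

    def scaled(self, factor: float) -> "MR820Curve":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return replace(self, reflection=self.reflection * factor)


@dataclass(frozen=True)
class MR820Result:
    """I_o, I_min, dI, dI/I_o and the initial decline slope of one curve."""

    i_o: float
    i_min: float
    delta_i: float
    delta_i_over_io: float
    initial_slope: float
    qc_flags: tuple[str, ...] = ()


def _smoothed(y: np.ndarray) -> np.ndarray:
    n = y.size
    window = min(31, n // 5)
    if window % 2 == 0:
        window -= 1
    if window < 5:
        return y
    return savgol_filter(y, window, polyorder=2)


def analyze_mr820(curve: MR820Curve, smooth: bool = True) -> MR820Result:
    """Extract I_o, dI, dI/I_o and the initial slope from one MR820 curve.

    I_o is the curve maximum and I_min the minimum (located on a smoothed
    copy unless ``smooth=False``). The initial slope is the least-squares
    slope of reflection vs time from the maximum to the first local minimum
    of the decline, capped at 30% of the samples. Flags: ``no PSI signal``
    for a flat curve (dI/I_o below 0.1% of I_o, a valid degenerate result
    with slope 0) and ``atypical`` when the maximum falls outside the first
    10% of samples.
    """
    y = _smoothed(curve.reflection) if smooth else curve.reflection
    t = curve.time_ms
    n = y.size
    flags: list[str] = []

    i_max_idx = int(np.argmax(y))
    i_min_idx = int(np.argmin(y))
    i_o = float(y[i_max_idx])
    i_min = float(y[i_min_idx])
    delta_i = i_o - i_min
    ratio = delta_i / i_o

    if ratio < FLAT_RATIO:
        # flat curve: exact-zero degenerate result (valid, flagged)
        return MR820Result(i_o, i_min, 0.0, 0.0, 0.0,
                           qc_flags=("no PSI signal",))

    if i_max_idx > max(1, n // 10):
        flags.append("atypical: maximum not in the first 10% of samples")
    if i_min_idx < i_max_idx:
        flags.append("atypical: minimum precedes maximum")
        i_min_idx = i_max_idx + int(np.argmin(y[i_max_idx:]))

    # end of the decline phase: the first (smoothed) local minimum after the
    # maximum, taken as the point where the curve has rebounded from its
    # running minimum by more than 5% of the amplitude (so noise wiggles on
    # the way down do not truncate the segment); capped at 30% of samples
    seg_end = i_min_idx
    tail = y[i_max_idx:i_min_idx + 1]
    running_min = np.minimum.accumulate(tail)
    rebounded = np.nonzero(tail > running_min + 0.05 * delta_i)[0]
    if rebounded.size:
        seg_end = i_max_idx + int(rebounded[0]) - 1
    seg_end = min(seg_end, i_max_idx + max(2, int(0.3 * n)))
    seg = slice(i_max_idx, seg_end + 1)
    if seg_end - i_max_idx < 1:
        slope = 0.0
        flags.append("decline segment too short for a slope")
    else:
        slope = float(np.polyfit(t[seg], curve.reflection[seg], 1)[0])
    return MR820Result(i_o, i_min, delta_i, ratio, slope, qc_flags=tuple(flags))
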