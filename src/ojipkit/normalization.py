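"""Double normalization of OJIP transients and relative variable fluorescence.

Three windows are standardized so the start point is 0 and the end point 1:

    V_O-P(t) = (F_t - F_o) / (F_P - F_o)
    V_O-J(t) = (F_t - F_o) / (F_J - F_o)
    V_O-K(t) = (F_t - F_o) / (F_K - F_o)

The band-specific relative variable fluorescence values read off these
curves are

    V_L = (F_L - F_o) / (F_K - F_o)   (L point on the O-K curve)
    V_K = (F_K - F_o) / (F_J - F_o)   (K point on the O-J curve)
    V_J = (F_J - F_o) / (F_P - F_o)   (J point on the O-P curve)

A rise of V_K marks donor-side (oxygen-evolving complex) damage, a rise of
V_L loss of antenna connectivity, and a rise of V_J a block of electron
transfer past Q_A. V_I = (F_I - F_o)/(F_P - F_o) is also computed: the
performance index PI_total needs it through the PSI-end efficiency deltaRo.

Being ratios of baseline-subtracted values, all of these are exactly
invariant under rescaling the signal and under adding a constant to every
sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import NormalizationError
from .transient import (
    DEFAULT_CARDINAL_TIMES,
    CardinalPoints,
    FluorescenceTransient,
    value_at,
)

#: window name -> (start cardinal, end cardinal)
WINDOWS: dict[str, tuple[str, str]] = {
    "O-P": ("O", "P"),
    "O-J": ("O", "J"),
    "O-K": ("O", "K"),
}

_END_FIELD = {"P": "f_p", "J": "f_j", "K": "f_k"}


@dataclass(frozen=True)
class NormalizedCurve:
    """A double-normalized curve on one window; V(start)=0, V(end)=1."""

    window: str
    time_ms: np.ndarray
    v: np.ndarray
    group: str = ""
    sample_id: str = ""

    def value_at(self, t_ms) -> float | np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        out = np.interp(np.log10(t), np.log10(self.time_ms), self.v)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RelativeVariableFluorescence:
    """V_L (O-K scale), V_K (O-J scale), V_J and V_I (O-P scale)."""

    v_l: float
    v_k: float
    v_j: float
    v_i: float


@dataclass(frozen=True)
class DifferenceKinetics:
    """Group-mean treatment-minus-control curve on a common log grid."""

    window: str
    time_ms: np.ndarray
    delta_v: np.ndarray
    group: str = ""
    control: str = ""


def normalize(
    transient: FluorescenceTransient,
    cardinals: CardinalPoints,
    window: str,
    cardinal_times: Mapping[str, float] | None = None,
) -> NormalizedCurve:
    """Standardize one window of the transient to [0, 1].

    The returned grid is the transient's own samples inside the window with
    the exact window endpoints appended, so endpoint pinning holds by
    construction.
    """
    if window not in WINDOWS:
        raise ValueError(f"unknown window {window!r}; expected one of {sorted(WINDOWS)}")
    times = DEFAULT_CARDINAL_TIMES if cardinal_times is None else cardinal_times
    start_c, end_c = WINDOWS[window]
    t_start, t_end = float(times[start_c]), float(times[end_c])
    f_o = cardinals.f_o
    f_end = getattr(cardinals, _END_FIELD[end_c])
    denom = f_end - f_o
    if denom <= 0:
        raise NormalizationError(
            f"non-inducing curve, normalization undefined (F_{end_c} <= F_o on {window})"
        )
    inside = (transient.time_ms > t_start) & (transient.time_ms < t_end)
    t = np.concatenate(([t_start], transient.time_ms[inside], [t_end]))
    f = np.concatenate(
        ([value_at(transient, t_start)], transient.signal[inside], [value_at(transient, t_end)])
    )
    v = (f - f_o) / denom
    return NormalizedCurve(window, t, v, group=transient.group, sample_id=transient.sample_id)


def relative_variable_fluorescence(cardinals: CardinalPoints) -> RelativeVariableFluorescence:
    """Band-scale V_L, V_K, V_J plus V_I from one set of cardinal points."""
    f_o = cardinals.f_o
    for band, denom in (("O-K", cardinals.f_k - f_o),
                        ("O-J", cardinals.f_j - f_o),
                        ("O-P", cardinals.f_p - f_o)):
        if denom <= 0:
            raise NormalizationError(
                f"non-inducing curve, normalization undefined on the {band} band"
            )
    return RelativeVariableFluorescence(
        v_l=(cardinals.f_l - f_o) / (cardinals.f_k - f_o),
        v_k=(cardinals.f_k - f_o) / (cardinals.f_j - f_o),
        v_j=(cardinals.f_j - f_o) / (cardinals.f_p - f_o),
        v_i=(cardinals.f_i - f_o) / (cardinals.f_p - f_o),
    )


def common_grid(window_start_ms: float, window_end_ms: float,
                points_per_decade: int = 100) -> np.ndarray:
    """Log-uniform grid over a window, endpoints included."""
    decades = np.log10(window_end_ms / window_start_ms)
    n = max(2, int(round(decades * points_per_decade)) + 1)
    return np.geomspace(window_start_ms, window_end_ms, n)


def mean_curve(curves: Iterable[NormalizedCurve],
               points_per_decade: int = 100) -> NormalizedCurve:
    """Average normalized replicate curves on a common log grid."""
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    windows = {c.window for c in curves}
    if len(windows) > 1:
        raise ValueError(f"window mismatch: {sorted(windows)}")
    window = curves[0].window
    start = max(c.time_ms[0] for c in curves)
    end = min(c.time_ms[-1] for c in curves)
    grid = common_grid(start, end, points_per_decade)
    stack = np.vstack([c.value_at(grid) for c in curves])
    return NormalizedCurve(window, grid, stack.mean(axis=0),
                           group=curves[0].group)


def difference_kinetics(
    group_curves: Iterable[NormalizedCurve],
    control_curves: Iterable[NormalizedCurve],
    points_per_decade: int = 100,
) -> DifferenceKinetics:
    """Delta-V(t): mean treatment curve minus mean control curve.

    Replicates are normalized first and averaged afterwards; both groups are
    interpolated onto one log grid before subtraction.
    """
    g = mean_curve(group_curves, points_per_decade)
    c = mean_curve(control_curves, points_per_decade)
    if g.window != c.window:
        raise ValueError(f"window mismatch: {g.window!r} vs {c.window!r}")
    start = max(g.time_ms[0], c.time_ms[0])
    end = min(g.time_ms[-1], c.time_ms[-1])
    grid = common_grid(start, end, points_per_decade)
    dv = np.asarray(g.value_at(grid)) - np.asarray(c.value_at(grid))
    return DifferenceKinetics(g.window, grid, dv, group=g.group, control=c.group)
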