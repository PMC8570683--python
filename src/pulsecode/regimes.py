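"""Coding-regime analysis of an afferent threshold curve.

A sinusoidal threshold curve A(f) — amplitude needed at frequency f to evoke a
first spike — can be reinterpreted pulse-locally: reading each sinusoid as a
train of pulses of width w = 1000/f ms, contours of constant maximal position,
velocity and acceleration are straight lines in log–log coordinates: slopes
0, +1 and +2 against log pulse width (equivalently 0, −1, −2 against log
frequency).  Where the threshold curve runs parallel to one of those
contours, stimuli traded along that kinematic variable leave the afferent's
response unchanged, so that variable is the one the afferent effectively
codes there.  The analysis computes the threshold-curve slope (central
differences in log–log, reported against log width), subtracts each contour
slope, and labels each pulse width by the variable whose slope difference is
smallest in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ThresholdCurve", "RegimeMap", "slope_difference", "regime_at", "default_curve"]

#: contour slopes in (log w, log A) for the three local kinematic variables
CONTOUR_SLOPES = {"position": 0.0, "velocity": 1.0, "acceleration": 2.0}

#: tie-break order: lower derivative order wins
_VARIABLES = ("position", "velocity", "acceleration")


@dataclass(frozen=True)
class ThresholdCurve:
    """An afferent threshold curve A(f), evaluated in log–log space.

    Either tabulated (frequencies Hz strictly increasing, amplitudes μm > 0;
    evaluation by linear interpolation in log–log) or a log-parabola
    log10 A = log10 A_min + curvature · (log10 f − log10 f_min)².
    """

    frequencies: tuple[float, ...] = field(default_factory=tuple)
    amplitudes: tuple[float, ...] = field(default_factory=tuple)
    parabola: tuple[float, float, float] | None = None  # (f_min, A_min, curvature)

    def __post_init__(self) -> None:
        if self.parabola is None:
            f = np.asarray(self.frequencies, dtype=float)
            a = np.asarray(self.amplitudes, dtype=float)
            if f.size < 2:
                raise ValueError("need ≥ 2 tabulated points or a parabola")
            if np.any(np.diff(f) <= 0):
                raise ValueError("frequencies must be strictly increasing")
            if np.any(a <= 0) or np.any(f <= 0):
                raise ValueError("frequencies and amplitudes must be positive")

    @property
    def support(self) -> tuple[float, float]:
        """Frequency range (Hz) over which the curve is defined."""
        if self.parabola is not None:
            return (1.0, 1000.0)
        return (self.frequencies[0], self.frequencies[-1])

    def log_amplitude(self, freq) -> np.ndarray:
        """log10 A at frequency ``freq`` (Hz)."""
        logf = np.log10(np.asarray(freq, dtype=float))
        if self.parabola is not None:
            f_min, a_min, curv = self.parabola
            return np.log10(a_min) + curv * (logf - np.log10(f_min)) ** 2
        return np.interp(
            logf, np.log10(self.frequencies), np.log10(self.amplitudes)
        )


def default_curve() -> ThresholdCurve:
    """Shipped default: a log-parabola with its minimum at 250 Hz / 0.1 μm and
    curvature 1.25 decades/decade², a shape typical of Pacinian tuning.  It is
    a documented stand-in, not digitized afferent data.
    """
    return ThresholdCurve(parabola=(250.0, 0.1, 1.25))


@dataclass
class RegimeMap:
    """Per-width slope differences, regime labels and regime boundaries."""

    widths: np.ndarray  # ms, ascending
    slope_diffs: dict[str, np.ndarray]  # threshold-curve slope − contour slope
    labels: list[str]  # best-matching variable per width
    zero_crossings: dict[str, list[float]]  # widths where each difference = 0


def slope_difference(
    curve: ThresholdCurve, width_grid, smooth_window: int = 0
) -> RegimeMap:
    """Compare the threshold-curve slope with the iso-kinematic contour slopes.

    ``width_grid``: pulse widths in ms (any order; stored ascending).  The
    curve must cover the corresponding frequency range.  ``smooth_window``
    applies a centred moving average (in samples) to the slope estimate.
    """
    widths = np.sort(np.asarray(list(width_grid), dtype=float))
    if widths.size < 3:
        raise ValueError("need ≥ 3 widths to estimate slopes")
    freqs = 1000.0 / widths[::-1]  # ascending in f
    lo, hi = curve.support
    if freqs[0] < lo - 1e-9 or freqs[-1] > hi + 1e-9:
        raise ValueError(
            f"width grid maps to {freqs[0]:.1f}–{freqs[-1]:.1f} Hz, outside the "
            f"curve support {lo:.1f}–{hi:.1f} Hz"
        )
    logf = np.log10(freqs)
    loga = curve.log_amplitude(freqs)
    slope_f = np.gradient(loga, logf)  # d log A / d log f, ascending in f
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(slope_f, pad, mode="edge")
        slope_f = np.convolve(padded, kernel, mode="same")[pad : pad + slope_f.size]
    slope_w = -slope_f[::-1]  # d log A / d log w, ascending in width

    diffs = {v: slope_w - s for v, s in CONTOUR_SLOPES.items()}
    labels = []
    for i in range(widths.size):
        best = min(_VARIABLES, key=lambda v: (abs(diffs[v][i]), _VARIABLES.index(v)))
        labels.append(best)
    crossings = {v: _zero_crossings(widths, d) for v, d in diffs.items()}
    return RegimeMap(widths=widths, slope_diffs=diffs, labels=labels, zero_crossings=crossings)


def _zero_crossings(x: np.ndarray, y: np.ndarray) -> list[float]:
    out = [float(x[i]) for i in np.nonzero(y == 0)[0]]
    sign = np.sign(y)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    for i in idx:
        out.append(float(x[i] - y[i] * (x[i + 1] - x[i]) / (y[i + 1] - y[i])))
    return sorted(out)


def regime_at(regime_map: RegimeMap, width: float) -> str:
    """Regime label at a pulse width (nearest grid point); errors out of range."""
    w = regime_map.widths
    if not (w[0] - 1e-9 <= width <= w[-1] + 1e-9):
        raise ValueError(f"width {width} ms outside grid {w[0]:.3f}–{w[-1]:.3f} ms")
    return regime_map.labels[int(np.argmin(np.abs(w - width)))]
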