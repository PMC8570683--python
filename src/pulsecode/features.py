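"""Kinematic and intensity features of pulsatile stimuli, and iso-feature-lines.

Nine formulations are supported.  Three are temporally *local* — extrema of a
single pulse: maximal position, maximal velocity, maximal acceleration.  Six
are temporally *global* intensities — time averages of a rectified derivative
raised to a power, taken across the whole 500-ms stimulus including inter-pulse
silence: mean |velocity|^p and mean |acceleration|^p for p ∈ {1, 2, 3}.

For a single-period-cosine pulse x(t) = (a/2)(1 − cos 2πt/w) every feature is a
monomial c · a^m / w^k (times the pulse rate for the global means), so the locus
of constant feature value in the (width, amplitude) plane is a power law
a ∝ w^β with β = k/m.  These loci are the iso-feature-lines, labelled a–g:

    line  a : β = 0    max position  ≡ mean |velocity|      (congruent pair)
    line  b : β = 1/2  mean velocity²
    line  c : β = 2/3  mean velocity³
    line  d : β = 1    max velocity  ≡ mean |acceleration|  (congruent pair)
    line  e : β = 3/2  mean acceleration²
    line  f : β = 5/3  mean acceleration³
    line  g : β = 2    max acceleration

On log–log axes each line is affine with slope β.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .stimuli import PulseSpec

__all__ = [
    "FEATURE_NAMES",
    "LINE_OF_FEATURE",
    "ISO_EXPONENTS",
    "FeatureDef",
    "IsoLine",
    "feature_closed_form",
    "feature_numeric",
    "iso_amplitude",
    "build_isoline",
    "dpp_amplitude",
    "isoline_table",
]

_PI = np.pi

#: iso-line exponent β per line label
ISO_EXPONENTS: dict[str, Fraction] = {
    "a": Fraction(0),
    "b": Fraction(1, 2),
    "c": Fraction(2, 3),
    "d": Fraction(1),
    "e": Fraction(3, 2),
    "f": Fraction(5, 3),
    "g": Fraction(2),
}

#: feature name -> line label
LINE_OF_FEATURE: dict[str, str] = {
    "max_position": "a",
    "mean_abs_velocity": "a",
    "mean_sq_velocity": "b",
    "mean_cub_velocity": "c",
    "max_velocity": "d",
    "mean_abs_acceleration": "d",
    "mean_sq_acceleration": "e",
    "mean_cub_acceleration": "f",
    "max_acceleration": "g",
}

FEATURE_NAMES = tuple(LINE_OF_FEATURE)


@dataclass(frozen=True)
class FeatureDef:
    """A named feature with its iso-line label and exponent."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in LINE_OF_FEATURE:
            raise KeyError(f"unknown feature {self.name!r}; one of {FEATURE_NAMES}")

    @property
    def line_label(self) -> str:
        return LINE_OF_FEATURE[self.name]

    @property
    def iso_exponent(self) -> float:
        return float(ISO_EXPONENTS[self.line_label])


def feature_closed_form(feature: str, a: float, w: float, r: float = 90.0) -> float:
    """Closed-form feature value for a single-period-cosine pulse.

    Parameters: amplitude ``a`` (μm), width ``w`` (ms), pulse rate ``r`` (Hz).
    Local maxima ignore ``r``.  Global means are per-ms time averages over the
    full stimulus (rate in Hz is converted to pulses/ms), in μm-ms units:
    e.g. mean_abs_velocity is μm/ms, mean_sq_acceleration (μm/ms²)².
    """
    rp = r / 1000.0  # pulses per ms
    forms = {
        "max_position": lambda: a,
        "max_velocity": lambda: _PI * a / w,
        "max_acceleration": lambda: 2.0 * _PI**2 * a / w**2,
        "mean_abs_velocity": lambda: 2.0 * a * rp,
        "mean_sq_velocity": lambda: rp * _PI**2 * a**2 / (2.0 * w),
        "mean_cub_velocity": lambda: rp * 4.0 * _PI**2 * a**3 / (3.0 * w**2),
        "mean_abs_acceleration": lambda: rp * 4.0 * _PI * a / w,
        "mean_sq_acceleration": lambda: rp * 2.0 * _PI**4 * a**2 / w**3,
        "mean_cub_acceleration": lambda: rp * (32.0 / 3.0) * _PI**5 * a**3 / w**5,
    }
    try:
        return forms[feature]()
    except KeyError:
        raise KeyError(f"unknown feature {feature!r}; one of {FEATURE_NAMES}") from None


def feature_numeric(
    feature: str, waveform: np.ndarray, sample_rate: float, duration: float | None = None
) -> float:
    """Feature value computed from a sampled waveform (oracle for the closed forms).

    Velocity uses second-order central differences; acceleration uses the
    fourth-order five-point stencil (the pulse-edge acceleration step makes the
    plain double-difference too lossy for the cubed mean).  Global means are
    trapezoidal time averages of the rectified derivative raised to its power,
    over ``duration`` ms (default: the waveform's own length).
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size < 3:
        raise ValueError("waveform must have at least 3 samples")
    dt = 1000.0 / sample_rate  # ms
    if duration is None:
        duration = waveform.size * dt
    vel = np.gradient(waveform, dt)

    if feature == "max_position":
        return float(np.max(waveform))
    if feature == "max_velocity":
        return float(np.max(np.abs(vel)))
    if feature == "max_acceleration":
        # compact stencil: the wide one overshoots at the onset step
        acc2 = np.empty_like(waveform)
        acc2[1:-1] = (waveform[2:] - 2 * waveform[1:-1] + waveform[:-2]) / dt**2
        acc2[0], acc2[-1] = acc2[1], acc2[-2]
        return float(np.max(np.abs(acc2)))
    acc = _second_derivative(waveform, dt)
    power = {"abs": 1, "sq": 2, "cub": 3}
    for tag, p in power.items():
        if feature == f"mean_{tag}_velocity":
            return float(np.trapezoid(np.abs(vel) ** p, dx=dt) / duration)
        if feature == f"mean_{tag}_acceleration":
            return float(np.trapezoid(np.abs(acc) ** p, dx=dt) / duration)
    raise KeyError(f"unknown feature {feature!r}; one of {FEATURE_NAMES}")


def _second_derivative(x: np.ndarray, dt: float) -> np.ndarray:
    """Fourth-order central second derivative; second-order near the edges."""
    acc = np.empty_like(x)
    if x.size >= 5:
        acc[2:-2] = (-x[4:] + 16 * x[3:-1] - 30 * x[2:-2] + 16 * x[1:-3] - x[:-4]) / (
            12 * dt**2
        )
        acc[1] = (x[2] - 2 * x[1] + x[0]) / dt**2
        acc[-2] = (x[-1] - 2 * x[-2] + x[-3]) / dt**2
    else:
        acc[1:-1] = (x[2:] - 2 * x[1:-1] + x[:-2]) / dt**2
    acc[0] = acc[1]
    acc[-1] = acc[-2]
    return acc


def iso_amplitude(line: str, anchor: tuple[float, float], w) -> float | np.ndarray:
    """Amplitude on an iso-feature-line at width ``w``.

    ``anchor`` is (a₀, w₀); the line is a = a₀ · (w/w₀)^β with β the line's
    exponent.  Exact at w = w₀.  ``line`` may also be a feature name.
    """
    if line in LINE_OF_FEATURE:
        line = LINE_OF_FEATURE[line]
    if line not in ISO_EXPONENTS:
        raise KeyError(f"unknown iso-line {line!r}; one of {tuple(ISO_EXPONENTS)}")
    a0, w0 = anchor
    if a0 <= 0 or w0 <= 0:
        raise ValueError("anchor amplitude and width must be positive")
    beta = float(ISO_EXPONENTS[line])
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("width must be positive")
    out = a0 * (w / w0) ** beta
    return float(out) if out.ndim == 0 else out


# Printed endpoint amplitudes of line d′′ (μm) at the Range I width endpoints.
_DPP_TABLE_ENDPOINTS = (33.5, 24.5)


def dpp_amplitude(
    anchor: tuple[float, float],
    w,
    *,
    ref_rate: float = 90.0,
    comp_rate: float = 105.0,
    table_override: bool = False,
) -> float | np.ndarray:
    """Amplitude on line d′′ — shapes reduced so that, despite the higher
    comparison pulse rate, the stimulus-wide mean absolute acceleration equals
    the reference's.

    Closed form: mean |acc| ∝ a·r/w, so a(w) = a₀·(r_ref/r_comp)·(w/w₀).  With
    ``table_override`` a power law through the printed endpoint amplitudes is
    used instead (the published endpoints deviate ~2% from the closed form).
    """
    a0, w0 = anchor
    w = np.asarray(w, dtype=float)
    if table_override:
        a_top, a_bot = _DPP_TABLE_ENDPOINTS
        w_bot = 1000.0 / 240.0
        q = np.log(a_bot / a_top) / np.log(w_bot / w0)
        out = a_top * (w / w0) ** q
    else:
        out = a0 * (ref_rate / comp_rate) * (w / w0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class IsoLine:
    """An ordered set of comparison pulse shapes along one iso-feature-line."""

    line: str
    anchor: tuple[float, float]  # (a0 μm, w0 ms)
    widths: tuple[float, ...]  # change widths, ms (anchor excluded)
    amplitudes: tuple[float, ...]  # μm, matching widths
    rate: float  # Hz

    @property
    def n_levels(self) -> int:
        return len(self.widths)

    def pulse_specs(self, sample_rate: float = 40_000.0) -> list[PulseSpec]:
        return [PulseSpec(a, w, sample_rate) for a, w in zip(self.amplitudes, self.widths)]


def build_isoline(
    line: str, anchor: tuple[float, float], width_grid, rate: float = 90.0
) -> IsoLine:
    """Construct an iso-feature-line over a strictly monotone width grid.

    The grid holds the comparison (change) widths only; the anchor is excluded.
    """
    widths = np.asarray(list(width_grid), dtype=float)
    if widths.size == 0:
        raise ValueError("empty width grid")
    d = np.diff(widths)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("width grid must be strictly monotone")
    amps = np.atleast_1d(iso_amplitude(line, anchor, widths))
    if line in LINE_OF_FEATURE:
        line = LINE_OF_FEATURE[line]
    return IsoLine(line, tuple(anchor), tuple(widths), tuple(amps), rate)


def isoline_table(isolines: list[IsoLine]) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate iso-lines as (line_label, width_ms, amplitude_um) rows."""
    import pandas as pd

    rows = [
        {"line_label": il.line, "width_ms": w, "amplitude_um": a}
        for il in isolines
        for w, a in zip(il.widths, il.amplitudes)
    ]
    return pd.DataFrame(rows)
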