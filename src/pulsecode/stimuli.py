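"""Sampled pulsatile indentation stimuli.

The atomic element is a single-period "raised-cosine" pulse: one period of a
sinusoid taken from one minimum to the next, so the skin indentation starts at
the resting position (0, on top of a static pre-indentation), rises to the pulse
amplitude and returns to rest.  Pulses are repeated at a fixed rate to form
500-ms trains, and a trial is the seamless concatenation of a reference train
and a comparison train (identical to the reference on no-change trials).

Units are package-wide: amplitudes in μm, times/widths in ms, rates in Hz
(pulses/s), sample rates in samples/s.  Velocities are μm/ms and accelerations
μm/ms².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PulseSpec",
    "TrainSpec",
    "TrialStimulus",
    "make_pulse",
    "make_train",
    "make_trial",
    "RANGE_I",
    "RANGE_II",
    "StimulusRange",
]


class InvalidSpecError(ValueError):
    """Raised when a stimulus specification violates its invariants."""


@dataclass(frozen=True)
class PulseSpec:
    """A single-period-sinusoid indentation pulse.

    Parameters
    ----------
    amplitude : float
        Peak indentation depth beyond rest, μm.
    width : float
        Pulse duration (one sinusoid period), ms.
    sample_rate : float
        Sampling rate, samples/s (default 40 kHz as used for stimulus playout).
    """

    amplitude: float
    width: float
    sample_rate: float = 40_000.0

    def __post_init__(self) -> None:
        if not (self.amplitude > 0 and self.width > 0 and self.sample_rate > 0):
            raise InvalidSpecError(
                f"amplitude, width and sample_rate must be positive, got "
                f"({self.amplitude}, {self.width}, {self.sample_rate})"
            )
        if self.sample_rate * self.width / 1000.0 < 8:
            raise InvalidSpecError(
                f"pulse of width {self.width} ms at {self.sample_rate} Hz has "
                "fewer than 8 samples"
            )

    @property
    def n_samples(self) -> int:
        """Samples per pulse: round(width · fs / 1000)."""
        return int(round(self.width * self.sample_rate / 1000.0))


@dataclass(frozen=True)
class TrainSpec:
    """A train of identical pulses at a fixed rate.

    Pulses must not overlap: width ≤ 1000/rate ms.
    """

    pulse: PulseSpec
    rate: float  # pulses/s
    duration: float = 500.0  # ms

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.duration <= 0:
            raise InvalidSpecError("rate and duration must be positive")
        if self.pulse.width > 1000.0 / self.rate + 1e-9:
            raise InvalidSpecError(
                f"pulses overlap: width {self.pulse.width} ms exceeds the "
                f"inter-pulse interval {1000.0 / self.rate:.3f} ms at "
                f"{self.rate} Hz"
            )

    @property
    def n_pulses(self) -> int:
        """Number of pulse onsets that fit in the train: floor(duration·rate/1000)."""
        return int(np.floor(self.duration * self.rate / 1000.0 + 1e-9))


@dataclass(frozen=True)
class TrialStimulus:
    """Reference train followed seamlessly by a comparison train."""

    reference: TrainSpec
    comparison: TrainSpec
    is_change: bool

    def __post_init__(self) -> None:
        if self.reference.duration != self.comparison.duration:
            raise InvalidSpecError("reference and comparison durations must match")


def make_pulse(spec: PulseSpec) -> np.ndarray:
    """Sample a single pulse.

    The waveform is x(t) = (a/2)·(1 − cos(2πt/w)) for t ∈ [0, w): it starts at
    0, peaks at the amplitude a at mid-pulse, and returns to ~0 at the last
    sample.  Returns indentation positions in μm.
    """
    n = spec.n_samples
    t = np.arange(n) * (1000.0 / spec.sample_rate)  # ms
    return 0.5 * spec.amplitude * (1.0 - np.cos(2.0 * np.pi * t / spec.width))


def make_train(spec: TrainSpec) -> np.ndarray:
    """Sample a pulse train.

    Pulse onsets sit at k/rate seconds (k = 0 .. n_pulses−1), quantized to the
    sample grid by rounding; the waveform is zero between a pulse's offset and
    the next onset.
    """
    fs = spec.pulse.sample_rate
    n_total = int(round(spec.duration * fs / 1000.0))
    out = np.zeros(n_total)
    pulse = make_pulse(spec.pulse)
    for k in range(spec.n_pulses):
        start = int(round(k * fs / spec.rate))
        stop = min(start + pulse.size, n_total)
        out[start:stop] = pulse[: stop - start]
    return out


def make_trial_waveform(trial: TrialStimulus) -> np.ndarray:
    """Concatenate reference and comparison trains with no gap or overlap."""
    return np.concatenate([make_train(trial.reference), make_train(trial.comparison)])


# ---------------------------------------------------------------------------
# Experimental stimulus ranges and trial construction
# ---------------------------------------------------------------------------


def _widths_from_frequencies(freqs) -> tuple[float, ...]:
    return tuple(1000.0 / f for f in freqs)


@dataclass(frozen=True)
class StimulusRange:
    """One of the two tested regions of the (width, amplitude) stimulus space.

    ``change_widths`` are the comparison pulse widths (ms), ordered from the
    width nearest the reference down to the narrowest; the reference itself is
    not a change level.
    """

    name: str
    ref_amplitude: float  # μm
    ref_width: float  # ms
    ref_rate: float  # Hz
    change_widths: tuple[float, ...] = field(default_factory=tuple)

    @property
    def n_levels(self) -> int:
        return len(self.change_widths)


# Range I: sinusoid frequencies 170–240 Hz step 5 → 15 waveforms; the 170-Hz
# (5.882 ms) member is the reference, leaving 14 change levels.
RANGE_I = StimulusRange(
    name="I",
    ref_amplitude=40.0,
    ref_width=1000.0 / 170.0,
    ref_rate=90.0,
    change_widths=_widths_from_frequencies(range(175, 245, 5)),
)

# Range II: reference at 35 Hz (28.571 ms); ten change frequencies 38–65 Hz
# step 3, giving the printed endpoint widths 26.316 and 15.385 ms.  The grid is
# a default and can be overridden via StimulusRange.
RANGE_II = StimulusRange(
    name="II",
    ref_amplitude=100.0,
    ref_width=1000.0 / 35.0,
    ref_rate=30.0,
    change_widths=_widths_from_frequencies(range(38, 68, 3)),
)

STIMULUS_RANGES = {"I": RANGE_I, "II": RANGE_II}

#: Comparison pulse rates for the rate-change condition (Hz); reference is 90.
RATE_CHANGE_LEVELS = tuple(range(95, 140, 5))

#: Comparison pulse rate in the combined rate-and-shape conditions (d′, d′′).
RATE_AND_SHAPE_RATE = 105.0


def make_trial(
    condition: str,
    level: int | None,
    *,
    stimulus_range: StimulusRange = RANGE_I,
    line: str = "d",
    sample_rate: float = 40_000.0,
    dpp_table_override: bool = False,
) -> TrialStimulus:
    """Build the reference+comparison stimulus for one trial.

    Parameters
    ----------
    condition : {"shape", "rate", "rate_and_shape_dp", "rate_and_shape_dpp"}
        ``shape``: comparison pulses from iso-feature ``line`` at the reference
        rate. ``rate``: identical pulse shape, higher rate.  ``rate_and_shape_dp``:
        line-d shapes at 105 Hz (line d′).  ``rate_and_shape_dpp``: amplitudes
        reduced so the comparison's mean absolute acceleration matches the
        reference despite the extra pulses (line d′′).
    level : int or None
        0-based index into the condition's comparison grid; ``None`` builds a
        no-change trial (comparison identical to the reference).
    dpp_table_override : bool
        For d′′ only — use a power law through the printed endpoint amplitudes
        (33.5–24.5 μm) instead of the closed-form intensity match.
    """
    from . import features  # local import to avoid a cycle

    rng_ = stimulus_range
    ref_pulse = PulseSpec(rng_.ref_amplitude, rng_.ref_width, sample_rate)
    reference = TrainSpec(ref_pulse, rng_.ref_rate)
    if level is None:
        return TrialStimulus(reference, reference, is_change=False)

    if condition == "rate":
        if not 0 <= level < len(RATE_CHANGE_LEVELS):
            raise KeyError(f"rate level {level} outside 0..{len(RATE_CHANGE_LEVELS)-1}")
        comp = TrainSpec(ref_pulse, float(RATE_CHANGE_LEVELS[level]))
    elif condition == "shape":
        if not 0 <= level < rng_.n_levels:
            raise KeyError(f"shape level {level} outside 0..{rng_.n_levels-1}")
        w = rng_.change_widths[level]
        a = features.iso_amplitude(line, (rng_.ref_amplitude, rng_.ref_width), w)
        comp = TrainSpec(PulseSpec(a, w, sample_rate), rng_.ref_rate)
    elif condition == "rate_and_shape_dp":
        if not 0 <= level < rng_.n_levels:
            raise KeyError(f"d' level {level} outside 0..{rng_.n_levels-1}")
        w = rng_.change_widths[level]
        a = features.iso_amplitude("d", (rng_.ref_amplitude, rng_.ref_width), w)
        comp = TrainSpec(PulseSpec(a, w, sample_rate), RATE_AND_SHAPE_RATE)
    elif condition == "rate_and_shape_dpp":
        if not 0 <= level < rng_.n_levels:
            raise KeyError(f"d'' level {level} outside 0..{rng_.n_levels-1}")
        w = rng_.change_widths[level]
        a = features.dpp_amplitude(
            (rng_.ref_amplitude, rng_.ref_width),
            w,
            ref_rate=rng_.ref_rate,
            comp_rate=RATE_AND_SHAPE_RATE,
            table_override=dpp_table_override,
        )
        comp = TrainSpec(PulseSpec(a, w, sample_rate), RATE_AND_SHAPE_RATE)
    else:
        raise KeyError(f"unknown condition {condition!r}")
    return TrialStimulus(reference, comp, is_change=True)
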