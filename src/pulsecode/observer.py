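"""Simplified Pacinian-corpuscle population encoder and ROC neurometrics.

Pacinian (rapidly adapting type 2) afferents respond to brief indentation
pulses with at most a spike or two and show no rate adaptation across pulses,
so a pulse train is encoded pulse by pulse.  The encoder here reduces that
physiology to its geometry: each unit has an iso-response line in
(log width, log amplitude) space — the locus of pulse shapes at its firing
threshold — and fires on a given pulse with probability

    p = Φ((log a − L(w) − offset_u) / s),       L(w) = log a₀ + β_r·log(w/w₀)

where β_r is the population iso-response slope, offset_u a per-unit threshold
offset (Normal, SD = heterogeneity), and s the sigmoid width in log-amplitude
units.  A pulse lying *on* the population line drives every unit identically,
so stimuli traded along a collinear iso-feature-line are indistinguishable —
the geometric argument this model exists to test.

Discriminability between spike-count ensembles uses the rank (Mann–Whitney)
AUC with half-credit ties, folded to d = 2·|AUC − 0.5| so that both perfect
orderings score 1 and chance scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .features import IsoLine
from .stimuli import TrainSpec

__all__ = [
    "ObserverPopulation",
    "SpikeEnsemble",
    "simulate_ensemble",
    "auc",
    "discriminability",
    "neurometric_curve",
]


@dataclass(frozen=True)
class ObserverPopulation:
    """A population of per-pulse probabilistic spikers.

    Parameters
    ----------
    n_units : int
        Population size (default 192, a realistic PC count for one digit).
    iso_slope : float
        β_r, slope of the population iso-response line in log–log space.
        Defaults per stimulus range: ~1.2 (Range I geometry, near line d) or
        ~1.8 (Range II geometry, near lines f/g).
    anchor : (float, float)
        (a₀ μm, w₀ ms): a pulse shape lying on the population line, i.e. at the
        median unit's half-activation point.
    sigmoid_width : float
        s, in natural-log amplitude units.
    heterogeneity : float
        SD of per-unit threshold offsets (natural-log amplitude units).
    spike_cap : int or None
        1 → Bernoulli spiking per pulse (default); None → Poisson with mean
        ``poisson_mean`` · p.
    """

    n_units: int = 192
    iso_slope: float = 1.2
    anchor: tuple[float, float] = (40.0, 1000.0 / 170.0)
    sigmoid_width: float = 0.15
    heterogeneity: float = 0.3
    spike_cap: int | None = 1
    poisson_mean: float = 2.0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be ≥ 1")
        if self.heterogeneity < 0 or self.sigmoid_width <= 0:
            raise ValueError("heterogeneity ≥ 0 and sigmoid_width > 0 required")

    def unit_offsets(self, seed: int) -> np.ndarray:
        """Per-unit threshold offsets; deterministic in the seed."""
        rng = np.random.default_rng(seed)
        return rng.normal(0.0, self.heterogeneity, self.n_units)

    def firing_probability(
        self, amplitude: float, width: float, offsets: np.ndarray
    ) -> np.ndarray:
        a0, w0 = self.anchor
        drive = np.log(amplitude / a0) - self.iso_slope * np.log(width / w0)
        return norm.cdf((drive - offsets) / self.sigmoid_width)


@dataclass
class SpikeEnsemble:
    """Population spike counts for repeated presentations of one stimulus."""

    per_pulse: np.ndarray  # (n_pulses, n_trials) population counts per pulse
    label: str = ""

    @property
    def per_trial(self) -> np.ndarray:
        """Global 500-ms counts: column sums over pulses."""
        return self.per_pulse.sum(axis=0)

    @property
    def pooled_pulses(self) -> np.ndarray:
        """Local read-out sample: all per-pulse counts pooled (pulses × trials)."""
        return self.per_pulse.ravel()


def simulate_ensemble(
    pop: ObserverPopulation,
    train: TrainSpec,
    n_trials: int = 100,
    seed: int = 0,
    label: str = "",
    offsets: np.ndarray | None = None,
) -> SpikeEnsemble:
    """Simulate population responses to ``n_trials`` presentations of a train.

    Each unit responds to each pulse independently; the per-pulse population
    count sums over units.  Identical inputs give identical ensembles.  Pass
    ``offsets`` to reuse one concrete unit population across several stimuli
    (as ``neurometric_curve`` does); by default they derive from the seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be ≥ 1")
    rng = np.random.default_rng(seed)
    if offsets is None:
        offsets = pop.unit_offsets(seed)
    p = pop.firing_probability(train.pulse.amplitude, train.pulse.width, offsets)
    n_pulses = train.n_pulses
    shape = (n_pulses, n_trials, pop.n_units)
    if pop.spike_cap == 1:
        spikes = rng.random(shape) < p
        counts = spikes.sum(axis=2)
    else:
        counts = rng.poisson(pop.poisson_mean * p, size=shape).sum(axis=2)
    return SpikeEnsemble(per_pulse=counts, label=label)


def auc(ref_sample, comp_sample) -> float:
    """Rank-based ROC area: P(comparison response > reference response),
    ties half-credited.

    Equivalent to the Mann–Whitney U statistic normalized by n_ref·n_comp.
    """
    ref = np.asarray(ref_sample, dtype=float).ravel()
    comp = np.asarray(comp_sample, dtype=float).ravel()
    if ref.size == 0 or comp.size == 0:
        raise ValueError("samples must be non-empty")
    ranks = rankdata(np.concatenate([ref, comp]))
    u = ranks[ref.size :].sum() - comp.size * (comp.size + 1) / 2.0
    return float(u / (ref.size * comp.size))


def discriminability(ref_sample, comp_sample) -> float:
    """d = 2·|AUC − 0.5| ∈ [0, 1]; 0 is chance, 1 is error-free in either order."""
    return 2.0 * abs(auc(ref_sample, comp_sample) - 0.5)


def neurometric_curve(
    pop: ObserverPopulation,
    isoline: IsoLine,
    mode: str = "local",
    n_trials: int = 100,
    seed: int = 0,
    comparison_rate: float | None = None,
    rate_levels=None,
) -> np.ndarray:
    """Discriminability of each comparison level against the iso-line anchor.

    ``mode="local"`` compares pooled per-pulse count samples; ``mode="global"``
    compares per-trial 500-ms counts.  If ``rate_levels`` is given the
    comparisons are rate changes (anchor pulse shape at each listed rate)
    instead of the iso-line's shape levels.
    """
    if mode not in ("local", "global"):
        raise ValueError("mode must be 'local' or 'global'")
    from .stimuli import PulseSpec

    a0, w0 = isoline.anchor
    offsets = pop.unit_offsets(seed)
    ref_train = TrainSpec(PulseSpec(a0, w0), isoline.rate)
    ref = simulate_ensemble(
        pop, ref_train, n_trials, seed, label="reference", offsets=offsets
    )

    if rate_levels is not None:
        comps = [TrainSpec(PulseSpec(a0, w0), float(r)) for r in rate_levels]
    else:
        rate = comparison_rate if comparison_rate is not None else isoline.rate
        comps = [
            TrainSpec(PulseSpec(a, w), rate)
            for a, w in zip(isoline.amplitudes, isoline.widths)
        ]

    out = np.empty(len(comps))
    for i, comp_train in enumerate(comps):
        comp = simulate_ensemble(pop, comp_train, n_trials, seed + 1 + i, offsets=offsets)
        if mode == "local":
            out[i] = discriminability(ref.pooled_pulses, comp.pooled_pulses)
        else:
            out[i] = discriminability(ref.per_trial, comp.per_trial)
    return out
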