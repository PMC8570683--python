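"""Synthetic experiments with known ground truth.

Generates the full study design — trial schedules matching the published
session layout (30 repetitions per change level in 3 blocks of 10, with an
equal number of no-change trials interleaved pseudo-randomly), simulated
participants whose yes/no behaviour follows the mixture cumulative-Gaussian
observer, and cohorts whose thresholds are Normal(μ, σ) draws, mirroring the
hierarchical model's own population assumption.  Every pipeline stage is
therefore testable end-to-end with recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psychometric import PsychModel, predict
from .stimuli import (
    RANGE_I,
    RATE_CHANGE_LEVELS,
    STIMULUS_RANGES,
    StimulusRange,
)

__all__ = [
    "SyntheticParticipant",
    "ExperimentDesign",
    "make_design",
    "simulate_responses",
    "make_cohort",
]

TRIALS_PER_LEVEL = 30
BLOCKS = 3


@dataclass(frozen=True)
class SyntheticParticipant:
    """Ground-truth observer: a PsychModel plus a response seed."""

    participant_id: str
    model: PsychModel
    seed: int


@dataclass(frozen=True)
class ExperimentDesign:
    """One session's trial schedule.

    ``levels`` are the change stimulus levels on the detection axis (Δw = w₀−w
    in ms for shape conditions; Δrate in Hz for the rate condition).  Each
    level appears ``TRIALS_PER_LEVEL`` times (10 per block × 3 blocks) and the
    session holds an equal total of no-change trials, shuffled within block
    under the order seed.
    """

    condition: str
    stimulus_range: str
    line: str
    levels: tuple[float, ...]
    order_seed: int = 0

    @property
    def n_change(self) -> int:
        return len(self.levels) * TRIALS_PER_LEVEL

    @property
    def n_no_change(self) -> int:
        return self.n_change

    def schedule(self) -> pd.DataFrame:
        """Per-trial rows: (block, trial, level_ms, is_change)."""
        rng = np.random.default_rng(self.order_seed)
        per_block_change = [(lv, True) for lv in self.levels for _ in range(TRIALS_PER_LEVEL // BLOCKS)]
        per_block_nochange = [(0.0, False)] * len(per_block_change)
        rows = []
        for b in range(BLOCKS):
            block = per_block_change + per_block_nochange
            order = rng.permutation(len(block))
            for t, i in enumerate(order):
                lv, chg = block[i]
                rows.append({"block": b, "trial": t, "level_ms": lv, "is_change": chg})
        return pd.DataFrame(rows)


def make_design(
    condition: str,
    stimulus_range: str = "I",
    line: str = "d",
    order_seed: int = 0,
) -> ExperimentDesign:
    """Build the published session design for a condition.

    Shape sessions in Range I have 14 change levels (420 change + 420
    no-change trials), Range II 10 levels (300 + 300); the rate session has 9
    levels (270 + 270).  The rate-and-shape sessions (d′, d′′) reuse the
    Range I shape grid.
    """
    if condition in ("shape", "rate_and_shape_dp", "rate_and_shape_dpp"):
        rng_: StimulusRange = STIMULUS_RANGES[stimulus_range]
        levels = tuple(rng_.ref_width - w for w in rng_.change_widths)
    elif condition == "rate":
        rng_ = RANGE_I
        levels = tuple(float(r - rng_.ref_rate) for r in RATE_CHANGE_LEVELS)
    else:
        raise KeyError(f"unknown condition {condition!r}")
    return ExperimentDesign(
        condition=condition,
        stimulus_range=rng_.name,
        line=line,
        levels=levels,
        order_seed=order_seed,
    )


def simulate_responses(
    participant: SyntheticParticipant, design: ExperimentDesign
) -> pd.DataFrame:
    """Simulate one session: yes with probability P(x) on change trials and γ
    on no-change trials; reproducible under the participant's seed.

    Returns the standard trial table (participant, condition, line, level_ms,
    is_change, response).
    """
    sched = design.schedule()
    rng = np.random.default_rng(participant.seed)
    m = participant.model
    p_yes = np.where(
        sched["is_change"].to_numpy(),
        predict(m, sched["level_ms"].to_numpy(float)),
        m.guess,
    )
    resp = (rng.random(len(sched)) < p_yes).astype(int)
    out = sched.copy()
    out.insert(0, "participant", participant.participant_id)
    out.insert(1, "condition", design.condition)
    out.insert(2, "line", design.line)
    out["response"] = resp
    return out[["participant", "condition", "line", "level_ms", "is_change", "response"]]


def make_cohort(
    n: int,
    mu: float,
    sigma: float,
    seed: int = 0,
    gamma_range: tuple[float, float] = (0.02, 0.18),
    delta_range: tuple[float, float] = (0.01, 0.08),
    width_range: tuple[float, float] = (0.2, 0.5),
    theta_bounds: tuple[float, float] = (0.05, 1.715),
) -> list[SyntheticParticipant]:
    """Draw a cohort: θ_i ~ Normal(μ, σ) truncated to ``theta_bounds`` and
    nuisance parameters uniform in their stated ranges.

    The γ range matches the span of false-alarm rates observed in the study
    (0.02–0.18); ψ widths of 0.2–0.5 ms give realistic session difficulty.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if sigma < 0:
        raise ValueError("σ must be ≥ 0")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        theta = rng.normal(mu, sigma) if sigma > 0 else mu
        while not (theta_bounds[0] <= theta <= theta_bounds[1]):
            theta = rng.normal(mu, sigma)
        model = PsychModel(
            threshold=float(theta),
            width=float(rng.uniform(*width_range)),
            guess=float(rng.uniform(*gamma_range)),
            lapse=float(rng.uniform(*delta_range)),
        )
        out.append(
            SyntheticParticipant(
                participant_id=f"S{i+1:02d}",
                model=model,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out
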