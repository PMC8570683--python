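"""Bayesian fitting of the yes/no change-detection psychometric function.

The observer model is a mixture cumulative Gaussian

    P(x) = γ + (1 − δ − γ) · Φ((x − θ) / σ_w)

where x is the stimulus level (here the pulse-width reduction Δw = w₀ − w in
ms, so detectability increases with x), θ is the threshold (the Gaussian mean,
where P crosses the midpoint between the false-alarm floor γ and the lapse
ceiling 1 − δ), and σ_w is the psychometric width.  No-change trials live at
x = 0, far below threshold, and chiefly inform γ.

Inference is by exhaustive grid evaluation: a binomial likelihood over a
4-D parameter grid with independent uniform priors, marginalized down to a
posterior density over θ (the "threshold PDF").  The participant's point
estimate is the mode of that marginal; ties on the grid break toward the
smallest level.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PsychModel",
    "ThresholdPDF",
    "GridSpec",
    "predict",
    "fit",
    "fa_correct",
]


@dataclass(frozen=True)
class PsychModel:
    """Mixture cumulative-Gaussian observer parameters."""

    threshold: float  # θ, stimulus-level units (ms of pulse-width reduction)
    width: float  # σ_w, same units
    guess: float = 0.0  # γ, false-alarm rate
    lapse: float = 0.0  # δ

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.guess < 0 or self.lapse < 0 or self.guess + self.lapse >= 1:
            raise ValueError("require 0 ≤ γ, 0 ≤ δ and γ + δ < 1")


def predict(model: PsychModel, x) -> float | np.ndarray:
    """Probability of a "yes" response at stimulus level ``x``.

    Monotone nondecreasing in x, bounded in [γ, 1 − δ].
    """
    x = np.asarray(x, dtype=float)
    p = model.guess + (1.0 - model.lapse - model.guess) * norm.cdf(
        (x - model.threshold) / model.width
    )
    return float(p) if p.ndim == 0 else p


def fa_correct(p_hat, guess: float, lapse: float = 0.0):
    """False-alarm correction: (p̂ − γ)/(1 − γ − δ), clipped to [0, 1]."""
    if guess + lapse >= 1:
        raise ValueError("γ + δ must be < 1")
    p_hat = np.asarray(p_hat, dtype=float)
    out = np.clip((p_hat - guess) / (1.0 - guess - lapse), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GridSpec:
    """Parameter grids for the posterior evaluation.

    θ is uniform over the tested level range; γ and δ uniform on [0, 0.3] and
    [0, 0.1] (brackets the observed false-alarm rates); σ_w log-spaced on
    [0.05, 3] ms.
    """

    theta_range: tuple[float, float]
    n_theta: int = 41
    sigma_range: tuple[float, float] = (0.05, 3.0)
    n_sigma: int = 25
    gamma_range: tuple[float, float] = (0.0, 0.3)
    n_gamma: int = 16
    delta_range: tuple[float, float] = (0.0, 0.1)
    n_delta: int = 11

    def axes(self):
        theta = np.linspace(*self.theta_range, self.n_theta)
        sigma = np.geomspace(*self.sigma_range, self.n_sigma)
        gamma = np.linspace(*self.gamma_range, self.n_gamma)
        delta = np.linspace(*self.delta_range, self.n_delta)
        return theta, sigma, gamma, delta


@dataclass
class ThresholdPDF:
    """Posterior density over the threshold θ on a stimulus-level grid."""

    grid: np.ndarray  # θ levels, ascending
    density: np.ndarray  # sums to 1
    mode: float
    ci95: tuple[float, float]
    estimates: dict = field(default_factory=dict)  # marginal-mode γ̂, δ̂, σ̂_w
    flagged: bool = False  # degenerate data / boundary mode
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "ci95": list(self.ci95),
            "estimates": self.estimates,
            "grid": self.grid.tolist(),
            "density": self.density.tolist(),
            "flagged": self.flagged,
            "message": self.message,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdPDF":
        return cls(
            grid=np.asarray(d["grid"], dtype=float),
            density=np.asarray(d["density"], dtype=float),
            mode=float(d["mode"]),
            ci95=tuple(d["ci95"]),
            estimates=dict(d.get("estimates", {})),
            flagged=bool(d.get("flagged", False)),
            message=str(d.get("message", "")),
        )


def _central_ci(grid: np.ndarray, density: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    cdf = np.cumsum(density)
    cdf /= cdf[-1]
    lo = float(np.interp((1 - mass) / 2, cdf, grid))
    hi = float(np.interp(1 - (1 - mass) / 2, cdf, grid))
    return lo, hi


@functools.lru_cache(maxsize=32)
def _log_predict_table(gridspec: GridSpec, levels: tuple[float, ...]):
    """log P and log(1−P) over the full parameter grid at each level.

    Shapes (nθ, nσ, nγ, nδ, n_levels).  Cached: the table depends only on the
    grid and the level set, not the data, so replicate fits reuse it.
    """
    theta, sigma, gamma, delta = gridspec.axes()
    x = np.asarray(levels)
    z = (x[None, None, :] - theta[:, None, None]) / sigma[None, :, None]
    core = norm.cdf(z)  # (nθ, nσ, L)
    g = gamma[:, None, None]  # (nγ, 1, 1) -> broadcast later
    d = delta[None, :, None]
    span = 1.0 - g - d  # (nγ, nδ, 1)
    # P has shape (nθ, nσ, nγ, nδ, L)
    p = g[None, None] + span[None, None] * core[:, :, None, None, :]
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p), np.log1p(-p)


def _aggregate(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse a trial table to per-level (x, n, k).  No-change trials map to x=0."""
    t = trials.copy()
    x = np.where(t["is_change"].astype(bool), t["level_ms"].astype(float), 0.0)
    t = pd.DataFrame({"x": x, "resp": t["response"].astype(int)})
    agg = t.groupby("x")["resp"].agg(["count", "sum"]).reset_index()
    return (
        agg["x"].to_numpy(float),
        agg["count"].to_numpy(float),
        agg["sum"].to_numpy(float),
    )


def fit(
    trials: pd.DataFrame,
    gridspec: GridSpec | None = None,
    theta_range: tuple[float, float] | None = None,
) -> ThresholdPDF:
    """Fit one participant/condition and return the threshold posterior.

    ``trials`` needs columns ``level_ms`` (stimulus level, Δw in ms),
    ``is_change`` and ``response`` (1 = "yes").  Requires at least two distinct
    levels.  Degenerate data (all-yes or all-no) produce a flagged result with
    a boundary mode rather than an exception.
    """
    x, n, k = _aggregate(trials)
    if x.size < 2:
        raise ValueError("need responses at ≥ 2 stimulus levels")
    if gridspec is None:
        if theta_range is None:
            change = x[x > 0]
            theta_range = (0.0, float(change.max()))
        gridspec = GridSpec(theta_range=theta_range)

    logp, log1mp = _log_predict_table(gridspec, tuple(x))
    loglik = logp @ k + log1mp @ (n - k)  # (nθ, nσ, nγ, nδ)

    post = np.exp(loglik - loglik.max())
    post /= post.sum()

    theta, sigma, gamma, delta = gridspec.axes()
    theta_marg = post.sum(axis=(1, 2, 3))
    theta_marg /= theta_marg.sum()
    i_mode = int(np.argmax(theta_marg))  # first max -> smallest level on ties

    sig_marg = post.sum(axis=(0, 2, 3))
    gam_marg = post.sum(axis=(0, 1, 3))
    del_marg = post.sum(axis=(0, 1, 2))
    estimates = {
        "sigma_w": float(sigma[np.argmax(sig_marg)]),
        "gamma": float(gamma[np.argmax(gam_marg)]),
        "delta": float(delta[np.argmax(del_marg)]),
    }

    flagged = False
    message = ""
    if k.sum() == 0 or k.sum() == n.sum():
        flagged = True
        message = "degenerate data: all responses identical"
    elif i_mode in (0, theta.size - 1):
        flagged = True
        message = "threshold mode at grid boundary"

    return ThresholdPDF(
        grid=theta,
        density=theta_marg,
        mode=float(theta[i_mode]),
        ci95=_central_ci(theta, theta_marg),
        estimates=estimates,
        flagged=flagged,
        message=message,
    )
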