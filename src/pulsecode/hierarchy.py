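"""Two-level Bayesian aggregation of per-participant threshold posteriors.

Participant thresholds are modelled as draws from a Normal(μ, σ) population,
truncated to the tested stimulus range.  For each candidate (μ, σ) the
participant's evidence is

    p(d_i | μ, σ) = ∫ p(d_i | θ) · p(θ | μ, σ) dθ,

evaluated numerically on the θ grid; because the per-participant prior over θ
is uniform on that range, the participant's threshold PDF is proportional to
p(d_i | θ).  The population density p(θ | μ, σ) is the plain Normal density —
the integral is merely restricted to the tested range, it is not a
renormalized truncated distribution.  That distinction matters: renormalizing
inflates the evidence for μ near the range boundary (the lost tail mass is
handed back to the interior) and drags the posterior mode to the edge,
whereas the restricted plain density correctly penalizes population means
whose mass falls outside the tested range.

The cohort likelihood is the product over participants on a (μ, σ) grid with
a uniform prior on the box (σ spanning 0.5–30 ms), and the population
estimate is the mode of the σ-marginalized μ posterior with its 95% credible
interval (central by default; highest-density optional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .psychometric import ThresholdPDF, _central_ci

__all__ = ["PopulationPosterior", "participant_likelihood", "population_posterior"]


@dataclass
class PopulationPosterior:
    """Posterior over the population mean threshold μ (and SD σ)."""

    mu_grid: np.ndarray
    sigma_grid: np.ndarray
    joint: np.ndarray  # (nμ, nσ), sums to 1
    mu_marginal: np.ndarray  # sums to 1
    mode: float
    ci95: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "ci95": list(self.ci95),
            "mu_grid": self.mu_grid.tolist(),
            "mu_marginal": self.mu_marginal.tolist(),
            "sigma_grid": self.sigma_grid.tolist(),
        }


def _normal_weights(theta: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Normal(θ; μ, σ) density on the θ grid, shape (nμ, nσ, nθ).

    Deliberately not renormalized over the grid: the hierarchical integral runs
    only over the tested stimulus range, so mass outside it is simply lost.
    """
    sig = sigma[None, :, None]
    z = (theta[None, None, :] - mu[:, None, None]) / sig
    return norm.pdf(z) / sig


def participant_likelihood(
    threshold_pdf: ThresholdPDF, mu, sigma
) -> float | np.ndarray:
    """p(d_i | μ, σ) up to the participant-specific constant.

    Numeric integral over the θ grid of the participant's threshold density
    times the Normal(μ, σ) population density, restricted to the grid range.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    if np.any(sigma <= 0):
        raise ValueError("σ must be positive")
    w = _normal_weights(threshold_pdf.grid, mu, sigma)
    out = w @ threshold_pdf.density
    return float(out[0, 0]) if out.size == 1 else np.squeeze(out)


def population_posterior(
    threshold_pdfs: list[ThresholdPDF],
    n_mu: int = 121,
    sigma_range: tuple[float, float] = (0.5, 30.0),
    n_sigma: int = 60,
    interval: str = "central",
) -> PopulationPosterior:
    """Pool participants into a posterior over the population mean threshold.

    μ runs over the participants' θ grid (``n_mu`` points); σ is log-spaced
    over ``sigma_range``.  ``interval`` selects the 95% credible interval
    flavour: "central" or "hdi".
    """
    if not threshold_pdfs:
        raise ValueError("need at least one participant")
    theta = threshold_pdfs[0].grid
    for pdf in threshold_pdfs[1:]:
        if not np.allclose(pdf.grid, theta):
            raise ValueError("all participants must share the same θ grid")

    mu = np.linspace(theta[0], theta[-1], n_mu)
    sigma = np.geomspace(*sigma_range, n_sigma)
    w = _normal_weights(theta, mu, sigma)  # (nμ, nσ, nθ)

    dens = np.stack([pdf.density for pdf in threshold_pdfs])  # (P, nθ)
    lik = np.einsum("msk,pk->pms", w, dens)
    loglik = np.sum(np.log(np.clip(lik, 1e-300, None)), axis=0)  # (nμ, nσ)

    joint = np.exp(loglik - loglik.max())
    joint /= joint.sum()
    mu_marg = joint.sum(axis=1)
    mu_marg /= mu_marg.sum()
    i_mode = int(np.argmax(mu_marg))

    if interval == "central":
        ci = _central_ci(mu, mu_marg)
    elif interval == "hdi":
        ci = _hdi(mu, mu_marg)
    else:
        raise ValueError("interval must be 'central' or 'hdi'")

    return PopulationPosterior(
        mu_grid=mu,
        sigma_grid=sigma,
        joint=joint,
        mu_marginal=mu_marg,
        mode=float(mu[i_mode]),
        ci95=ci,
    )


def _hdi(grid: np.ndarray, density: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval on a discrete grid (smallest covering set)."""
    order = np.argsort(density)[::-1]
    cum = np.cumsum(density[order])
    keep = order[: int(np.searchsorted(cum, mass)) + 1]
    return float(grid[keep].min()), float(grid[keep].max())
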