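"""Conjugate Bayesian ideal learner over log-ratio series.

The learner assumes the log-ratios r_s of adjacent interval durations
are iid Normal(μ, σ²) with a Normal–Inverse-χ² prior over (μ, σ²).  The
uninformative default prior (κ₀ = 0, ν₀ = −1, prior scale 0, arbitrary
μ₀) makes MAP estimates coincide with maximum likelihood, and gives the
posterior predictive for a new log-ratio the Student-t form

    r_new | R  ~  t_{n−1}(r̄, s²),   s² = (1 + n)·Σ(r_i − r̄)² / (n(n−1)),

whose differential entropy (in nats) is the predictability score: low
entropy means an observer who has internalized the distribution can
predict the next relative duration well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from speechtiming.series import LogRatioSeries

__all__ = [
    "PriorSpec",
    "Posterior",
    "PredictiveT",
    "LearnerError",
    "fit_posterior",
    "posterior_predictive",
    "differential_entropy",
    "gaussian_entropy",
    "sample_predictions",
]


class LearnerError(ValueError):
    """Raised for degenerate or insufficient data."""


@dataclass(frozen=True)
class PriorSpec:
    """Normal–Inverse-χ² prior hyperparameters.

    ``scale0`` is the ν₀σ₀² product (sum-of-squares scale); the default
    (mu0 arbitrary, kappa0=0, nu0=−1, scale0=0) is the uninformative
    setting under which the posterior point estimates equal the ML
    estimates.
    """

    mu0: float = 0.0
    kappa0: float = 0.0
    nu0: float = -1.0
    scale0: float = 0.0


@dataclass(frozen=True)
class Posterior:
    """Posterior over (μ, σ²) after observing n log-ratios."""

    n: int
    rbar: float
    ssd: float
    mu_n: float
    kappa_n: float
    nu_n: float
    scale_n: float

    @property
    def mu_hat(self) -> float:
        """MAP / ML location estimate (equal under the default prior)."""
        return self.mu_n

    @property
    def sigma2_hat(self) -> float:
        """ML variance estimate, Σ(r−r̄)²/n."""
        return self.ssd / self.n

    @property
    def sigma2_unbiased(self) -> float:
        """Unbiased variance estimate, Σ(r−r̄)²/(n−1)."""
        return self.ssd / (self.n - 1)

    @property
    def degenerate(self) -> bool:
        """All observations identical: no spread to learn from."""
        return self.scale_n <= 0


@dataclass(frozen=True)
class PredictiveT:
    """Student-t posterior predictive; ``scale2`` is the squared scale."""

    df: float
    loc: float
    scale2: float

    @property
    def scale(self) -> float:
        return float(np.sqrt(self.scale2))

    def pdf(self, x: np.ndarray | float) -> np.ndarray | float:
        return stats.t.pdf(x, df=self.df, loc=self.loc, scale=self.scale)

    def cdf(self, x: np.ndarray | float) -> np.ndarray | float:
        return stats.t.cdf(x, df=self.df, loc=self.loc, scale=self.scale)


def _present(r: LogRatioSeries | np.ndarray) -> np.ndarray:
    x = r.r if isinstance(r, LogRatioSeries) else np.asarray(r, dtype=float)
    return x[np.isfinite(x)]


def fit_posterior(
    r: LogRatioSeries | np.ndarray, prior: PriorSpec = PriorSpec()
) -> Posterior:
    """Conjugate Normal–Inverse-χ² update on the present log-ratios."""
    x = _present(r)
    n = len(x)
    if n < 2:
        raise LearnerError(f"need >= 2 present log-ratios, got {n}")
    rbar = float(np.mean(x))
    ssd = float(np.sum((x - rbar) ** 2))
    kappa_n = prior.kappa0 + n
    nu_n = prior.nu0 + n
    mu_n = (prior.kappa0 * prior.mu0 + n * rbar) / kappa_n
    scale_n = (
        prior.scale0 + ssd + (prior.kappa0 * n / kappa_n) * (rbar - prior.mu0) ** 2
    )
    return Posterior(
        n=n,
        rbar=rbar,
        ssd=ssd,
        mu_n=float(mu_n),
        kappa_n=float(kappa_n),
        nu_n=float(nu_n),
        scale_n=float(scale_n),
    )


def posterior_predictive(p: Posterior) -> PredictiveT:
    """Student-t predictive for the next log-ratio.

    General form t_{ν_n}(μ_n, scale_n·(κ_n + 1)/(κ_n·ν_n)); under the
    default prior this is t_{n−1}(r̄, (1+n)·ssd/(n(n−1))).
    """
    if p.degenerate:
        raise LearnerError("degenerate posterior: all observations identical")
    scale2 = p.scale_n * (p.kappa_n + 1.0) / (p.kappa_n * p.nu_n)
    return PredictiveT(df=p.nu_n, loc=p.mu_n, scale2=float(scale2))


def differential_entropy(t: PredictiveT) -> float:
    """Differential entropy h = −∫ p ln p of the predictive, in nats.

    Closed form for a location-scale Student-t with ν degrees of freedom
    and squared scale s²:

        h = ½ ln s² + (ν+1)/2 · [ψ((ν+1)/2) − ψ(ν/2)] + ln(√ν · B(ν/2, ½)).
    """
    if t.scale2 <= 0:
        raise LearnerError("entropy undefined for nonpositive squared scale")
    nu = t.df
    h_std = (
        (nu + 1.0) / 2.0 * (special.digamma((nu + 1.0) / 2.0) - special.digamma(nu / 2.0))
        + np.log(np.sqrt(nu) * special.beta(nu / 2.0, 0.5))
    )
    return float(h_std + 0.5 * np.log(t.scale2))


def gaussian_entropy(variance: float) -> float:
    """Differential entropy ½·ln(2πe·v) of a normal with variance v;
    the large-n limit of the Student-t predictive's entropy."""
    if variance <= 0:
        raise LearnerError("entropy undefined for nonpositive variance")
    return float(0.5 * np.log(2.0 * np.pi * np.e * variance))


def sample_predictions(p: Posterior, n_draws: int, seed: int) -> np.ndarray:
    """Forward-sample the learner's predictions.

    Each draw samples (μ, σ²) from the posterior — σ² as scale_n/χ²_{ν_n},
    μ ~ Normal(μ_n, σ²/κ_n) — then a prediction r_new ~ Normal(μ, σ²).
    The empirical distribution of the draws converges to the closed-form
    Student-t predictive.
    """
    if n_draws <= 0:
        raise LearnerError(f"n_draws must be positive, got {n_draws}")
    if p.degenerate:
        raise LearnerError("degenerate posterior: all observations identical")
    rng = np.random.default_rng(seed)
    sigma2 = p.scale_n / rng.chisquare(p.nu_n, size=n_draws)
    mu = rng.normal(p.mu_n, np.sqrt(sigma2 / p.kappa_n))
    return rng.normal(mu, np.sqrt(sigma2))
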