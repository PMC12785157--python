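"""Relaxed-clock rate model: gamma hyperpriors and lognormal branch rates.

The locus mean rate mu_r (substitutions/site/100 Ma) carries a gamma prior
("rgene_gamma"); the variance of log branch rates sigma^2 carries its own
gamma prior ("sigma2_gamma").  Branch rates are i.i.d. lognormal with
E[rate] = mu_r and Var[log rate] = sigma^2, i.e.
log rate ~ Normal(log mu_r - sigma^2/2, sigma^2).

Gamma parameters are shape/rate (mean = a/b): the derivation a = (m/s)^2,
b = m/s^2 from a target mean m and standard deviation s is only consistent
with the rate parameterisation (m = 0.03 = s gives a = 1, b ~ 33.33,
mean a/b = 0.03).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GammaSpec:
    """Gamma prior with shape ``a`` and rate ``b`` (mean a/b, SD sqrt(a)/b)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("gamma shape and rate must be positive")

    @property
    def mean(self) -> float:
        return self.a / self.b

    @property
    def sd(self) -> float:
        return math.sqrt(self.a) / self.b

    def log_pdf(self, x: float) -> float:
        if x <= 0:
            return -math.inf
        return (self.a * math.log(self.b) - math.lgamma(self.a)
                + (self.a - 1.0) * math.log(x) - self.b * x)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.a, 1.0 / self.b, size=size)


def gamma_from_mean_sd(m: float, s: float) -> GammaSpec:
    """Gamma spec with prior mean ``m`` and SD ``s``: a=(m/s)^2, b=m/s^2."""
    if m <= 0 or s <= 0:
        raise ValueError("mean and SD must be positive")
    return GammaSpec(a=(m / s) ** 2, b=m / s ** 2)


@dataclass(frozen=True)
class ClockHyperParams:
    """Priors for the locus mean rate and the log-rate variance."""

    rgene: GammaSpec
    sigma2: GammaSpec


# The standard hyperpriors: locus rate Gamma(1, 33.3333) (mean 0.03
# substitutions/site/100 Ma); log-rate variance Gamma(1, 10) (mean 0.1),
# raised to Gamma(10, 10) (mean 1) under the high-heterogeneity strategy B4.
RGENE_DEFAULT = gamma_from_mean_sd(0.03, 0.03)
SIGMA2_DEFAULT = GammaSpec(1.0, 10.0)
SIGMA2_HIGH_HET = GammaSpec(10.0, 10.0)


def default_hyperpriors(strategy: str = "A1") -> ClockHyperParams:
    """Clock hyperpriors for a named calibration strategy (A1..B4)."""
    strategy = strategy.upper()
    if strategy not in {"A1", "A2", "A3", "B1", "B2", "B3", "B4"}:
        raise ValueError(f"unknown strategy {strategy!r}")
    sigma2 = SIGMA2_HIGH_HET if strategy == "B4" else SIGMA2_DEFAULT
    return ClockHyperParams(rgene=RGENE_DEFAULT, sigma2=sigma2)


def lognormal_rate_log_pdf(rate: float, mu_r: float, sigma2: float) -> float:
    """Log-density of one branch rate under the mean-corrected lognormal.

    E[rate] = mu_r, Var[log rate] = sigma2.  The sigma2 -> 0 limit is a
    point mass at mu_r (log-density -inf away from it).
    """
    if rate <= 0 or mu_r <= 0:
        return -math.inf
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    if sigma2 == 0:
        return math.inf if rate == mu_r else -math.inf
    z = math.log(rate) - (math.log(mu_r) - 0.5 * sigma2)
    return (-LOG_SQRT_2PI - 0.5 * math.log(sigma2) - math.log(rate)
            - 0.5 * z * z / sigma2)


def branch_rate_log_prior(rates: np.ndarray, mu_r: float,
                          sigma2: float) -> float:
    """Sum of independent lognormal log-densities over branch rates."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        return -math.inf
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    if sigma2 == 0:
        return math.inf if np.allclose(rates, mu_r) else -math.inf
    z = np.log(rates) - (math.log(mu_r) - 0.5 * sigma2)
    return float(np.sum(-LOG_SQRT_2PI - 0.5 * math.log(sigma2)
                        - np.log(rates) - 0.5 * z * z / sigma2))


def sample_branch_rates(n: int, mu_r: float, sigma2: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw i.i.d. branch rates with E[rate]=mu_r, Var[log rate]=sigma2."""
    if sigma2 == 0:
        return np.full(n, mu_r)
    return rng.lognormal(math.log(mu_r) - 0.5 * sigma2,
                         math.sqrt(sigma2), size=n)
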