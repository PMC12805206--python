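"""Prior densities for the two-group ordinal MRF.

* Overall thresholds: independent beta-prime distributions on the
  exponentiated thresholds, ``exp(mu) ~ BetaPrime(a, b)``.  On the log-odds
  scale this is ``a*mu - (a+b)*log(1+exp(mu)) - log B(a,b)`` (for a=b=1, the
  standard logistic density).
* Overall interactions: Cauchy slab with a wide scale.
* Difference parameters: Cauchy slab (when included) or an exact point mass
  at zero (when excluded) — a spike-and-slab mixture governed by binary
  inclusion indicators.
* Indicators: either independent Bernoulli(pi), under which every
  configuration of differences is a-priori equally likely when pi=1/2, or a
  beta-Bernoulli prior that places a Beta(alpha, beta) hyperprior on the
  inclusion probability; with alpha=beta=1 the implied distribution of the
  *number* of included differences is uniform, which corrects for
  multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.special import betaln, gammaln

__all__ = [
    "BernoulliPrior",
    "BetaBernoulliPrior",
    "PriorConfig",
    "log_threshold_prior",
    "log_cauchy",
    "log_indicator_prior",
    "single_indicator_prior_odds",
    "conditional_log_prior_odds",
]


@dataclass(frozen=True)
class BernoulliPrior:
    """Independent Bernoulli(pi) on each inclusion indicator."""

    pi: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.pi < 1.0):
            raise ValueError("pi must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class BetaBernoulliPrior:
    """Beta(alpha, beta) hyperprior on a shared inclusion probability."""

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


IndicatorPrior = Union[BernoulliPrior, BetaBernoulliPrior]


@dataclass
class PriorConfig:
    """All prior hyperparameters, with package defaults.

    difference_scale is shared by threshold- and interaction-difference slabs
    unless ``threshold_difference_scale`` overrides it.
    """

    threshold_shape_a: float = 1.0
    threshold_shape_b: float = 1.0
    overall_interaction_scale: float = 2.5
    difference_scale: float = 1.0
    threshold_difference_scale: float = None
    threshold_indicator_prior: IndicatorPrior = field(default_factory=BernoulliPrior)
    interaction_indicator_prior: IndicatorPrior = field(default_factory=BernoulliPrior)

    def __post_init__(self):
        for name in ("threshold_shape_a", "threshold_shape_b",
                     "overall_interaction_scale", "difference_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.threshold_difference_scale is None:
            self.threshold_difference_scale = self.difference_scale
        elif self.threshold_difference_scale <= 0:
            raise ValueError("threshold_difference_scale must be positive")

    def to_dict(self) -> dict:
        def _ip(p):
            if isinstance(p, BernoulliPrior):
                return {"type": "Bernoulli", "pi": p.pi}
            return {"type": "BetaBernoulli", "alpha": p.alpha, "beta": p.beta}

        return {
            "threshold_shape_a": self.threshold_shape_a,
            "threshold_shape_b": self.threshold_shape_b,
            "overall_interaction_scale": self.overall_interaction_scale,
            "difference_scale": self.difference_scale,
            "threshold_difference_scale": self.threshold_difference_scale,
            "threshold_indicator_prior": _ip(self.threshold_indicator_prior),
            "interaction_indicator_prior": _ip(self.interaction_indicator_prior),
        }


def log_threshold_prior(mu, a: float, b: float):
    """Log-density of a threshold whose exponential is BetaPrime(a, b).

    Change of variables from ``y = exp(mu) ~ BetaPrime(a, b)`` gives
    ``a*mu - (a+b)*log(1+exp(mu)) - log B(a, b)``; the ``log1p(exp(mu))``
    term is evaluated stably via softplus for |mu| up to ~700.
    """
    if a <= 0 or b <= 0:
        raise ValueError("beta-prime shapes must be positive")
    mu = np.asarray(mu, dtype=float)
    softplus = np.where(mu > 0, mu + np.log1p(np.exp(-np.abs(mu))),
                        np.log1p(np.exp(-np.abs(mu))))
    out = a * mu - (a + b) * softplus - betaln(a, b)
    return float(out) if out.ndim == 0 else out


def log_cauchy(x, scale: float):
    """Log-density of a centered Cauchy with the given scale."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    x = np.asarray(x, dtype=float)
    out = -np.log(np.pi * scale) - np.log1p((x / scale) ** 2)
    return float(out) if out.ndim == 0 else out


def log_indicator_prior(indicators, prior: IndicatorPrior) -> float:
    """Log prior mass of a full indicator configuration.

    Bernoulli: ``k log pi + (K-k) log(1-pi)``.  Beta-Bernoulli (indicators
    exchangeable given the latent inclusion probability):
    ``log B(alpha+k, beta+K-k) - log B(alpha, beta)``.
    """
    g = np.asarray(indicators, dtype=np.int64).ravel()
    if g.size < 1:
        raise ValueError("need at least one indicator")
    if np.any((g != 0) & (g != 1)):
        raise ValueError("indicators must be binary")
    k = int(g.sum())
    K = g.size
    if isinstance(prior, BernoulliPrior):
        return k * np.log(prior.pi) + (K - k) * np.log1p(-prior.pi)
    if isinstance(prior, BetaBernoulliPrior):
        return float(betaln(prior.alpha + k, prior.beta + K - k)
                     - betaln(prior.alpha, prior.beta))
    raise TypeError(f"unknown indicator prior: {prior!r}")


def single_indicator_prior_odds(prior: IndicatorPrior) -> float:
    """Marginal prior odds P(gamma=1)/P(gamma=0) of a single indicator.

    Under the beta-Bernoulli prior the marginal inclusion probability of any
    one indicator is alpha/(alpha+beta), hence odds alpha/beta.
    """
    if isinstance(prior, BernoulliPrior):
        return prior.pi / (1.0 - prior.pi)
    if isinstance(prior, BetaBernoulliPrior):
        return prior.alpha / prior.beta
    raise TypeError(f"unknown indicator prior: {prior!r}")


def conditional_log_prior_odds(prior: IndicatorPrior, k_other: int, K: int) -> float:
    """Log odds of including one indicator given the rest of its family.

    ``k_other`` counts included indicators among the other ``K - 1``.  For
    Bernoulli priors the indicators are independent so the conditioning is
    irrelevant; for beta-Bernoulli the odds are (alpha+k_other)/(beta+K-1-k_other),
    which is how the prior adapts to the number of already-included effects.
    """
    if isinstance(prior, BernoulliPrior):
        return float(np.log(prior.pi) - np.log1p(-prior.pi))
    if isinstance(prior, BetaBernoulliPrior):
        return float(np.log(prior.alpha + k_other)
                     - np.log(prior.beta + K - 1 - k_other))
    raise TypeError(f"unknown indicator prior: {prior!r}")
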