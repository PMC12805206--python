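"""Posterior summaries: inclusion probabilities, Bayes factors, intervals.

The inclusion Bayes factor for a difference indicator gamma is the ratio of
posterior to prior odds of gamma = 1,

    BF_10 = [ pip / (1 - pip) ] / prior_odds,

where pip is the posterior inclusion probability (the posterior mean of the
indicator, estimated by the fraction of MCMC draws with gamma = 1).  BF_10
quantifies evidence for a group difference; its reciprocal BF_01 quantifies
evidence for parameter equivalence — the Bayes factor can support the null.
Under a Bernoulli(1/2) prior the prior odds are one and the Bayes factor
equals the posterior odds.

Chains whose pip is exactly 0 or 1 only bound the Bayes factor; such values
are clamped to 1/(2T) from the boundary and flagged, so an infinite BF is
never reported silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .priors import PriorConfig, single_indicator_prior_odds
from .sampler import PosteriorDraws

__all__ = [
    "InferenceSummary",
    "posterior_inclusion_probability",
    "inclusion_bayes_factor",
    "summarize_parameters",
]

#: Minimum number of included draws before conditional summaries are reported.
MIN_CONDITIONAL_DRAWS = 10


def posterior_inclusion_probability(indicator_draws) -> float:
    """Posterior mean of a binary indicator chain."""
    g = np.asarray(indicator_draws)
    if g.size == 0:
        raise ValueError("empty indicator chain")
    return float(g.mean())


def inclusion_bayes_factor(pip: float, prior_odds: float, T: int):
    """Inclusion Bayes factor BF_10 from a pip and the prior odds.

    Returns ``(bf, is_bound)``; degenerate pips (0 or 1) are clamped to
    ``1/(2T)`` from the boundary and flagged as a bound on the true BF.
    """
    if not (0.0 <= pip <= 1.0):
        raise ValueError("pip must be in [0, 1]")
    if prior_odds <= 0:
        raise ValueError("prior_odds must be positive")
    if T < 1:
        raise ValueError("T must be >= 1")
    is_bound = pip in (0.0, 1.0)
    eps = 1.0 / (2.0 * T)
    pip_c = min(max(pip, eps), 1.0 - eps)
    return (pip_c / (1.0 - pip_c)) / prior_odds, is_bound


def _summary_row(chain: np.ndarray) -> dict:
    q = np.quantile(chain, [0.025, 0.975])  # type-7 interpolation (default)
    return {
        "mean": float(chain.mean()),
        "sd": float(chain.std(ddof=1)) if chain.size > 1 else 0.0,
        "lower": float(q[0]),
        "upper": float(q[1]),
    }


@dataclass
class InferenceSummary:
    """Tabular posterior summary plus run metadata."""

    effects: pd.DataFrame  # one row per parameter / tested effect
    meta: dict

    def to_json_dict(self) -> dict:
        return {"meta": self.meta,
                "effects": self.effects.to_dict(orient="records")}


def _effect_rows(name_fmt, index, chains, indicators, prior_odds, T):
    """Rows for tested difference effects (model-averaged + conditional)."""
    rows = []
    for k, idx in enumerate(index):
        chain = chains[:, k]
        row = {"effect": name_fmt(idx), "type": name_fmt.__name__}
        if indicators is not None:
            g = indicators[:, k]
            pip = posterior_inclusion_probability(g)
            bf, bound = inclusion_bayes_factor(pip, prior_odds, T)
            row.update(pip=pip, bf_10=bf, bf_bound=bound)
            row.update({f"avg_{k2}": v for k2, v in _summary_row(chain).items()})
            inc = chain[g == 1]
            if inc.size >= MIN_CONDITIONAL_DRAWS:
                row.update({f"cond_{k2}": v
                            for k2, v in _summary_row(inc).items()})
            else:
                row.update(cond_mean=np.nan, cond_sd=np.nan,
                           cond_lower=np.nan, cond_upper=np.nan)
        else:
            row.update(pip=np.nan, bf_10=np.nan, bf_bound=False)
            row.update({f"avg_{k2}": v for k2, v in _summary_row(chain).items()})
            row.update(cond_mean=np.nan, cond_sd=np.nan,
                       cond_lower=np.nan, cond_upper=np.nan)
        rows.append(row)
    return rows


def summarize_parameters(draws: PosteriorDraws,
                         priors: PriorConfig = None) -> InferenceSummary:
    """Full posterior summary of a sampler run.

    Difference effects get posterior inclusion probabilities and inclusion
    Bayes factors (when indicators were sampled); every parameter gets
    model-averaged mean/sd/95% interval, and tested effects additionally get
    summaries conditional on inclusion (omitted when the effect was included
    in fewer than ``MIN_CONDITIONAL_DRAWS`` draws).
    """
    if draws.n_draws == 0:
        raise ValueError("empty draws")
    if priors is None:
        priors = PriorConfig()
    T = draws.n_draws
    rows = []

    def interaction(idx):
        return f"sigma[{idx[0]},{idx[1]}]"

    def delta_interaction(idx):
        return f"delta_sigma[{idx[0]},{idx[1]}]"

    def threshold(idx):
        return f"mu[{idx[0]},{idx[1] + 1}]"

    def delta_threshold(idx):
        return f"delta_mu[{idx[0]},{idx[1] + 1}]"

    rows += _effect_rows(interaction, draws.pair_index,
                         draws.overall_interactions, None, 1.0, T)
    po_int = single_indicator_prior_odds(priors.interaction_indicator_prior)
    # per-pair interaction-difference indicators attach to scalar chains
    if draws.interaction_indicators is not None:
        ind = draws.interaction_indicators
    else:
        ind = None
    rows += _effect_rows(delta_interaction, draws.pair_index,
                         draws.interaction_diffs, ind, po_int, T)

    if draws.overall_thresholds is not None:
        rows += _effect_rows(threshold, draws.threshold_index,
                             draws.overall_thresholds, None, 1.0, T)
        po_thr = single_indicator_prior_odds(priors.threshold_indicator_prior)
        if draws.threshold_indicators is not None:
            # the indicator is per variable; expand to the vector components
            var_of = np.array([i for i, _ in draws.threshold_index])
            ind_thr = draws.threshold_indicators[:, var_of]
        else:
            ind_thr = None
        rows += _effect_rows(delta_threshold, draws.threshold_index,
                             draws.threshold_diffs, ind_thr, po_thr, T)
    else:
        idx1, idx2 = draws.threshold_index
        rows += _effect_rows(lambda i: f"mu_g1[{i[0]},{i[1] + 1}]", idx1,
                             draws.group1_thresholds, None, 1.0, T)
        rows += _effect_rows(lambda i: f"mu_g2[{i[0]},{i[1] + 1}]", idx2,
                             draws.group2_thresholds, None, 1.0, T)

    df = pd.DataFrame(rows)
    df = df.drop(columns=["type"])
    return InferenceSummary(effects=df, meta=dict(draws.meta))
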