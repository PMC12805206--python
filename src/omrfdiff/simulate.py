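"""Synthetic two-group OMRF truth models and data.

The generator emulates a psychometric simulation design: an overall network
whose nonzero pairwise interactions are drawn from a right-skewed, mostly
positive pool (questionnaire networks are dominated by weak positive
partial associations), 4-point Likert-style marginals, a configurable edge
density (each potential interaction retained independently with probability
``density``), and a configurable proportion of pairs that truly differ
between groups, with difference magnitudes drawn from a two-sided uniform
mixture ``+/- U(diff_low, diff_high)`` (equal probability of either sign).
Group models carry half the difference each, so the overall model is the
average of the two groups.

Because extreme marginal distributions make group differences undetectable
(and can starve a category of observations entirely), a safeguard resamples
the whole process — truth and data — until the second-most frequent category
of every variable in both groups reaches a minimum count.

The empirical interaction pool the design is calibrated against in applied
work is not bundled; the default pool is a shifted-gamma surrogate chosen to
be right-skewed with mostly small positive values, and any empirical vector
can be supplied instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .model import (ENUMERATION_GUARD, GroupModel, OrdinalDataset,
                    category_probabilities, enumerate_joint_pmf)
from .two_group import DifferenceModel, TwoGroupModel, derive_group_model

__all__ = [
    "TruthConfig",
    "sample_dataset",
    "generate_truth",
    "recenter_thresholds",
    "apply_marginal_safeguard",
    "run_simulation_cell",
]


@dataclass
class TruthConfig:
    """Design of the data-generating truth.

    ``diff_low``/``diff_high`` bound the magnitude of true group differences;
    they are mandatory design choices of any simulation (defaults 0.1/0.5).
    ``interaction_pool``/``threshold_pool`` may supply empirical parameter
    vectors; otherwise parametric surrogates are used (shifted gamma for
    interactions, Gaussian for thresholds).
    """

    p: int = 6
    n_categories: int = 4
    density: float = 0.15
    prop_diff: float = 0.0
    diff_low: float = 0.1
    diff_high: float = 0.5
    interaction_pool: Optional[np.ndarray] = None
    interaction_gamma_shape: float = 2.0
    interaction_gamma_scale: float = 0.1
    interaction_loc: float = -0.05
    threshold_pool: Optional[np.ndarray] = None
    threshold_loc: float = 0.0
    threshold_scale: float = 0.5
    min_second_category_count: int = 10
    recenter: bool = True
    seed: Optional[int] = None

    def __post_init__(self):
        if self.p < 2:
            raise ValueError("need at least two variables")
        if not (0.0 <= self.density <= 1.0):
            raise ValueError("density must lie in [0, 1]")
        if not (0.0 <= self.prop_diff <= 1.0):
            raise ValueError("prop_diff must lie in [0, 1]")
        if not (0.0 < self.diff_low < self.diff_high):
            raise ValueError("require 0 < diff_low < diff_high")
        if np.isscalar(self.n_categories):
            self.n_categories = np.full(self.p, int(self.n_categories),
                                        dtype=np.int64)
        else:
            self.n_categories = np.asarray(self.n_categories, dtype=np.int64)
        if np.any(self.n_categories < 2):
            raise ValueError("every variable needs at least 2 categories")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["n_categories"] = self.n_categories.tolist()
        for k in ("interaction_pool", "threshold_pool"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        return d


def sample_dataset(model: GroupModel, n: int, method: str = "exact",
                   rng: np.random.Generator = None,
                   gibbs_sweeps: int = 1000) -> OrdinalDataset:
    """Draw ``n`` i.i.d. rows from an OMRF.

    ``exact`` inverts the enumerated joint pmf (small networks only);
    ``gibbs`` runs single-site Gibbs sweeps per row from a uniform random
    start (rows vectorized; one sweep updates every variable once).
    """
    rng = np.random.default_rng(rng)
    ncat = model.n_categories
    p = model.n_variables
    if method == "exact":
        try:
            table = enumerate_joint_pmf(model)
        except Exception as err:
            raise type(err)(f"{err}; use method='gibbs' instead") from err
        idx = rng.choice(table.states.shape[0], size=n, p=table.probabilities)
        X = table.states[idx]
    elif method == "gibbs":
        X = np.stack([rng.integers(0, m, size=n) for m in ncat], axis=1)
        sig = model.interactions
        for _ in range(gibbs_sweeps):
            for i in range(p):
                rest = X @ sig[:, i] - sig[i, i] * X[:, i]
                mu = np.concatenate(([0.0], model.thresholds[i]))
                E = mu[None, :] + np.outer(rest, np.arange(mu.size))
                E -= E.max(axis=1, keepdims=True)
                P = np.exp(E)
                P /= P.sum(axis=1, keepdims=True)
                X[:, i] = (P.cumsum(axis=1) < rng.random((n, 1))).sum(axis=1)
    else:
        raise ValueError("method must be 'exact' or 'gibbs'")
    return OrdinalDataset(responses=np.asarray(X, dtype=np.int64),
                          n_categories=ncat)


def recenter_thresholds(model: GroupModel, target_marginals: list,
                        max_iter: int = 100, tol: float = 0.01) -> GroupModel:
    """Adjust thresholds so model marginals match target category pmfs.

    Deterministic fixed-point pass: each iteration shifts ``mu_{ic}`` by the
    log-odds gap between target and current marginals (both relative to the
    baseline category).  Converges quickly for moderate interactions; used
    to keep sparse-condition marginals comparable to the dense condition so
    structural sparsity is not confounded with a marginal shift.
    """
    thr = [t.copy() for t in model.thresholds]
    sig = model.interactions
    for _ in range(max_iter):
        cur = GroupModel(thresholds=thr, interactions=sig)
        table = enumerate_joint_pmf(cur)
        worst = 0.0
        for i in range(model.n_variables):
            marg = table.marginal(i)
            tgt = np.asarray(target_marginals[i], dtype=float)
            worst = max(worst, float(np.abs(marg - tgt).max()))
            adj = (np.log(tgt[1:] / tgt[0]) - np.log(marg[1:] / marg[0]))
            thr[i] = thr[i] + adj
        if worst < tol:
            break
    return GroupModel(thresholds=thr, interactions=sig)


def generate_truth(cfg: TruthConfig, rng: np.random.Generator = None
                   ) -> TwoGroupModel:
    """Draw one two-group truth model from the design in ``cfg``.

    Edges are retained i.i.d. with probability ``density``; retained overall
    interactions come from the pool (or its parametric surrogate); a
    ``prop_diff`` fraction of all pairs (rounded to the nearest count)
    receives an interaction difference with magnitude ``U(diff_low,
    diff_high)`` and random sign.  Threshold differences are zero: the
    harness assumes threshold equality and targets interaction differences.
    """
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    p = cfg.p
    npair = p * (p - 1) // 2
    if cfg.prop_diff > 0 and npair == 0:
        raise ValueError("prop_diff > 0 requires at least one variable pair")

    def draw_interactions(k):
        if cfg.interaction_pool is not None:
            pool = np.asarray(cfg.interaction_pool, dtype=float)
            return rng.choice(pool, size=k, replace=True)
        return cfg.interaction_loc + rng.gamma(
            cfg.interaction_gamma_shape, cfg.interaction_gamma_scale, size=k)

    def draw_thresholds(k):
        if cfg.threshold_pool is not None:
            pool = np.asarray(cfg.threshold_pool, dtype=float)
            return rng.choice(pool, size=k, replace=True)
        return rng.normal(cfg.threshold_loc, cfg.threshold_scale, size=k)

    thresholds = [draw_thresholds(int(m) - 1) for m in cfg.n_categories]

    dense_vals = draw_interactions(npair)
    retained = rng.random(npair) < cfg.density
    vals = np.where(retained, dense_vals, 0.0)
    iu = np.triu_indices(p, 1)
    sig = np.zeros((p, p))
    sig[iu] = vals
    overall = GroupModel(thresholds=thresholds, interactions=sig)

    if cfg.recenter and cfg.density < 1.0 and not retained.all():
        dense_sig = np.zeros((p, p))
        dense_sig[iu] = dense_vals
        dense = GroupModel(thresholds=[t.copy() for t in thresholds],
                           interactions=dense_sig)
        n_states = int(np.prod(cfg.n_categories, dtype=np.int64))
        if n_states <= ENUMERATION_GUARD:
            targets = [enumerate_joint_pmf(dense).marginal(i)
                       for i in range(p)]
            overall = recenter_thresholds(overall, targets)
        else:
            warnings.warn("state space too large for threshold re-centering; "
                          "skipped", stacklevel=2)

    n_diff = int(round(cfg.prop_diff * npair))
    deltas = np.zeros(npair)
    if n_diff > 0:
        which = rng.choice(npair, size=n_diff, replace=False)
        mags = rng.uniform(cfg.diff_low, cfg.diff_high, size=n_diff)
        signs = rng.choice([-1.0, 1.0], size=n_diff)
        deltas[which] = signs * mags
    dsig = np.zeros((p, p))
    dsig[iu] = deltas
    diffs = DifferenceModel(
        threshold_diffs=[np.zeros(int(m) - 1) for m in cfg.n_categories],
        interaction_diffs=dsig,
    )
    return TwoGroupModel(overall=overall, diffs=diffs)


def _passes_safeguard(data: OrdinalDataset, min_count: int) -> bool:
    for i in range(data.n_variables):
        counts = np.bincount(data.responses[:, i],
                             minlength=int(data.n_categories[i]))
        if np.sort(counts)[-2] < min_count:
            return False
    return True


def apply_marginal_safeguard(generator: Callable, cfg: TruthConfig,
                             rng: np.random.Generator = None,
                             max_resamples: int = 100):
    """Re-run the whole truth+data process until marginals are usable.

    ``generator(rng)`` must return ``(truth, data1, data2)``.  The entire
    process is resampled until the second-most frequent response category of
    every variable in both groups holds at least
    ``cfg.min_second_category_count`` observations.  Returns ``(truth,
    data1, data2, resample_count)``.
    """
    rng = np.random.default_rng(rng)
    for attempt in range(max_resamples + 1):
        truth, d1, d2 = generator(rng)
        ok = (_passes_safeguard(d1, cfg.min_second_category_count)
              and _passes_safeguard(d2, cfg.min_second_category_count))
        if ok:
            return truth, d1, d2, attempt
    raise RuntimeError(
        f"marginal safeguard not satisfied after {max_resamples} resamples; "
        "the design produces degenerate marginals")


def run_simulation_cell(cfg: TruthConfig, n_per_group: int,
                        priors, sampler_cfg, replicates: int,
                        seed: int = None,
                        method: str = "exact") -> pd.DataFrame:
    """One condition cell of the simulation harness.

    For each replicate: draw a truth model and safeguarded data, run the
    spike-and-slab selection sampler, and record each pair's posterior
    inclusion probability next to its ground-truth difference flag.  Returns
    a tidy table with columns replicate, var_i, var_j, true_delta,
    true_diff, pip.

    Randomness is derived per replicate from ``seed``, with the truth model
    on its own substream: cells run at different sample sizes under the same
    seed share truth draws, so sample-size comparisons are paired (common
    random numbers).

    Matching the truth (which has no threshold differences), the analysis
    assumes threshold equality across groups and selects interaction
    differences only; ``sampler_cfg.update_threshold_differences`` is
    overridden accordingly.
    """
    from dataclasses import replace

    from .sampler import run_selection

    if seed is None:
        seed = cfg.seed if cfg.seed is not None else 0

    rows = []
    for rep in range(replicates):
        attempt_box = [0]

        def gen(_unused):
            k = attempt_box[0]
            attempt_box[0] += 1
            truth = generate_truth(cfg, np.random.default_rng((seed, rep, k, 0)))
            rd = np.random.default_rng((seed, rep, k, 1))
            d1 = sample_dataset(derive_group_model(truth, 1), n_per_group,
                                method=method, rng=rd)
            d2 = sample_dataset(derive_group_model(truth, 2), n_per_group,
                                method=method, rng=rd)
            return truth, d1, d2

        truth, d1, d2, _ = apply_marginal_safeguard(gen, cfg, None)
        run_seed = int(np.random.default_rng((seed, rep, 2)).integers(0, 2**31 - 1))
        # the harness assumes threshold equality across groups and targets
        # interaction differences only
        scfg = replace(sampler_cfg, seed=run_seed,
                       update_threshold_differences=False)
        draws = run_selection(d1, d2, priors, scfg,
                              alignment_mode="Collapse")
        pips = draws.interaction_pips()
        for k, (i, j) in enumerate(draws.pair_index):
            td = float(truth.diffs.interaction_diffs[i, j])
            rows.append({
                "replicate": rep, "var_i": i, "var_j": j,
                "true_delta": td, "true_diff": int(td != 0.0),
                "pip": float(pips[k]),
            })
    return pd.DataFrame(rows)
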