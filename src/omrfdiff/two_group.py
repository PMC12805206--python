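"""Two-group reparameterization of the ordinal MRF.

Group differences are tested in a contrast parameterization: each parameter
(threshold or interaction) is written as an *overall* value phi shared by both
groups plus a *difference* delta, with each group carrying half the contrast:

    group 1 = phi - delta/2,        group 2 = phi + delta/2,

so delta = group2 - group1 and phi = (group1 + group2)/2.  Setting delta = 0
recovers a single shared OMRF; the Bayes factor machinery tests exactly that
restriction per threshold vector and per interaction.

Thresholds attach to specific response categories, so cross-group threshold
comparison requires both groups to share a category coding.  Two alignment
strategies are supported for categories unobserved in one group:

* ``Free`` — each group's unobserved categories are squeezed out of that
  group's coding only; group thresholds are estimated separately and the
  threshold-difference test is unavailable.
* ``Collapse`` — a category unobserved in *either* group is merged into the
  next lower category (or the next higher one when the lowest is missing) in
  *both* groups, preserving a common coding so thresholds remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import GroupModel, OrdinalDataset, log_pseudolikelihood

__all__ = [
    "DifferenceModel",
    "TwoGroupModel",
    "AlignmentPlan",
    "derive_group_model",
    "align_categories",
    "two_group_log_pseudolikelihood",
]


@dataclass
class DifferenceModel:
    """Group-2-minus-group-1 contrasts for thresholds and interactions."""

    threshold_diffs: list  # ragged, matching n_categories - 1 per variable
    interaction_diffs: np.ndarray  # symmetric p x p, zero diagonal

    def __post_init__(self):
        self.threshold_diffs = [
            np.asarray(t, dtype=float).ravel() for t in self.threshold_diffs
        ]
        d = np.asarray(self.interaction_diffs, dtype=float)
        p = len(self.threshold_diffs)
        if d.shape != (p, p):
            raise ValueError("interaction_diffs must be p x p")
        d = np.triu(d, 1)
        self.interaction_diffs = d + d.T


@dataclass
class TwoGroupModel:
    """Overall OMRF plus the group-difference contrasts."""

    overall: GroupModel
    diffs: DifferenceModel

    def __post_init__(self):
        if len(self.diffs.threshold_diffs) != self.overall.n_variables:
            raise ValueError("overall and diffs disagree on variable count")
        for t, d in zip(self.overall.thresholds, self.diffs.threshold_diffs):
            if t.size != d.size:
                raise ValueError("threshold_diffs shape mismatch")
        if self.diffs.interaction_diffs.shape != self.overall.interactions.shape:
            raise ValueError("interaction_diffs shape mismatch")


def derive_group_model(m: TwoGroupModel, group: int) -> GroupModel:
    """Group-specific OMRF implied by (overall, diffs).

    ``group`` is 1 or 2; group 1 subtracts and group 2 adds half of every
    difference parameter.
    """
    if group not in (1, 2):
        raise ValueError("group must be 1 or 2")
    s = -0.5 if group == 1 else 0.5
    thr = [
        t + s * d for t, d in zip(m.overall.thresholds, m.diffs.threshold_diffs)
    ]
    sig = m.overall.interactions + s * m.diffs.interaction_diffs
    return GroupModel(thresholds=thr, interactions=sig)


@dataclass
class AlignmentPlan:
    """Per-group category recodings produced by :func:`align_categories`.

    ``mappings[g][i]`` maps variable ``i``'s original code to its recoded
    value in group ``g`` (index 0 = group 1).  Mappings are monotone
    non-decreasing and surjective onto consecutive codes starting at 0; in
    Collapse mode both groups share one mapping.
    """

    mode: str
    mappings: list  # [group1_maps, group2_maps]; each a list of int arrays
    n_categories: list = field(default=None)  # [ncat_group1, ncat_group2]

    def __post_init__(self):
        if self.mode not in ("Free", "Collapse"):
            raise ValueError("mode must be 'Free' or 'Collapse'")
        if self.n_categories is None:
            self.n_categories = [
                np.array([mp.max() + 1 for mp in gmaps], dtype=np.int64)
                for gmaps in self.mappings
            ]

    def to_dict(self) -> dict:
        """JSON-serializable audit record of the recoding."""
        return {
            "mode": self.mode,
            "group1_mappings": [mp.tolist() for mp in self.mappings[0]],
            "group2_mappings": [mp.tolist() for mp in self.mappings[1]],
            "group1_n_categories": self.n_categories[0].tolist(),
            "group2_n_categories": self.n_categories[1].tolist(),
        }


def _squeeze_map(observed: np.ndarray, n_cat: int) -> np.ndarray:
    """Monotone map dropping unobserved codes, renumbering consecutively."""
    mapping = np.zeros(n_cat, dtype=np.int64)
    nxt = 0
    for c in range(n_cat):
        if observed[c]:
            mapping[c] = nxt
            nxt += 1
        else:
            # unobserved codes never occur in the data; park them on the
            # previous kept code to keep the map monotone
            mapping[c] = max(nxt - 1, 0)
    return mapping


def _collapse_map(obs_both: np.ndarray, obs_any: np.ndarray, n_cat: int) -> np.ndarray:
    """Shared map merging categories unobserved in either group.

    Categories observed in both groups are kept; a category missing in one
    group merges into the next lower kept category, or the next higher kept
    category when nothing lies below it.  Categories observed in neither
    group are simply removed.
    """
    kept = [c for c in range(n_cat) if obs_both[c]]
    if len(kept) < 2:
        raise ValueError(
            "fewer than 2 categories observed in both groups; thresholds "
            "are not identifiable under Collapse alignment"
        )
    rank = {c: r for r, c in enumerate(kept)}
    mapping = np.zeros(n_cat, dtype=np.int64)
    for c in range(n_cat):
        if c in rank:
            mapping[c] = rank[c]
        else:
            lower = [k for k in kept if k < c]
            if lower:
                mapping[c] = rank[lower[-1]]
            else:
                higher = [k for k in kept if k > c]
                mapping[c] = rank[higher[0]]
    return mapping


def align_categories(
    data1: OrdinalDataset, data2: OrdinalDataset, mode: str = "Collapse"
):
    """Reconcile category codings across the two groups.

    Returns ``(plan, recoded_data1, recoded_data2)``.  See the module
    docstring for the Free/Collapse semantics.  Raises ``ValueError`` if any
    variable is left with fewer than 2 observed categories in either group.
    """
    if data1.n_variables != data2.n_variables:
        raise ValueError("groups must share the same variables")
    if mode not in ("Free", "Collapse"):
        raise ValueError("mode must be 'Free' or 'Collapse'")
    p = data1.n_variables
    n_cat = np.maximum(data1.n_categories, data2.n_categories)
    maps1, maps2 = [], []
    for i in range(p):
        nc = int(n_cat[i])
        obs1 = np.zeros(nc, dtype=bool)
        obs2 = np.zeros(nc, dtype=bool)
        if data1.n_rows:
            obs1[np.unique(data1.responses[:, i])] = True
        if data2.n_rows:
            obs2[np.unique(data2.responses[:, i])] = True
        if data1.n_rows == 0 and data2.n_rows == 0:
            # prior-only usage: nothing to align, keep the declared coding
            obs1[:] = obs2[:] = True
        if mode == "Free":
            if obs1.sum() < 2 or obs2.sum() < 2:
                raise ValueError(
                    f"variable {i}: fewer than 2 observed categories in one "
                    "group; no identifiable threshold"
                )
            maps1.append(_squeeze_map(obs1, nc))
            maps2.append(_squeeze_map(obs2, nc))
        else:
            shared = _collapse_map(obs1 & obs2, obs1 | obs2, nc)
            maps1.append(shared)
            maps2.append(shared)

    def _recode(data, gmaps):
        if data.n_rows == 0:
            ncat = np.array([mp.max() + 1 for mp in gmaps], dtype=np.int64)
            return OrdinalDataset(
                responses=np.empty((0, p), dtype=np.int64),
                n_categories=ncat,
                variable_names=list(data.variable_names),
            )
        cols = [gmaps[i][data.responses[:, i]] for i in range(p)]
        ncat = np.array([mp.max() + 1 for mp in gmaps], dtype=np.int64)
        return OrdinalDataset(
            responses=np.stack(cols, axis=1),
            n_categories=ncat,
            variable_names=list(data.variable_names),
        )

    plan = AlignmentPlan(mode=mode, mappings=[maps1, maps2])
    return plan, _recode(data1, maps1), _recode(data2, maps2)


def two_group_log_pseudolikelihood(
    m: TwoGroupModel, data1: OrdinalDataset, data2: OrdinalDataset
) -> float:
    """Joint log-pseudolikelihood of the two independent samples.

    Rows are independent within and between groups, so the value is the sum
    of the per-group pseudolikelihoods under the derived group models.
    Requires Collapse-compatible shapes (shared category structure).
    """
    total = 0.0
    for g, data in ((1, data1), (2, data2)):
        if data.n_rows:
            total += log_pseudolikelihood(derive_group_model(m, g), data)
    return total
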