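r"""One-group ordinal Markov random field (OMRF).

The OMRF is an exponential-family graphical model for ordinal variables.
Variable ``i`` takes category indices ``0, ..., m_i`` and carries category
threshold parameters ``mu_i1, ..., mu_i,m_i`` (the baseline ``mu_i0`` is fixed
to zero for identifiability).  A symmetric matrix ``sigma`` of pairwise
interactions encodes conditional dependence through a linear-by-linear term in
the category indices.  The joint pmf is

    P(x) \propto exp( sum_i mu_{i, x_i} + sum_{i<j} sigma_ij x_i x_j ),

whose normalizing constant sums over all prod_i (m_i + 1) category
configurations and is intractable for realistic dimensions; inference
therefore works with the pseudolikelihood, the product of the adjacent
category full conditionals

    P(X_i = c | rest) \propto exp( mu_{ic} + c * sum_{j != i} sigma_ij x_j ).

With binary variables the model reduces exactly to the Ising model with
external fields ``mu_i1`` and couplings ``sigma_ij``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OrdinalDataset",
    "GroupModel",
    "JointPmfTable",
    "category_probabilities",
    "log_pseudolikelihood",
    "enumerate_joint_pmf",
    "ENUMERATION_GUARD",
]

#: Largest joint state space the exact enumeration oracle will materialize.
ENUMERATION_GUARD = 10_000_000


class CapacityError(RuntimeError):
    """Raised when an exact computation would exceed the enumeration guard."""


@dataclass
class OrdinalDataset:
    """Integer-coded ordinal response matrix.

    Parameters
    ----------
    responses : ndarray of shape (n, p)
        Category indices; column ``i`` must lie in ``{0, ..., m_i}``.
    n_categories : ndarray of shape (p,)
        Number of categories per variable (``m_i + 1``), each at least 2.
    variable_names : list of str, optional
        Defaults to ``V1..Vp``.
    """

    responses: np.ndarray
    n_categories: np.ndarray
    variable_names: list = field(default=None)

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=np.int64)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D matrix")
        self.n_categories = np.asarray(self.n_categories, dtype=np.int64)
        if self.n_categories.shape != (self.responses.shape[1],):
            raise ValueError("n_categories length must match number of columns")
        if np.any(self.n_categories < 2):
            raise ValueError("every variable needs at least 2 categories")
        if self.responses.size:
            if self.responses.min() < 0:
                raise ValueError("negative category codes are not allowed")
            over = self.responses >= self.n_categories[None, :]
            if over.any():
                r, c = np.argwhere(over)[0]
                raise ValueError(
                    f"entry ({r},{c})={self.responses[r, c]} exceeds category "
                    f"bound {self.n_categories[c] - 1}"
                )
        if self.variable_names is None:
            self.variable_names = [f"V{i + 1}" for i in range(self.n_variables)]
        elif len(self.variable_names) != self.n_variables:
            raise ValueError("variable_names length mismatch")

    @property
    def n_rows(self) -> int:
        return self.responses.shape[0]

    @property
    def n_variables(self) -> int:
        return self.responses.shape[1]


@dataclass
class GroupModel:
    """Thresholds and pairwise interactions of one OMRF.

    ``thresholds[i]`` holds ``mu_{i1}, ..., mu_{i,m_i}`` (log-odds vs. the
    baseline category 0, whose threshold is fixed at zero).  ``interactions``
    is a symmetric ``p x p`` matrix with zero diagonal; the upper triangle is
    authoritative and mirrored on construction.
    """

    thresholds: list
    interactions: np.ndarray

    def __post_init__(self):
        self.thresholds = [np.asarray(t, dtype=float).ravel() for t in self.thresholds]
        sig = np.asarray(self.interactions, dtype=float)
        p = len(self.thresholds)
        if sig.shape != (p, p):
            raise ValueError("interactions must be p x p")
        if not np.all(np.isfinite(sig)) or not all(
            np.all(np.isfinite(t)) for t in self.thresholds
        ):
            raise ValueError("model parameters must be finite")
        for t in self.thresholds:
            if t.size < 1:
                raise ValueError("each variable needs at least one threshold")
        # mirror the upper triangle; zero the diagonal
        sig = np.triu(sig, 1)
        self.interactions = sig + sig.T

    @property
    def n_variables(self) -> int:
        return len(self.thresholds)

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([t.size + 1 for t in self.thresholds], dtype=np.int64)


@dataclass
class JointPmfTable:
    """Exhaustive enumeration of the joint pmf (small networks only)."""

    states: np.ndarray  # (n_states, p) category-index vectors
    probabilities: np.ndarray  # sums to 1

    def marginal(self, i: int) -> np.ndarray:
        """Marginal pmf of variable ``i``."""
        m = self.states[:, i].max() + 1
        return np.bincount(self.states[:, i], weights=self.probabilities, minlength=m)


def _check_row(model: GroupModel, row: np.ndarray) -> np.ndarray:
    row = np.asarray(row, dtype=np.int64).ravel()
    if row.size != model.n_variables:
        raise ValueError("row length does not match the model")
    ncat = model.n_categories
    if np.any(row < 0) or np.any(row >= ncat):
        raise ValueError("row contains out-of-range category indices")
    return row


def category_probabilities(model: GroupModel, row: np.ndarray, i: int) -> np.ndarray:
    """Full conditional of variable ``i`` given the rest of ``row``.

    Returns ``P(X_i = c | x_{-i})`` for ``c = 0..m_i`` under the adjacent
    category form: log-weight ``mu_{ic} + c * sum_{j != i} sigma_ij x_j`` with
    ``mu_{i0} = 0``.
    """
    row = _check_row(model, row)
    rest = float(model.interactions[i] @ row) - model.interactions[i, i] * row[i]
    m = model.thresholds[i].size
    logw = np.concatenate(([0.0], model.thresholds[i])) + np.arange(m + 1) * rest
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def log_pseudolikelihood(model: GroupModel, data: OrdinalDataset) -> float:
    """Sum of log full conditionals over all rows and variables.

    Additive over rows; always <= 0.  An empty dataset contributes 0 (with a
    warning, since that usually signals a data-handling bug upstream).
    """
    if not np.array_equal(data.n_categories, model.n_categories):
        raise ValueError("dataset category structure does not match the model")
    if data.n_rows == 0:
        warnings.warn("log_pseudolikelihood of an empty dataset is 0", stacklevel=2)
        return 0.0
    X = data.responses
    R = X @ model.interactions  # rest scores; diagonal is zero so no self term
    total = 0.0
    for i in range(model.n_variables):
        mu = np.concatenate(([0.0], model.thresholds[i]))
        cats = np.arange(mu.size)
        E = mu[None, :] + np.outer(R[:, i], cats)
        mx = E.max(axis=1)
        lse = mx + np.log(np.exp(E - mx[:, None]).sum(axis=1))
        total += float(E[np.arange(X.shape[0]), X[:, i]].sum() - lse.sum())
    return total


def enumerate_joint_pmf(model: GroupModel, guard: int = ENUMERATION_GUARD) -> JointPmfTable:
    """Exact joint pmf by exhaustive enumeration.

    Materializes all ``prod_i (m_i + 1)`` category configurations; refuses to
    run past ``guard`` states because the normalizing constant is what makes
    full-likelihood inference intractable in the first place.
    """
    ncat = model.n_categories
    n_states = int(np.prod(ncat, dtype=np.int64))
    if n_states > guard:
        raise CapacityError(
            f"joint state space has {n_states} configurations, above the "
            f"enumeration guard of {guard}"
        )
    grids = np.meshgrid(*[np.arange(m) for m in ncat], indexing="ij")
    states = np.stack([g.ravel() for g in grids], axis=1).astype(np.int64)
    logw = np.zeros(n_states)
    for i in range(model.n_variables):
        mu = np.concatenate(([0.0], model.thresholds[i]))
        logw += mu[states[:, i]]
    p = model.n_variables
    for i in range(p):
        for j in range(i + 1, p):
            sij = model.interactions[i, j]
            if sij != 0.0:
                logw += sij * states[:, i] * states[:, j]
    logw -= logw.max()
    w = np.exp(logw)
    return JointPmfTable(states=states, probabilities=w / w.sum())
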