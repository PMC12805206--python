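"""Reading two-group ordinal data and writing analysis reports."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import OrdinalDataset
from .priors import (BernoulliPrior, BetaBernoulliPrior, PriorConfig)
from .sampler import SamplerConfig

__all__ = ["RunConfig", "read_dataset", "write_report", "load_run_config"]


@dataclass
class RunConfig:
    """End-to-end settings of one `fit` run."""

    input_path: str
    group_column: str
    group_labels: Optional[list] = None  # first label = Group 1
    variable_columns: Optional[list] = None
    alignment_mode: str = "Collapse"
    priors: PriorConfig = field(default_factory=PriorConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    category_orders: Optional[dict] = None  # column -> ordered label list
    output_dir: str = "."
    verbosity: int = 1


def _codes_for_column(col: pd.Series, name: str, order=None):
    """Map a column's labels to consecutive 0-based codes (pooled groups)."""
    empties = col.isna() | (col.astype(str).str.strip() == "")
    if empties.any():
        r = int(np.nonzero(empties.values)[0][0])
        raise ValueError(f"missing value in column '{name}', data row {r}")
    if order is not None:
        order = list(order)
        unknown = set(col.unique()) - set(order)
        if unknown:
            raise ValueError(
                f"column '{name}' contains labels {sorted(map(str, unknown))} "
                "not in the supplied category order")
        mapping = {lab: k for k, lab in enumerate(order)}
        codes = col.map(mapping).to_numpy(dtype=np.int64)
        observed = np.unique(codes)
        # squeeze out unobserved labels so codes are consecutive from 0
        remap = {c: k for k, c in enumerate(observed)}
        return np.vectorize(remap.get)(codes), [order[c] for c in observed]
    vals = col.unique()
    try:
        numeric = pd.to_numeric(pd.Series(vals))
    except (ValueError, TypeError):
        raise ValueError(
            f"column '{name}' has non-numeric labels; supply an explicit "
            "category order") from None
    levels = numeric.sort_values().index
    ordered = [vals[i] for i in levels]
    mapping = {lab: k for k, lab in enumerate(ordered)}
    return col.map(mapping).to_numpy(dtype=np.int64), ordered


def read_dataset(path, group_column: str, variable_columns=None,
                 group_labels=None, category_orders=None):
    """Read a delimited two-group dataset.

    Labels in each variable column are mapped to consecutive 0-based codes
    using the categories observed in the pooled data (alignment across
    groups happens later).  Numeric labels order naturally; string labels
    need an explicit order in ``category_orders``.  Returns
    ``(data_group1, data_group2, mapping_record)``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=object, keep_default_na=False,
                     na_values=[""])
    if group_column not in df.columns:
        raise ValueError(f"group column '{group_column}' not found")
    if variable_columns is None:
        variable_columns = [c for c in df.columns if c != group_column]
    missing = [c for c in variable_columns if c not in df.columns]
    if missing:
        raise ValueError(f"variable columns not found: {missing}")

    glabs = df[group_column]
    if glabs.isna().any():
        r = int(np.nonzero(glabs.isna().values)[0][0])
        raise ValueError(f"missing group label in data row {r}")
    seen = list(pd.unique(glabs))
    if group_labels is None:
        group_labels = seen  # first-appearance order defines Group 1
    if len(group_labels) != 2 or len(seen) != 2 or set(map(str, seen)) != set(
            map(str, group_labels)):
        raise ValueError(
            f"expected exactly two group labels, found {sorted(map(str, seen))}")

    codes = {}
    orders = {}
    category_orders = category_orders or {}
    for c in variable_columns:
        codes[c], orders[c] = _codes_for_column(
            df[c], c, category_orders.get(c))
    X = np.stack([codes[c] for c in variable_columns], axis=1)
    ncat = X.max(axis=0) + 1
    mask1 = (glabs.astype(str) == str(group_labels[0])).to_numpy()
    d1 = OrdinalDataset(responses=X[mask1], n_categories=ncat,
                        variable_names=list(variable_columns))
    d2 = OrdinalDataset(responses=X[~mask1], n_categories=ncat,
                        variable_names=list(variable_columns))
    record = {
        "group_labels": [str(group_labels[0]), str(group_labels[1])],
        "category_orders": {c: [str(v) for v in orders[c]]
                            for c in variable_columns},
    }
    return d1, d2, record


def write_report(summary, out_dir, basename: str = "results") -> dict:
    """Write the JSON summary and the flat per-effect CSV table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    jpath = out_dir / f"{basename}.json"
    cpath = out_dir / f"{basename}_effects.csv"
    with open(jpath, "w") as fh:
        json.dump(summary.to_json_dict(), fh, indent=2, default=str)
    summary.effects.to_csv(cpath, index=False, float_format="%.10g")
    return {"json": str(jpath), "csv": str(cpath)}


def _prior_from_dict(d):
    if d is None:
        return BernoulliPrior()
    t = d.get("type", "Bernoulli")
    if t == "Bernoulli":
        return BernoulliPrior(pi=float(d.get("pi", 0.5)))
    if t == "BetaBernoulli":
        return BetaBernoulliPrior(alpha=float(d.get("alpha", 1.0)),
                                  beta=float(d.get("beta", 1.0)))
    raise ValueError(f"unknown indicator prior type '{t}'")


def load_run_config(path) -> RunConfig:
    """Load a YAML run configuration file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    pr = raw.get("priors", {})
    priors = PriorConfig(
        threshold_shape_a=float(pr.get("threshold_shape_a", 1.0)),
        threshold_shape_b=float(pr.get("threshold_shape_b", 1.0)),
        overall_interaction_scale=float(pr.get("overall_interaction_scale", 2.5)),
        difference_scale=float(pr.get("difference_scale", 1.0)),
        threshold_difference_scale=pr.get("threshold_difference_scale"),
        threshold_indicator_prior=_prior_from_dict(
            pr.get("threshold_indicator_prior")),
        interaction_indicator_prior=_prior_from_dict(
            pr.get("interaction_indicator_prior")),
    )
    sm = raw.get("sampler", {})
    sampler = SamplerConfig(**{k: sm[k] for k in sm})
    return RunConfig(
        input_path=raw.get("input_path", ""),
        group_column=raw.get("group_column", "group"),
        group_labels=raw.get("group_labels"),
        variable_columns=raw.get("variable_columns"),
        alignment_mode=raw.get("alignment_mode", "Collapse"),
        priors=priors,
        sampler=sampler,
        category_orders=raw.get("category_orders"),
        output_dir=raw.get("output_dir", "."),
        verbosity=int(raw.get("verbosity", 1)),
    )
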