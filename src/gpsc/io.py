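"""Reading and writing spatial datasets and clustering results.

Datasets are comma-delimited UTF-8 text with a header. Coordinates are
treated as planar Euclidean throughout (distances are straight-line even for
longitude/latitude columns — a caveat at continental scale).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusteringState, SpatialDataset
from .metrics import adjusted_mutual_info, adjusted_rand_index

__all__ = ["ColumnSpec", "read_dataset", "write_dataset", "write_results"]

logger = logging.getLogger("gpsc")


@dataclass
class ColumnSpec:
    """Role assignment for dataset columns: two spatial columns, any number
    of covariates, one response, and an optional true-label column."""

    spatial_cols: tuple[str, str] = ("s1", "s2")
    covariate_cols: list[str] = field(default_factory=lambda: ["x1", "x2"])
    response_col: str = "y"
    label_col: str | None = None

    def used_columns(self) -> list[str]:
        cols = [*self.spatial_cols, *self.covariate_cols, self.response_col]
        if self.label_col:
            cols.append(self.label_col)
        return cols

    def __post_init__(self) -> None:
        if len(self.spatial_cols) != 2:
            raise ValueError("exactly two spatial columns are required")
        cols = self.used_columns()
        if len(set(cols)) != len(cols):
            raise ValueError(f"column roles overlap: {cols}")


def read_dataset(path: str | Path, spec: ColumnSpec | None = None) -> SpatialDataset:
    """Load and validate a dataset; rows with missing values in any used
    column are dropped (with a logged count), never imputed."""
    spec = spec or ColumnSpec()
    df = pd.read_csv(path)
    missing = [c for c in spec.used_columns() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    used = df[spec.used_columns()]
    numeric = used.apply(pd.to_numeric, errors="coerce")
    bad_cells = numeric.isna() & ~used.isna()
    if bad_cells.any().any():
        col = bad_cells.any()[bad_cells.any()].index[0]
        raise ValueError(f"{path}: non-numeric values in column {col!r}")
    keep = ~numeric.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with missing values", path, n_dropped)
    numeric = numeric[keep]
    if len(numeric) == 0:
        raise ValueError(f"{path}: no usable rows after dropping missing values")
    true_labels = (
        numeric[spec.label_col].to_numpy(dtype=int) if spec.label_col else None
    )
    return SpatialDataset(
        s=numeric[list(spec.spatial_cols)].to_numpy(),
        x=numeric[spec.covariate_cols].to_numpy(),
        y=numeric[spec.response_col].to_numpy(),
        true_labels=true_labels,
    )


def write_dataset(dataset: SpatialDataset, path: str | Path) -> None:
    """Write a dataset as CSV with columns s1,s2,x1..xp,y[,true_label]."""
    cols = {"s1": dataset.s[:, 0], "s2": dataset.s[:, 1]}
    for j in range(dataset.p):
        cols[f"x{j + 1}"] = dataset.x[:, j]
    cols["y"] = dataset.y
    if dataset.true_labels is not None:
        cols["true_label"] = dataset.true_labels
    pd.DataFrame(cols).to_csv(path, index=False)


def write_results(
    state: ClusteringState, dataset: SpatialDataset, path: str | Path
) -> None:
    """Write clustering output: the input columns plus ``predicted_label``
    as CSV, and a JSON sidecar (same path, .json suffix) with the config,
    iteration history, per-cluster sizes and kernel hyperparameters, and
    ARI/AMI against the true labels when those are present."""
    path = Path(path)
    cols = {"s1": dataset.s[:, 0], "s2": dataset.s[:, 1]}
    for j in range(dataset.p):
        cols[f"x{j + 1}"] = dataset.x[:, j]
    cols["y"] = dataset.y
    if dataset.true_labels is not None:
        cols["true_label"] = dataset.true_labels
    cols["predicted_label"] = state.labels
    pd.DataFrame(cols).to_csv(path, index=False)

    cfg = state.config
    sizes = np.bincount(state.labels, minlength=cfg.L + 1)[1:]
    sidecar: dict = {
        "config": {
            "L": cfg.L,
            "T": cfg.T,
            "lambda": cfg.lambda_,
            "feature_mode": cfg.feature_mode,
            "restarts": cfg.restarts,
            "seed": cfg.seed,
            "init_strategy": cfg.init_strategy,
        },
        "iterations": state.iteration,
        "converged": state.converged,
        "history": state.history,
        "cluster_sizes": sizes.tolist(),
        "clusters": [
            None
            if m is None
            else {
                "sigma2": m.params.sigma2,
                "b": m.params.b,
                "tau2": m.params.tau2,
                "log_marginal_likelihood": m.log_marginal,
            }
            for m in state.models
        ],
    }
    if dataset.true_labels is not None:
        sidecar["ari"] = adjusted_rand_index(state.labels, dataset.true_labels)
        sidecar["ami"] = adjusted_mutual_info(state.labels, dataset.true_labels)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
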