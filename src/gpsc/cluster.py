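"""Gaussian Process Spatial Clustering (GPSC).

Partitions supervised spatial observations (s_i, x_i, y_i) into L clusters,
each governed by its own unknown response function f_j, under the model

    y_i = sum_j 1(l_i = j) f_j(x_i).

Each iteration (a) fits one GP per cluster on that cluster's current members
and (b) reassigns every observation to the cluster whose GP predicts its
response best, optionally penalized by distance to the cluster's spatial
center:

    l_i <- argmin_j (fhat_j(s_i, x_i) - y_i)^2 + lambda * ||s_i - C_j||

The loop stops when the label vector stabilizes, or after T iterations.

Two practical devices make the iteration reliable from uninformed starts,
both in the spirit of bounding the covariance parameters to prevent
overfitting:

* **Annealed bounds.** From a random initialization every cluster is a
  mixture of response functions; an unconstrained GP can near-interpolate
  such a mixture (the response is a deterministic map away from region
  boundaries), zeroing all residuals and freezing the labels in a poor
  state. Early iterations therefore run with high floors on the length
  scale and nugget — forcing rigid fits close to the mixture-weighted mean
  function, whose prediction errors separate the mixture components
  coherently — and the floors are relaxed geometrically, iterating to
  label-stability at each level, until the configured bounds are reached.
  Informed starts ("given" labels) skip the schedule entirely, so a correct
  initialization is evaluated, and left fixed, at the configured bounds.
* **Multi-initialization.** Random initialization is restarted ``n_init``
  times and the final state with the highest summed per-cluster log
  marginal likelihood is kept; a correct partition explains each cluster as
  a smooth function plus small noise and dominates this score.

Features (and the spatial coordinates used for the penalty) are z-scored
once with whole-dataset statistics, so a single isotropic length scale and
a data-scale-free lambda are meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans

from .gp import GPModel, KernelParams, ParamBounds, blup_predict, fit_gp_mle

__all__ = [
    "SpatialDataset",
    "GPSCConfig",
    "ClusteringState",
    "initialize_labels",
    "fit_cluster_models",
    "cluster_centers",
    "reassign",
    "gpsc_fit",
    "predict_cluster",
]

logger = logging.getLogger("gpsc")


@dataclass
class SpatialDataset:
    """n observations of spatial coordinates s (n x 2), covariates x (n x p),
    response y (n,), with optional integer true labels. Missing values are
    rejected, never imputed."""

    s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    true_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s = np.atleast_2d(np.asarray(self.s, dtype=float))
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.s.shape[0]
        if n < 1:
            raise ValueError("dataset must contain at least one observation")
        if self.s.shape[1] != 2:
            raise ValueError(f"s must have exactly 2 columns, got {self.s.shape[1]}")
        if self.x.shape[0] != n or self.y.shape[0] != n:
            raise ValueError(
                f"row counts differ: s={n}, x={self.x.shape[0]}, y={self.y.shape[0]}"
            )
        for name, arr in (("s", self.s), ("x", self.x), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains missing or non-finite values")
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels, dtype=int).ravel()
            if self.true_labels.shape[0] != n:
                raise ValueError("true_labels length mismatch")

    @property
    def n(self) -> int:
        return self.s.shape[0]

    @property
    def p(self) -> int:
        return self.x.shape[1]


@dataclass
class GPSCConfig:
    """Tuning parameters of the clustering loop.

    L : number of clusters (>= 1).
    T : cap on total fit/reassign iterations, summed over annealing levels;
        the loop normally stops earlier, when labels stabilize at the final
        level.
    lambda_ : spatial-contiguity penalty weight (>= 0), applied to Euclidean
        distances between standardized coordinates; 0 disables the penalty.
    feature_mode : "space+covariates" fits each GP on [s, x] (as in the
        algorithm's listing), "covariates" on x alone (as in the model
        equation). The latter is the default: including raw coordinates
        lets a flexible GP absorb region structure spatially and weakens the
        functional separation the reassignment relies on; spatial structure
        is better injected through lambda.
    bounds : kernel hyperparameter box at the final annealing level;
        default scales with var(y) (see ParamBounds.default).
    restarts : random MLE multi-starts on the first fit of each annealing
        level (later fits warm-start from the previous hyperparameters).
    n_init : independent random initializations; the state with the highest
        summed per-cluster log marginal likelihood is returned. Applies to
        init_strategy "random" only.
    min_cluster_size : smallest cluster a reseeding donor may be left with.
    init_strategy : "random", "spatial-kmeans", or "given".
    anneal_levels : number of relaxation levels before the final bounds;
        0 disables annealing.
    anneal_b0, anneal_tau0 : initial floors — length scale b0 (standardized
        squared-distance units) and nugget fraction tau0 * var(y).
    anneal_decay : geometric floor decay per level.
    anneal_sigma_cap : cap on sigma2, as a multiple of var(y), during the
        pre-final levels (prevents the signal variance from buying back the
        flexibility the floors remove).
    max_iter_per_level : iteration cap at each level before relaxing.
    """

    L: int
    T: int = 60
    lambda_: float = 0.0
    feature_mode: str = "covariates"
    bounds: ParamBounds | None = None
    restarts: int = 2
    seed: int | None = None
    n_init: int = 3
    min_cluster_size: int = 1
    init_strategy: str = "random"
    anneal_levels: int = 5
    anneal_b0: float = 20.0
    anneal_tau0: float = 0.5
    anneal_decay: float = 0.25
    anneal_sigma_cap: float = 4.0
    max_iter_per_level: int = 8

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.feature_mode not in ("space+covariates", "covariates"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        if self.init_strategy not in ("random", "spatial-kmeans", "given"):
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.anneal_levels < 0:
            raise ValueError("anneal_levels must be >= 0")


@dataclass
class _Scaler:
    """Fixed z-scoring transform (whole-dataset statistics)."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, M: np.ndarray) -> "_Scaler":
        std = M.std(axis=0)
        std = np.where(std == 0, 1.0, std)
        return cls(mean=M.mean(axis=0), std=std)

    def transform(self, M: np.ndarray) -> np.ndarray:
        return (M - self.mean) / self.std


@dataclass
class ClusteringState:
    """Result of a GPSC run: final labels (1..L), per-cluster models and
    spatial centers (None marks an empty cluster), and the iteration trace.
    ``score`` is the summed per-cluster log marginal likelihood used to rank
    multi-initialization runs."""

    labels: np.ndarray
    models: list[GPModel | None]
    centers: list[np.ndarray | None]
    iteration: int
    converged: bool
    history: list[int]
    config: GPSCConfig
    score: float = float("-inf")
    _s_scaler: _Scaler | None = field(default=None, repr=False)
    _x_scaler: _Scaler | None = field(default=None, repr=False)


def _build_design(s_std: np.ndarray, x_std: np.ndarray, feature_mode: str) -> np.ndarray:
    if feature_mode == "space+covariates":
        return np.hstack([s_std, x_std])
    return x_std


def initialize_labels(
    dataset: SpatialDataset,
    config: GPSCConfig,
    strategy: str | None = None,
    given: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Initial label vector in {1..L}; every cluster non-empty.

    "random" draws uniform labels (redrawn, bounded, until no cluster is
    empty); "spatial-kmeans" runs K-means on the spatial coordinates alone;
    "given" validates and returns the supplied vector.
    """
    strategy = strategy or config.init_strategy
    L, n = config.L, dataset.n
    if n < L:
        raise ValueError(f"infeasible: n={n} observations for L={L} clusters")
    if strategy == "given":
        if given is None:
            raise ValueError("init_strategy 'given' requires a label vector")
        labels = np.asarray(given, dtype=int).ravel()
        if labels.shape[0] != n or labels.min() < 1 or labels.max() > L:
            raise ValueError("given labels must be length n with values in {1..L}")
        return labels.copy()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if strategy == "spatial-kmeans":
        km_seed = int(rng.integers(2**31 - 1))
        km = KMeans(n_clusters=L, n_init=10, random_state=km_seed)
        return km.fit_predict(dataset.s) + 1
    for _ in range(1000):
        labels = rng.integers(1, L + 1, size=n)
        if len(np.unique(labels)) == L:
            return labels
    raise RuntimeError("failed to draw an initialization with all clusters non-empty")


def fit_cluster_models(
    dataset: SpatialDataset,
    labels: np.ndarray,
    config: GPSCConfig,
    design: np.ndarray | None = None,
    bounds: ParamBounds | None = None,
    warm: list[KernelParams | None] | None = None,
    rng: np.random.Generator | None = None,
) -> list[GPModel | None]:
    """One GP per non-empty cluster, fitted on that cluster's rows of the
    design matrix; None marks an empty cluster."""
    if design is None:
        s_std = _Scaler.fit(dataset.s).transform(dataset.s)
        x_std = _Scaler.fit(dataset.x).transform(dataset.x)
        design = _build_design(s_std, x_std, config.feature_mode)
    if bounds is None:
        bounds = config.bounds or ParamBounds.default(dataset.y.var())
    if rng is None:
        rng = np.random.default_rng(config.seed)
    models: list[GPModel | None] = []
    for j in range(1, config.L + 1):
        mask = labels == j
        if not mask.any():
            models.append(None)
            continue
        init = warm[j - 1] if warm is not None else None
        if init is not None:
            lo, hi = bounds.as_arrays()
            clipped = np.clip([init.sigma2, init.b, init.tau2], lo, hi)
            init = KernelParams(*clipped)
        restarts = 1 if init is not None else config.restarts
        models.append(
            fit_gp_mle(
                design[mask],
                dataset.y[mask],
                bounds=bounds,
                restarts=restarts,
                seed=rng,
                init=init,
            )
        )
    return models


def cluster_centers(
    s: np.ndarray, labels: np.ndarray, L: int
) -> list[np.ndarray | None]:
    """Coordinate-wise mean of s per cluster; None for empty clusters."""
    centers: list[np.ndarray | None] = []
    for j in range(1, L + 1):
        mask = labels == j
        centers.append(s[mask].mean(axis=0) if mask.any() else None)
    return centers


def _penalized_errors(
    design: np.ndarray,
    s_std: np.ndarray,
    y: np.ndarray,
    models: list[GPModel | None],
    centers: list[np.ndarray | None],
    lambda_: float,
) -> np.ndarray:
    """n x L matrix of squared prediction errors plus spatial penalties;
    +inf columns for empty clusters."""
    n, L = design.shape[0], len(models)
    cost = np.full((n, L), np.inf)
    for j, (model, center) in enumerate(zip(models, centers)):
        if model is None:
            continue
        pred = blup_predict(model, design)
        cost[:, j] = (pred - y) ** 2
        if lambda_ > 0:
            if center is None:
                raise ValueError(f"cluster {j + 1} has a model but no center")
            cost[:, j] += lambda_ * np.linalg.norm(s_std - center, axis=1)
    return cost


def reassign(
    dataset: SpatialDataset,
    models: list[GPModel | None],
    centers: list[np.ndarray | None],
    lambda_: float = 0.0,
    design: np.ndarray | None = None,
    s_std: np.ndarray | None = None,
    feature_mode: str = "covariates",
) -> np.ndarray:
    """Assign each observation to the cluster minimizing squared prediction
    error + lambda * distance-to-center. Ties break to the lowest index;
    empty clusters are never selected."""
    if all(m is None for m in models):
        raise ValueError("all clusters are empty; cannot reassign")
    if s_std is None:
        s_std = _Scaler.fit(dataset.s).transform(dataset.s)
    if design is None:
        x_std = _Scaler.fit(dataset.x).transform(dataset.x)
        design = _build_design(s_std, x_std, feature_mode)
    cost = _penalized_errors(design, s_std, dataset.y, models, centers, lambda_)
    return np.argmin(cost, axis=1) + 1


def _reseed_empty_clusters(
    labels: np.ndarray,
    cost: np.ndarray,
    L: int,
    min_cluster_size: int,
) -> np.ndarray:
    """Give each empty cluster the observation with the largest current
    assignment cost, provided its donor cluster stays >= min_cluster_size."""
    labels = labels.copy()
    own_cost = cost[np.arange(labels.shape[0]), labels - 1]
    for j in range(1, L + 1):
        if np.any(labels == j):
            continue
        sizes = np.bincount(labels, minlength=L + 1)
        eligible = sizes[labels] > min_cluster_size
        if not eligible.any():
            logger.warning("cluster %d stays empty: no eligible donor", j)
            continue
        idx = np.flatnonzero(eligible)[np.argmax(own_cost[eligible])]
        logger.info(
            "reseeding empty cluster %d with observation %d (cost %.3g)",
            j, idx, own_cost[idx],
        )
        labels[idx] = j
    return labels


def _anneal_schedule(config: GPSCConfig, var_y: float) -> list[ParamBounds]:
    """Bounds per level: relaxing floors, ending at the configured bounds.

    Besides the b and tau2 floors, pre-final levels cap sigma2 at a small
    multiple of var(y): an unbounded signal variance can compensate for a
    rigid length scale (the fit's effective flexibility scales with
    sigma2/tau2), which would defeat the rigid phase entirely.
    """
    final = config.bounds or ParamBounds.default(var_y)
    levels = []
    for lev in range(config.anneal_levels):
        b_floor = max(final.b[0], config.anneal_b0 * config.anneal_decay**lev)
        tau_floor = max(final.tau2[0], config.anneal_tau0 * var_y * config.anneal_decay**lev)
        sigma_cap = min(final.sigma2[1], config.anneal_sigma_cap * var_y)
        levels.append(
            ParamBounds(
                sigma2=(min(final.sigma2[0], sigma_cap), sigma_cap),
                b=(min(b_floor, final.b[1]), final.b[1]),
                tau2=(min(tau_floor, final.tau2[1]), final.tau2[1]),
            )
        )
    levels.append(final)
    return levels


def _gpsc_single(
    dataset: SpatialDataset,
    config: GPSCConfig,
    labels: np.ndarray,
    design: np.ndarray,
    s_std: np.ndarray,
    rng: np.random.Generator,
    anneal: bool,
) -> ClusteringState:
    """One annealed descent from one initialization."""
    var_y = float(dataset.y.var())
    schedule = _anneal_schedule(config, var_y) if anneal else [
        config.bounds or ParamBounds.default(var_y)
    ]
    history: list[int] = []
    converged = False
    models: list[GPModel | None] = []
    centers: list[np.ndarray | None] = []
    total_iter = 0
    final_level = len(schedule) - 1
    for level, bounds in enumerate(schedule):
        warm: list[KernelParams | None] | None = None
        for _ in range(config.max_iter_per_level):
            if total_iter >= config.T:
                break
            total_iter += 1
            models = fit_cluster_models(
                dataset, labels, config, design=design, bounds=bounds, warm=warm, rng=rng
            )
            centers = cluster_centers(s_std, labels, config.L)
            cost = _penalized_errors(
                design, s_std, dataset.y, models, centers, config.lambda_
            )
            new_labels = np.argmin(cost, axis=1) + 1
            new_labels = _reseed_empty_clusters(
                new_labels, cost, config.L, config.min_cluster_size
            )
            changes = int(np.sum(new_labels != labels))
            history.append(changes)
            logger.info(
                "level %d iteration %d: %d label changes", level, total_iter, changes
            )
            if changes == 0:
                converged = level == final_level
                break
            labels = new_labels
            warm = [m.params if m is not None else None for m in models]
        if total_iter >= config.T:
            break

    last_changed = history and history[-1] != 0
    if last_changed:
        # reassignment moved labels on the very last iteration; refresh models
        models = fit_cluster_models(
            dataset, labels, config, design=design, bounds=schedule[-1],
            warm=[m.params if m is not None else None for m in models], rng=rng,
        )
        centers = cluster_centers(s_std, labels, config.L)
    score = float(sum(m.log_marginal for m in models if m is not None))
    return ClusteringState(
        labels=labels,
        models=models,
        centers=centers,
        iteration=total_iter,
        converged=converged,
        history=history,
        config=config,
        score=score,
    )


def gpsc_fit(
    dataset: SpatialDataset,
    config: GPSCConfig,
    init: np.ndarray | None = None,
) -> ClusteringState:
    """Run the full clustering loop.

    Alternates per-cluster GP fitting, center computation and penalized
    reassignment under the annealed bound schedule, stopping when the label
    vector stabilizes at the final level (or after T total iterations).
    Random initializations are restarted ``config.n_init`` times and the
    best state by summed log marginal likelihood is returned. An explicit
    ``init`` label vector (or init_strategy="given") bypasses both the
    annealing schedule and the restarts: the supplied labels are refined
    directly at the configured bounds. Deterministic given ``config.seed``.
    """
    s_scaler = _Scaler.fit(dataset.s)
    x_scaler = _Scaler.fit(dataset.x)
    s_std = s_scaler.transform(dataset.s)
    x_std = x_scaler.transform(dataset.x)
    design = _build_design(s_std, x_std, config.feature_mode)
    rng = np.random.default_rng(config.seed)

    strategy = "given" if init is not None else config.init_strategy
    if strategy == "given":
        starts = [initialize_labels(dataset, config, strategy="given", given=init)]
        anneal = False
    elif strategy == "spatial-kmeans":
        starts = [initialize_labels(dataset, config, strategy=strategy, rng=rng)]
        anneal = config.anneal_levels > 0
    else:
        starts = [
            initialize_labels(dataset, config, strategy="random", rng=rng)
            for _ in range(config.n_init)
        ]
        anneal = config.anneal_levels > 0

    best: ClusteringState | None = None
    for i, labels0 in enumerate(starts):
        state = _gpsc_single(dataset, config, labels0, design, s_std, rng, anneal)
        logger.info(
            "initialization %d/%d: score %.1f, %d iterations, converged=%s",
            i + 1, len(starts), state.score, state.iteration, state.converged,
        )
        if best is None or state.score > best.score:
            best = state
    assert best is not None
    best._s_scaler = s_scaler
    best._x_scaler = x_scaler
    return best


def predict_cluster(
    state: ClusteringState,
    s_new: np.ndarray,
    x_new: np.ndarray,
    y_new: np.ndarray,
    lambda_: float | None = None,
) -> np.ndarray:
    """Apply the fitted reassignment rule to new observations, without
    refitting any GP."""
    if all(m is None for m in state.models):
        raise ValueError("state has no fitted models")
    s_new = np.atleast_2d(np.asarray(s_new, dtype=float))
    x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    y_new = np.asarray(y_new, dtype=float).ravel()
    if s_new.shape[0] == 0:
        return np.empty(0, dtype=int)
    q_expected = next(m for m in state.models if m is not None).train_inputs.shape[1]
    s_std = state._s_scaler.transform(s_new)
    x_std = state._x_scaler.transform(x_new)
    design = _build_design(s_std, x_std, state.config.feature_mode)
    if design.shape[1] != q_expected:
        raise ValueError(
            f"feature dimension mismatch: built {design.shape[1]} columns, "
            f"models expect {q_expected}"
        )
    lam = state.config.lambda_ if lambda_ is None else lambda_
    cost = _penalized_errors(design, s_std, y_new, state.models, state.centers, lam)
    return np.argmin(cost, axis=1) + 1
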