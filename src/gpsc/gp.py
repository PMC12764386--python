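"""Gaussian process regression engine.

Implements the squared-exponential (RBF) kernel

    K(x, x') = sigma2 * exp(-||x - x'||^2 / (2 b))

with spatial variance ``sigma2`` and length scale ``b`` (note: ``b`` divides
the squared distance directly; the common ``exp(-d^2 / (2 l^2))`` convention
is the reparameterization ``b = l**2``, see :meth:`KernelParams.from_lengthscale`),
marginal-likelihood estimation of (sigma2, b, tau2) over a bounded box, and
BLUP (posterior-mean / kriging) prediction

    y_hat(x*) = K(x*, X) (K(X, X) + tau2 I)^{-1} Y.

The prior mean is zero; responses are centered before fitting and the offset
is restored at prediction time. A nugget tau2 >= 1e-8 * sigma2 is always
present on the Gram diagonal for conditioning and so that in-sample residuals
stay informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from scipy.spatial.distance import cdist

__all__ = [
    "KernelParams",
    "ParamBounds",
    "GPModel",
    "GPNumericalError",
    "rbf_kernel",
    "log_marginal_likelihood",
    "fit_gp_mle",
    "blup_predict",
]

#: relative jitter floor added to the Gram diagonal (times sigma2)
JITTER = 1e-8


class GPNumericalError(RuntimeError):
    """Gram matrix could not be factorized even after maximal jitter."""


@dataclass(frozen=True)
class KernelParams:
    """RBF kernel hyperparameters.

    Parameters
    ----------
    sigma2 : float
        Spatial variance (response units squared). Must be positive.
    b : float
        Length scale, in units of squared feature distance. Must be positive.
    tau2 : float
        Nugget / observation-noise variance. Non-negative.
    """

    sigma2: float
    b: float
    tau2: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma2 > 0 and np.isfinite(self.sigma2)):
            raise ValueError(f"sigma2 must be positive and finite, got {self.sigma2}")
        if not (self.b > 0 and np.isfinite(self.b)):
            raise ValueError(f"b must be positive and finite, got {self.b}")
        if not (self.tau2 >= 0 and np.isfinite(self.tau2)):
            raise ValueError(f"tau2 must be non-negative and finite, got {self.tau2}")

    @classmethod
    def from_lengthscale(cls, sigma2: float, lengthscale: float, tau2: float = 0.0) -> "KernelParams":
        """Build params from the ``exp(-d^2/(2 l^2))`` convention: b = l**2."""
        return cls(sigma2=sigma2, b=lengthscale**2, tau2=tau2)


@dataclass(frozen=True)
class ParamBounds:
    """Box constraints for the MLE, as (low, high) pairs.

    Defaults follow the convention that sigma2 and tau2 scale with the
    response variance: pass ``ParamBounds.default(var_y)``.
    """

    sigma2: tuple[float, float]
    b: tuple[float, float]
    tau2: tuple[float, float]

    @classmethod
    def default(cls, var_y: float) -> "ParamBounds":
        v = max(float(var_y), 1e-8)
        return cls(
            sigma2=(1e-3 * v, 1e3 * v),
            b=(1e-2, 1e3),
            tau2=(1e-8 * v, 1.0 * v),
        )

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.sigma2[0], self.b[0], self.tau2[0]])
        hi = np.array([self.sigma2[1], self.b[1], self.tau2[1]])
        if np.any(lo <= 0) or np.any(hi < lo) or not np.all(np.isfinite(hi)):
            raise ValueError(f"bounds must be finite positive intervals: {self}")
        return lo, hi

    def contains(self, p: KernelParams, rtol: float = 1e-6) -> bool:
        lo, hi = self.as_arrays()
        v = np.array([p.sigma2, p.b, p.tau2])
        return bool(np.all(v >= lo * (1 - rtol)) and np.all(v <= hi * (1 + rtol)))


def _as_design(A: np.ndarray, name: str = "design") -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if A.ndim != 2 or A.shape[1] < 1:
        raise ValueError(f"{name} must be a 2-D matrix with >= 1 column, got shape {A.shape}")
    return A


def rbf_kernel(A: np.ndarray, B: np.ndarray, params: KernelParams) -> np.ndarray:
    """Evaluate the RBF kernel between the rows of two design matrices.

    Returns the m x r matrix with entries
    ``sigma2 * exp(-||A_i - B_k||^2 / (2 b))``. The nugget is *not* added
    here; callers add ``tau2`` to the diagonal of square Gram matrices.
    """
    A = _as_design(A, "A")
    B = _as_design(B, "B")
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"column mismatch: A has {A.shape[1]} columns, B has {B.shape[1]}")
    d2 = cdist(A, B, metric="sqeuclidean")
    return params.sigma2 * np.exp(-d2 / (2.0 * params.b))


def _gram(X: np.ndarray, params: KernelParams, d2: np.ndarray | None = None) -> np.ndarray:
    if d2 is None:
        d2 = cdist(X, X, metric="sqeuclidean")
    K = params.sigma2 * np.exp(-d2 / (2.0 * params.b))
    diag = params.tau2 + JITTER * params.sigma2
    K[np.diag_indices_from(K)] += diag
    return K


def _chol_with_jitter(K: np.ndarray, sigma2: float):
    """Cholesky of K, escalating diagonal jitter up to 1e-4*sigma2 on failure."""
    jitter = 0.0
    for _ in range(5):
        try:
            return linalg.cholesky(K + jitter * np.eye(K.shape[0]), lower=True)
        except linalg.LinAlgError:
            jitter = max(jitter * 10.0, JITTER * sigma2 * 10.0)
    raise GPNumericalError(
        f"Gram matrix not positive definite after maximal jitter ({jitter:.3g})"
    )


def log_marginal_likelihood(
    X: np.ndarray, Y: np.ndarray, params: KernelParams
) -> float:
    """log N(Y | 0, K(X, X) + tau2 I) for a centered response vector Y."""
    X = _as_design(X, "X")
    Y = np.asarray(Y, dtype=float).ravel()
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError(f"X has {n} rows but Y has {Y.shape[0]} entries")
    K = _gram(X, params)
    try:
        L = _chol_with_jitter(K, params.sigma2)
    except GPNumericalError as e:
        raise GPNumericalError(f"{e}; params={params}") from e
    alpha = linalg.cho_solve((L, True), Y)
    return float(
        -0.5 * Y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * math.log(2 * math.pi)
    )


def _nll_and_grad(z: np.ndarray, d2: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative log marginal likelihood and gradient in z = log(sigma2, b, tau2).

    Uses d/dtheta log p = 0.5 tr((alpha alpha^T - K^{-1}) dK/dtheta).
    """
    sigma2, b, tau2 = np.exp(z)
    n = Y.shape[0]
    E = np.exp(-d2 / (2.0 * b))
    K = sigma2 * E
    diag = tau2 + JITTER * sigma2
    K[np.diag_indices_from(K)] += diag
    try:
        L = linalg.cholesky(K, lower=True)
    except linalg.LinAlgError:
        return np.inf, np.zeros(3)
    alpha = linalg.cho_solve((L, True), Y)
    nll = 0.5 * Y @ alpha + np.sum(np.log(np.diag(L))) + 0.5 * n * math.log(2 * math.pi)
    Kinv = linalg.cho_solve((L, True), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv  # d(logp)/dK up to the trace pairing
    # dK/dlog(sigma2) = sigma2*E + jitter*sigma2*I; dK/dlog(b) = K_rbf * d2/(2b);
    # dK/dlog(tau2) = tau2*I
    g_sigma2 = 0.5 * (np.sum(W * (sigma2 * E)) + JITTER * sigma2 * np.trace(W))
    g_b = 0.5 * np.sum(W * (sigma2 * E * (d2 / (2.0 * b))))
    g_tau2 = 0.5 * tau2 * np.trace(W)
    return float(nll), -np.array([g_sigma2, g_b, g_tau2])


@dataclass
class GPModel:
    """A fitted zero-mean GP: hyperparameters, training data and solve cache.

    ``train_targets`` are stored centered; ``y_offset`` is re-added by
    :func:`blup_predict`.
    """

    params: KernelParams
    train_inputs: np.ndarray
    train_targets: np.ndarray
    y_offset: float = 0.0
    log_marginal: float = float("-inf")
    _chol: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _alpha: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.train_inputs = _as_design(self.train_inputs, "train_inputs")
        self.train_targets = np.asarray(self.train_targets, dtype=float).ravel()
        if self.train_targets.shape[0] != self.train_inputs.shape[0]:
            raise ValueError("train_inputs and train_targets length mismatch")
        if self._chol is None:
            K = _gram(self.train_inputs, self.params)
            self._chol = _chol_with_jitter(K, self.params.sigma2)
            self._alpha = linalg.cho_solve((self._chol, True), self.train_targets)

    @property
    def n(self) -> int:
        return self.train_inputs.shape[0]


def fit_gp_mle(
    X: np.ndarray,
    Y: np.ndarray,
    bounds: ParamBounds | None = None,
    restarts: int = 3,
    seed: int | np.random.Generator | None = None,
    init: KernelParams | None = None,
    maxiter: int = 100,
) -> GPModel:
    """Fit RBF-GP hyperparameters by bounded maximum marginal likelihood.

    Runs L-BFGS-B on log-parameters from ``restarts`` starting points (a
    moment-based heuristic start, plus log-uniform random draws inside the
    box; ``init``, when given, replaces the heuristic start — used for
    warm-starting across clustering iterations). Deterministic given ``seed``.

    Raises an empty-cluster ``ValueError`` for n = 0 and
    :class:`GPNumericalError` if every start fails.
    """
    X = _as_design(X, "X")
    Y = np.asarray(Y, dtype=float).ravel()
    n = X.shape[0]
    if n == 0:
        raise ValueError("cannot fit a GP on an empty cluster (n=0)")
    if Y.shape[0] != n:
        raise ValueError(f"X has {n} rows but Y has {Y.shape[0]} entries")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")

    offset = float(Y.mean())
    Yc = Y - offset
    var_y = float(Yc.var())
    if bounds is None:
        bounds = ParamBounds.default(var_y if var_y > 0 else 1.0)
    lo, hi = bounds.as_arrays()
    log_lo, log_hi = np.log(lo), np.log(hi)

    d2 = cdist(X, X, metric="sqeuclidean")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    starts: list[np.ndarray] = []
    if init is not None:
        z0 = np.log(np.clip([init.sigma2, init.b, init.tau2], lo, hi))
        starts.append(z0)
    else:
        # heuristic: sigma2 ~ var(y), b ~ median squared distance, tau2 ~ 10% var(y)
        med = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
        z0 = np.log(np.clip([max(var_y, lo[0]), med, 0.1 * max(var_y, lo[0])], lo, hi))
        starts.append(z0)
    for _ in range(restarts - 1):
        starts.append(rng.uniform(log_lo, log_hi))

    best_z, best_nll = None, np.inf
    for z0 in starts:
        res = optimize.minimize(
            _nll_and_grad,
            z0,
            args=(d2, Yc),
            jac=True,
            method="L-BFGS-B",
            bounds=list(zip(log_lo, log_hi)),
            options={"maxiter": maxiter},
        )
        if np.isfinite(res.fun) and res.fun < best_nll:
            best_nll, best_z = float(res.fun), res.x
    if best_z is None:
        raise GPNumericalError("all MLE restarts failed to produce a finite likelihood")

    sigma2, b, tau2 = np.exp(np.clip(best_z, log_lo, log_hi))
    params = KernelParams(sigma2=sigma2, b=b, tau2=tau2)
    return GPModel(
        params=params,
        train_inputs=X,
        train_targets=Yc,
        y_offset=offset,
        log_marginal=-best_nll,
    )


def blup_predict(model: GPModel, Xstar: np.ndarray) -> np.ndarray:
    """BLUP / posterior mean at new inputs: K(X*,X) (K+tau2 I)^{-1} Y + offset."""
    Xstar = _as_design(Xstar, "Xstar")
    if Xstar.shape[1] != model.train_inputs.shape[1]:
        raise ValueError(
            f"Xstar has {Xstar.shape[1]} columns, model expects {model.train_inputs.shape[1]}"
        )
    if Xstar.shape[0] == 0:
        return np.empty(0)
    Kstar = rbf_kernel(Xstar, model.train_inputs, model.params)
    return Kstar @ model._alpha + model.y_offset
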