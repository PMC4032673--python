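"""Polynomial smooth support vector machine (PSSVM).

The linear SVM with hinge loss is recast as an unconstrained, twice
continuously differentiable, strictly convex minimization by replacing the
plus function x+ = max(x, 0) with a piecewise-cubic surrogate

    h(x, k) = x                                   if x > 1/k,
              -(k^3/16) (x + 1/k)^3 (x - 3/k)     if |x| <= 1/k,
              0                                   if x < -1/k,

which matches x+ exactly outside [-1/k, 1/k] and deviates by at most
3/(16 k), attained at x = 0.  With samples a_i (rows of A), labels
l_i in {+1, -1} and margins r_i = 1 - l_i (a_i^T w - gamma), the training
problem is

    min_{w, gamma}  F = (nu/2) sum_i h(r_i, k)^2 + (1/2)(||w||^2 + gamma^2).

F is strictly convex (the regularizer contributes the identity to the
Hessian), so a damped Newton method from any starting point finds the
unique global minimizer; here Newton's method with Armijo backtracking is
used, the standard solver for smooth SVM objectives.  Prediction is
sign(x^T w - gamma) with sign(0) mapped to +1.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .errors import InvalidHyperparameterError, InvalidInputError, SplitError

__all__ = [
    "LabeledDataset",
    "PssvmHyperparams",
    "SolverConfig",
    "PssvmModel",
    "smooth_plus",
    "smooth_plus_d1",
    "smooth_plus_d2",
    "objective",
    "gradient_hessian",
    "train",
    "fit_classifier",
    "predict",
    "decision_function",
    "split_train_test",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class LabeledDataset:
    """Feature matrix with +/-1 labels (+1 = male, -1 = female).

    ``groups`` optionally carries subject identifiers for bookkeeping; it is
    never used by the solver.
    """

    X: np.ndarray  # m x n feature matrix
    y: np.ndarray  # length-m labels in {+1, -1}
    feature_names: tuple[str, ...] | None = None
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise InvalidInputError(f"X must be 2-D, got shape {self.X.shape}")
        if self.y.shape != (self.X.shape[0],):
            raise InvalidInputError(
                f"labels shape {self.y.shape} does not match {self.X.shape[0]} samples"
            )
        if not np.isfinite(self.X).all():
            raise InvalidInputError("non-finite feature values")
        if not np.isin(self.y, (-1, 1)).all():
            raise InvalidInputError("labels must be +1 or -1")
        self.y = self.y.astype(np.int64)

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            X=self.X[idx],
            y=self.y[idx],
            feature_names=self.feature_names,
            groups=None if self.groups is None else np.asarray(self.groups)[idx],
        )


@dataclass(frozen=True)
class PssvmHyperparams:
    """Penalty weight nu > 0 and smoothing sharpness k > 0."""

    nu: float = 100.0
    k: float = 10.0

    def __post_init__(self) -> None:
        if not (self.nu > 0):
            raise InvalidHyperparameterError(f"nu must be > 0, got {self.nu}")
        if not (self.k > 0):
            raise InvalidHyperparameterError(f"k must be > 0, got {self.k}")


@dataclass(frozen=True)
class SolverConfig:
    """Newton-Armijo settings: tolerance on ||grad F||, iteration caps."""

    tol: float = 1e-8
    max_iter: int = 100
    armijo_sigma: float = 1e-4
    max_backtracks: int = 30


@dataclass
class PssvmModel:
    """A trained separating plane x^T omega = gamma with its provenance.

    When ``mean`` / ``scale`` are set, inputs are z-scored with them before
    the plane is applied (the statistics come from the training split).
    """

    omega: np.ndarray
    gamma: float
    hyperparams: PssvmHyperparams
    converged: bool
    final_gradient_norm: float
    n_iter: int = 0
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None
    feature_names: tuple[str, ...] | None = None

    def to_dict(self) -> dict:
        d = {
            "omega": list(map(float, self.omega)),
            "gamma": float(self.gamma),
            "nu": self.hyperparams.nu,
            "k": self.hyperparams.k,
            "converged": bool(self.converged),
            "gradient_norm": float(self.final_gradient_norm),
            "n_iter": int(self.n_iter),
            "standardization": None,
            "feature_names": list(self.feature_names) if self.feature_names else None,
        }
        if self.mean is not None:
            d["standardization"] = {
                "mean": list(map(float, self.mean)),
                "sd": list(map(float, self.scale)),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PssvmModel":
        std = d.get("standardization")
        return cls(
            omega=np.asarray(d["omega"], dtype=np.float64),
            gamma=float(d["gamma"]),
            hyperparams=PssvmHyperparams(nu=d["nu"], k=d["k"]),
            converged=bool(d["converged"]),
            final_gradient_norm=float(d["gradient_norm"]),
            n_iter=int(d.get("n_iter", 0)),
            mean=None if std is None else np.asarray(std["mean"], dtype=np.float64),
            scale=None if std is None else np.asarray(std["sd"], dtype=np.float64),
            feature_names=tuple(d["feature_names"]) if d.get("feature_names") else None,
        )


# ---------------------------------------------------------------------------
# smoothing function and derivatives
# ---------------------------------------------------------------------------

def _check_k(k: float) -> float:
    if not (k > 0):
        raise InvalidHyperparameterError(f"smoothing parameter k must be > 0, got {k}")
    return float(k)


def _piecewise(x, k: float, mid_fn, upper):
    k = _check_k(k)
    x_arr = np.asarray(x, dtype=np.float64)
    inv = 1.0 / k
    out = np.zeros_like(x_arr)
    hi = x_arr > inv
    out[hi] = upper(x_arr[hi])
    mid = ~hi & (x_arr >= -inv)
    out[mid] = mid_fn(x_arr[mid], k, inv)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def smooth_plus(x, k: float):
    """Piecewise-cubic smooth surrogate h(x, k) of the plus function.

    Equals x for x > 1/k, 0 for x < -1/k, and the quartic-free cubic
    -(k^3/16)(x + 1/k)^3 (x - 3/k) in between; C^1 everywhere with
    h(+-1/k) = {1/k, 0} matching the outer branches.
    """
    return _piecewise(
        x, k,
        lambda t, k_, inv: -(k_**3 / 16.0) * (t + inv) ** 3 * (t - 3.0 * inv),
        lambda t: t,
    )


def smooth_plus_d1(x, k: float):
    """First derivative of ``smooth_plus`` (continuous; 1 above, 0 below)."""
    return _piecewise(
        x, k,
        lambda t, k_, inv: -(k_**3 / 4.0) * (t + inv) ** 2 * (t - 2.0 * inv),
        lambda t: np.ones_like(t),
    )


def smooth_plus_d2(x, k: float):
    """Second derivative of ``smooth_plus`` on each piece.

    The boundary points +-1/k are assigned to the middle piece, where the
    polynomial value is 0 anyway, so the choice is measure-zero and the
    result is continuous.  Nonnegative everywhere: h is convex.
    """
    return _piecewise(
        x, k,
        lambda t, k_, inv: -(3.0 * k_**3 / 4.0) * (t + inv) * (t - inv),
        lambda t: np.zeros_like(t),
    )


# ---------------------------------------------------------------------------
# objective, derivatives, solver
# ---------------------------------------------------------------------------

def _margins(omega: np.ndarray, gamma: float, data: LabeledDataset) -> np.ndarray:
    omega = np.asarray(omega, dtype=np.float64)
    if omega.shape != (data.n,):
        raise InvalidInputError(
            f"omega has shape {omega.shape}, expected ({data.n},)"
        )
    return 1.0 - data.y * (data.X @ omega - gamma)


def objective(
    omega: np.ndarray, gamma: float, data: LabeledDataset, hp: PssvmHyperparams
) -> float:
    """F(omega, gamma) = (nu/2) ||h(r, k)||^2 + (1/2)(||omega||^2 + gamma^2)."""
    r = _margins(omega, gamma, data)
    hv = smooth_plus(r, hp.k)
    omega = np.asarray(omega, dtype=np.float64)
    return float(0.5 * hp.nu * hv @ hv + 0.5 * (omega @ omega + gamma * gamma))


def gradient_hessian(
    omega: np.ndarray, gamma: float, data: LabeledDataset, hp: PssvmHyperparams
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient and (generalized) Hessian of F w.r.t. (omega, gamma).

    With theta = (omega, gamma), r_i = 1 - l_i (a_i^T omega - gamma) and
    c_i = -l_i (a_i, -1) = dr_i/dtheta:

        grad F = nu sum_i h(r_i) h'(r_i) c_i + theta
        Hess F = nu sum_i [h'(r_i)^2 + h(r_i) h''(r_i)] c_i c_i^T + I

    The loss term is positive semidefinite (h >= 0 and h'' >= 0), so the
    Hessian's smallest eigenvalue is at least 1.
    """
    r = _margins(omega, gamma, data)
    k = hp.k
    hv = smooth_plus(r, k)
    h1 = smooth_plus_d1(r, k)
    h2 = smooth_plus_d2(r, k)
    # c_i = -l_i * (a_i, -1): stack as rows of C (m x (n+1))
    C = np.empty((data.m, data.n + 1))
    C[:, : data.n] = -data.y[:, None] * data.X
    C[:, data.n] = data.y
    theta = np.concatenate([np.asarray(omega, dtype=np.float64), [float(gamma)]])
    grad = hp.nu * (C.T @ (hv * h1)) + theta
    w = h1 * h1 + hv * h2  # >= 0 elementwise
    hess = hp.nu * (C.T * w) @ C + np.eye(data.n + 1)
    return grad, hess


def train(
    data: LabeledDataset,
    hp: PssvmHyperparams = PssvmHyperparams(),
    config: SolverConfig = SolverConfig(),
    x0: np.ndarray | None = None,
) -> PssvmModel:
    """Minimize F by Newton's method with Armijo backtracking.

    Starts at (omega, gamma) = 0 unless ``x0`` is given; since F is
    strictly convex the start point only affects the iteration count, not
    the result.  Returns a model with ``converged=False`` (and a warning)
    if ||grad F|| has not fallen below ``config.tol`` after
    ``config.max_iter`` Newton steps.
    """
    if data.m < 2:
        raise InvalidInputError("need at least two samples to train")
    if len(np.unique(data.y)) < 2:
        raise InvalidInputError("training data must contain both classes")
    theta = np.zeros(data.n + 1) if x0 is None else np.asarray(x0, dtype=np.float64)
    if theta.shape != (data.n + 1,):
        raise InvalidInputError(f"x0 must have shape ({data.n + 1},)")

    grad_norm = math.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, config.max_iter + 1):
        omega, gamma = theta[:-1], theta[-1]
        grad, hess = gradient_hessian(omega, gamma, data, hp)
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm <= config.tol:
            converged = True
            n_iter -= 1
            break
        step = linalg.cho_solve(linalg.cho_factor(hess), -grad)
        f0 = objective(omega, gamma, data, hp)
        slope = float(grad @ step)  # < 0 for a descent direction
        # near the minimizer the predicted decrease falls below the floating-
        # point resolution of F; allow that much slack so the full Newton step
        # (quadratically convergent there) is not rejected on rounding noise
        f_noise = 10.0 * np.finfo(np.float64).eps * max(1.0, abs(f0))
        t = 1.0
        for _ in range(config.max_backtracks):
            trial = theta + t * step
            trial_f = objective(trial[:-1], trial[-1], data, hp)
            if trial_f <= f0 + config.armijo_sigma * t * slope + f_noise:
                break
            t *= 0.5
        theta = theta + t * step
    else:
        # loop exhausted: re-check optimality at the final iterate
        grad, _ = gradient_hessian(theta[:-1], theta[-1], data, hp)
        grad_norm = float(np.linalg.norm(grad))
        converged = grad_norm <= config.tol

    if not converged:
        warnings.warn(
            f"PSSVM solver did not converge: ||grad|| = {grad_norm:.3e} "
            f"after {config.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return PssvmModel(
        omega=theta[:-1].copy(),
        gamma=float(theta[-1]),
        hyperparams=hp,
        converged=converged,
        final_gradient_norm=grad_norm,
        n_iter=n_iter,
        feature_names=data.feature_names,
    )


def fit_classifier(
    data: LabeledDataset,
    hp: PssvmHyperparams = PssvmHyperparams(),
    config: SolverConfig = SolverConfig(),
    standardize: bool = True,
) -> PssvmModel:
    """Standardize features on the training data, then train.

    Raw pixel-scale features (hundreds of px) would dominate the fixed unit
    regularizer, so each column is z-scored with statistics computed on the
    training split only; the statistics are stored in the model and applied
    automatically at prediction time.  Columns with zero spread get scale 1.
    """
    if not standardize:
        return train(data, hp, config)
    mean = data.X.mean(axis=0)
    scale = data.X.std(axis=0)
    scale[scale == 0] = 1.0
    z = LabeledDataset(
        X=(data.X - mean) / scale,
        y=data.y,
        feature_names=data.feature_names,
    )
    model = train(z, hp, config)
    model.mean = mean
    model.scale = scale
    return model


# ---------------------------------------------------------------------------
# prediction and splitting
# ---------------------------------------------------------------------------

def decision_function(model: PssvmModel, features: np.ndarray) -> np.ndarray:
    """Signed distance surrogate x^T omega - gamma (standardized if fitted so)."""
    x = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if x.shape[1] != model.omega.shape[0]:
        raise InvalidInputError(
            f"feature dimension {x.shape[1]} does not match model "
            f"dimension {model.omega.shape[0]}"
        )
    if model.mean is not None:
        x = (x - model.mean) / model.scale
    return x @ model.omega - model.gamma


def predict(model: PssvmModel, features: np.ndarray) -> np.ndarray:
    """Classify feature vectors: sign(x^T omega - gamma), with sign(0) -> +1."""
    scores = decision_function(model, features)
    labels = np.where(scores >= 0.0, 1, -1).astype(np.int64)
    if np.ndim(features) == 1:
        return labels[0]
    return labels


def split_train_test(
    dataset: LabeledDataset, train_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Uniform random split without replacement; ceil(fraction*m) train rows.

    Reproducible from ``seed``.  Raises :class:`SplitError` if the training
    side would be empty or single-class (retry with another seed or a
    larger fraction).
    """
    if not (0.0 < train_fraction < 1.0):
        raise InvalidInputError(f"train_fraction must be in (0, 1), got {train_fraction}")
    m = dataset.m
    n_train = math.ceil(train_fraction * m)
    if n_train >= m:
        raise SplitError("split leaves no test samples; lower the fraction")
    perm = np.random.default_rng(seed).permutation(m)
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    train_set = dataset.subset(train_idx)
    if train_set.m == 0 or len(np.unique(train_set.y)) < 2:
        raise SplitError(
            "training split is empty or single-class; retry with another seed "
            "or a larger train_fraction"
        )
    return train_set, dataset.subset(test_idx)
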