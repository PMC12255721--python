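"""Gaussian-process surrogates over the encoded candidate pool.

One independent GP regressor is fitted per objective (AP yield, AP
selectivity, ...).  Inputs are the pool's [0, 1]-scaled features; targets are
standardized per objective before fitting and all posteriors are reported in
original AP units.  The kernel is a Matern 5/2 with independent per-dimension
length scales (bounded away from zero so one-hot geometry cannot collapse a
dimension) plus a fitted white-noise term with a floor of 1e-4 in
standardized units.  Hyperparameters maximize the marginal likelihood from a
seeded multi-start, so refitting with identical inputs and seed reproduces
identical hyperparameters.

Replicate observations (duplicate condition ids) are kept as separate rows;
the fitted noise term absorbs the scatter.

Beyond the scikit-learn fit, this module carries its own posterior linear
algebra (means, covariances, cross-covariances between arbitrary candidate
subsets) so acquisition functions can draw joint samples and condition on
pending batch picks without ever forming the full pool covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, Matern, WhiteKernel

from .space import CandidatePool

__all__ = [
    "ObservationSet",
    "ObjectivePosterior",
    "SurrogateModel",
    "Posterior",
    "fit",
    "predict",
    "sample_posterior",
]

NOISE_FLOOR = 1e-4  # standardized units
JITTER_START = 1e-10
JITTER_CAP = 1e-4  # documented escalation cap; singular beyond this is an error
MAX_OPT_ITER = 50  # L-BFGS iterations per hyperparameter start


class _FastMatern:
    """ARD Matern 5/2 (signal variance included) evaluated with BLAS-based
    squared distances; numerically equivalent to the fitted sklearn kernel's
    signal part but an order of magnitude faster on large cross-covariance
    blocks."""

    def __init__(self, signal_var: float, length_scale: np.ndarray):
        self.signal_var = float(signal_var)
        self.length_scale = np.atleast_1d(np.asarray(length_scale, dtype=float))

    def __call__(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        A = X / self.length_scale
        B = Y / self.length_scale
        d = A @ B.T
        d *= -2.0
        d += np.sum(A * A, axis=1)[:, None]
        d += np.sum(B * B, axis=1)[None, :]
        np.clip(d, 0.0, None, out=d)
        np.sqrt(d, out=d)
        d *= np.sqrt(5.0)
        k = d * d
        k /= 3.0
        k += d
        k += 1.0
        np.negative(d, out=d)
        np.exp(d, out=d)
        k *= d
        k *= self.signal_var
        return k

    def diag(self, X: np.ndarray) -> np.ndarray:
        return np.full(X.shape[0], self.signal_var)


@dataclass
class ObservationSet:
    """Measured objective vectors for pool conditions (the GP training data)."""

    condition_ids: np.ndarray
    Y: np.ndarray
    objective_names: tuple[str, ...]
    iteration_tags: np.ndarray | None = None

    def __post_init__(self):
        self.condition_ids = np.asarray(self.condition_ids, dtype=int)
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.Y.shape[0] != self.condition_ids.shape[0]:
            raise ValueError("Y rows must match condition ids")
        if self.Y.shape[1] != len(self.objective_names):
            raise ValueError("Y columns must match declared objectives")
        if not np.isfinite(self.Y).all():
            raise ValueError("objective values must be finite")
        if self.iteration_tags is None:
            self.iteration_tags = np.ones(len(self.condition_ids), dtype=int)
        else:
            self.iteration_tags = np.asarray(self.iteration_tags, dtype=int)

    def __len__(self) -> int:
        return len(self.condition_ids)

    @property
    def n_objectives(self) -> int:
        return self.Y.shape[1]

    def validate_against(self, pool: CandidatePool) -> None:
        ids = self.condition_ids
        if len(ids) and (ids.min() < 0 or ids.max() >= len(pool)):
            raise ValueError("observation ids outside the candidate pool")

    def extended(self, ids, Y, iteration: int) -> "ObservationSet":
        ids = np.asarray(ids, dtype=int)
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        return ObservationSet(
            condition_ids=np.concatenate([self.condition_ids, ids]),
            Y=np.vstack([self.Y, Y]) if len(self) else Y,
            objective_names=self.objective_names,
            iteration_tags=np.concatenate(
                [self.iteration_tags, np.full(len(ids), iteration, dtype=int)]
            ),
        )


def _jittered_cholesky(A: np.ndarray, allow_eigh: bool = False) -> np.ndarray:
    """Lower Cholesky factor with escalating diagonal jitter up to JITTER_CAP.

    With ``allow_eigh`` a severely rank-deficient (but PSD up to round-off)
    matrix falls back to an eigendecomposition factor instead of raising;
    used for posterior-covariance sampling where near-zero variance is
    legitimate.
    """
    jitter = 0.0
    scale = max(float(np.mean(np.diag(A))), 1.0)
    while True:
        try:
            return cholesky(A + jitter * scale * np.eye(A.shape[0]), lower=True)
        except Exception:
            jitter = JITTER_START if jitter == 0.0 else jitter * 100.0
            if jitter > JITTER_CAP:
                if allow_eigh:
                    w, V = np.linalg.eigh(A)
                    return V * np.sqrt(np.clip(w, 0.0, None))[None, :]
                raise np.linalg.LinAlgError(
                    f"kernel matrix singular even with jitter {JITTER_CAP:g}"
                )


@dataclass
class ObjectivePosterior:
    """Posterior algebra for a single objective's fitted GP.

    All public outputs are in original AP units; internal state is
    standardized.  ``kernel`` is the noise-free (signal) part of the fitted
    kernel.
    """

    kernel: object
    X_train: np.ndarray
    L: np.ndarray  # lower Cholesky of K_f(Xtr, Xtr) + noise I
    alpha_vec: np.ndarray  # (K + noise I)^{-1} y_std
    noise_level: float  # standardized units
    y_mean: float
    y_sd: float

    # --- standardized-scale posterior algebra (acquisition works on these) ---

    def mu_std(self, X: np.ndarray) -> np.ndarray:
        return self.kernel(X, self.X_train) @ self.alpha_vec

    def q_factor(self, X: np.ndarray) -> np.ndarray:
        """L^{-1} K_f(Xtr, X); cross/posterior covariances are built from these."""
        return solve_triangular(self.L, self.kernel(self.X_train, X), lower=True)

    def var_std(self, X: np.ndarray, Q: np.ndarray | None = None) -> np.ndarray:
        if Q is None:
            Q = self.q_factor(X)
        v = self.kernel.diag(X) - np.einsum("ij,ij->j", Q, Q)
        return np.clip(v, 0.0, None)

    def cov_std(self, Xa: np.ndarray, Xb: np.ndarray | None = None) -> np.ndarray:
        Qa = self.q_factor(Xa)
        if Xb is None:
            Xb, Qb = Xa, Qa
        else:
            Qb = self.q_factor(Xb)
        return self.kernel(Xa, Xb) - Qa.T @ Qb

    # --- original (AP) units ---

    def mean(self, X: np.ndarray) -> np.ndarray:
        return self.mu_std(X) * self.y_sd + self.y_mean

    def var(self, X: np.ndarray) -> np.ndarray:
        return self.var_std(X) * self.y_sd**2

    def cov(self, Xa: np.ndarray, Xb: np.ndarray | None = None) -> np.ndarray:
        return self.cov_std(Xa, Xb) * self.y_sd**2


@dataclass
class SurrogateModel:
    """Independent per-objective GPs sharing the pool's feature encoding."""

    objective_names: tuple[str, ...]
    posteriors: list[ObjectivePosterior]
    gprs: list[GaussianProcessRegressor] = field(repr=False, default_factory=list)
    train_ids: np.ndarray | None = None
    Y_train: np.ndarray | None = None  # observed targets (AP units)
    seed: int | None = None

    @property
    def n_objectives(self) -> int:
        return len(self.posteriors)

    def posterior_mean(self, pool: CandidatePool, ids) -> np.ndarray:
        X = pool.X[_check_ids(pool, ids)]
        return np.column_stack([p.mean(X) for p in self.posteriors])

    def posterior_var(self, pool: CandidatePool, ids) -> np.ndarray:
        X = pool.X[_check_ids(pool, ids)]
        return np.column_stack([p.var(X) for p in self.posteriors])

    def posterior_cov(self, pool: CandidatePool, ids_a, ids_b=None) -> np.ndarray:
        """Per-objective posterior covariance blocks (AP units), stacked on
        the first axis."""
        Xa = pool.X[_check_ids(pool, ids_a)]
        Xb = pool.X[_check_ids(pool, ids_b)] if ids_b is not None else None
        return np.stack([p.cov(Xa, Xb) for p in self.posteriors])


@dataclass
class Posterior:
    """Posterior summary over requested candidates, in AP units."""

    mean: np.ndarray  # (n, m)
    variance: np.ndarray  # (n, m)
    objective_names: tuple[str, ...]
    samples: np.ndarray | None = None  # (n_samples, n, m)


def _check_ids(pool: CandidatePool, ids) -> np.ndarray:
    ids = np.asarray(ids, dtype=int)
    if ids.size and (ids.min() < 0 or ids.max() >= len(pool)):
        raise ValueError("unknown pool id requested")
    return ids


def _make_kernel(n_features: int):
    if n_features == 0:
        signal = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(1.0)
    else:
        signal = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=np.ones(n_features),
            length_scale_bounds=(0.1, 100.0),
            nu=2.5,
        )
    return signal + WhiteKernel(noise_level=1e-2, noise_level_bounds=(NOISE_FLOOR, 10.0))


def _lbfgs_optimizer(obj_func, initial_theta, bounds):
    from scipy.optimize import minimize

    res = minimize(
        obj_func, initial_theta, method="L-BFGS-B", jac=True, bounds=bounds,
        options={"maxiter": MAX_OPT_ITER},
    )
    return res.x, res.fun


def fit(pool: CandidatePool, observations: ObservationSet, seed: int = 0,
        n_restarts: int = 1) -> SurrogateModel:
    """Fit one GP per objective by maximizing the marginal likelihood.

    Requires at least two observations.  Determinism: the multi-start
    hyperparameter optimization is keyed to ``seed``.
    """
    observations.validate_against(pool)
    if len(observations) < 2:
        raise ValueError("insufficient data: at least 2 observations required")
    X = pool.X[observations.condition_ids]
    posteriors: list[ObjectivePosterior] = []
    gprs: list[GaussianProcessRegressor] = []
    for j in range(observations.n_objectives):
        y = observations.Y[:, j]
        y_mean = float(y.mean())
        y_sd = float(y.std())
        if y_sd < 1e-12:
            y_sd = 1.0
        y_std = (y - y_mean) / y_sd
        gpr = GaussianProcessRegressor(
            kernel=_make_kernel(X.shape[1]),
            alpha=1e-10,
            normalize_y=False,
            optimizer=_lbfgs_optimizer,
            n_restarts_optimizer=n_restarts,
            random_state=(int(seed) + j) % (2**31 - 1),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gpr.fit(X, y_std)
        fitted_signal = gpr.kernel_.k1
        if isinstance(fitted_signal.k2, Matern):
            signal = _FastMatern(
                signal_var=float(fitted_signal.k1.constant_value),
                length_scale=fitted_signal.k2.length_scale,
            )
        else:  # zero-feature edge case keeps the sklearn kernel object
            signal = fitted_signal
        noise = float(gpr.kernel_.k2.noise_level)
        K = signal(X, X) + noise * np.eye(X.shape[0])
        L = _jittered_cholesky(K)
        alpha_vec = solve_triangular(
            L.T, solve_triangular(L, y_std, lower=True), lower=False
        )
        posteriors.append(
            ObjectivePosterior(
                kernel=signal,
                X_train=X.copy(),
                L=L,
                alpha_vec=alpha_vec,
                noise_level=noise,
                y_mean=y_mean,
                y_sd=y_sd,
            )
        )
        gprs.append(gpr)
    return SurrogateModel(
        objective_names=observations.objective_names,
        posteriors=posteriors,
        gprs=gprs,
        train_ids=observations.condition_ids.copy(),
        Y_train=observations.Y.copy(),
        seed=seed,
    )


def predict(model: SurrogateModel, pool: CandidatePool, ids) -> Posterior:
    """Posterior mean and variance (AP units) at the requested pool ids."""
    ids = _check_ids(pool, ids)
    return Posterior(
        mean=model.posterior_mean(pool, ids),
        variance=model.posterior_var(pool, ids),
        objective_names=model.objective_names,
    )


def sample_posterior(model: SurrogateModel, pool: CandidatePool, ids,
                     n_samples: int, seed: int = 0) -> np.ndarray:
    """Joint posterior samples over the requested ids, independent per objective.

    Returns an (n_samples, n_ids, n_objectives) array in AP units.  The joint
    covariance is factorized with escalating jitter; callers should request
    subsets rather than very large id sets (the full-pool matrix is never
    formed elsewhere in the package).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ids = _check_ids(pool, ids)
    X = pool.X[ids]
    rng = np.random.default_rng(seed)
    out = np.empty((n_samples, len(ids), model.n_objectives))
    for j, post in enumerate(model.posteriors):
        cov_std = post.cov_std(X)
        Lc = _jittered_cholesky(cov_std, allow_eigh=True)
        mean_std = post.mu_std(X)
        z = rng.standard_normal((n_samples, len(ids)))
        samples_std = mean_std[None, :] + z @ Lc.T
        out[:, :, j] = samples_std * post.y_sd + post.y_mean
    return out
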