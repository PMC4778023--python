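"""Optimization engines for the linearized DOT inverse problem.

SALSA (split augmented Lagrangian shrinkage, an ADMM variant) for
(nonnegative) l1-regularized least squares, the closed-form Tikhonov
baseline, and automatic regularization-weight selection by the
discrepancy principle.

The l1 weight lambda has a MAP interpretation: with Gaussian noise of
variance sigma^2 and a Laplacian image prior with sparsity parameter
alpha, the posterior mode solves the l1 problem with lambda = 2 sigma^2
alpha.  A physiologically plausible range of alpha therefore maps to a
lambda grid, and the discrepancy principle picks the member whose data
residual matches the known noise level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "SolverConfig",
    "LambdaGrid",
    "SalsaResult",
    "salsa_l1",
    "tikhonov",
    "select_lambda",
    "tikhonov_gamma_by_discrepancy",
    "default_alpha_grid",
]


@dataclass
class SolverConfig:
    """Settings shared by the iterative solvers.

    admm_mu is the augmented-Lagrangian penalty (results are insensitive
    to it within an order of magnitude); tol is the relative
    objective-change stopping tolerance; nonneg enforces x >= 0 via
    one-sided shrinkage.
    """

    lam: float = 0.0
    gamma: float = 0.0
    admm_mu: float = 1.0
    tol: float = 1e-5
    max_iter: int = 2000
    nonneg: bool = True

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.admm_mu > 0:
            raise ValueError("admm_mu must be positive")


@dataclass
class LambdaGrid:
    """Sparsity-parameter grid and the induced lambda grid (2 sigma^2 alpha)."""

    alphas: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.alphas.size == 0:
            raise ValueError("alpha grid must be nonempty")
        if np.any(self.alphas <= 0) or np.any(np.diff(self.alphas) <= 0):
            raise ValueError("alphas must be positive and strictly increasing")

    @property
    def lambdas(self) -> np.ndarray:
        return 2.0 * self.sigma2 * self.alphas


def default_alpha_grid(
    expected_contrast: float = 0.2,
    expected_volume_cm3: float = 0.4,
    n_points: int = 12,
    decades: float = 4.0,
) -> np.ndarray:
    """Log-spaced sparsity-parameter grid from coarse prior knowledge.

    Centered on 1/(expected contrast x expected object volume) — the
    reciprocal of the expected l1 mass of the image — and spanning
    ``decades`` decades, reflecting that clinical priors constrain the
    sparsity level only to within orders of magnitude.
    """
    center = 1.0 / (expected_contrast * expected_volume_cm3)
    half = decades / 2.0
    return center * np.logspace(-half, half, n_points)


@dataclass
class SalsaResult:
    x: np.ndarray
    objective_trace: np.ndarray = field(repr=False)
    n_iter: int = 0
    converged: bool = True

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


class _RidgeSolver:
    """Solves (A^T A + mu I) x = b, factoring once.

    Underdetermined systems go through the Woodbury identity with a
    Cholesky factorization of (A A^T + mu I); otherwise the normal
    matrix is factored directly.
    """

    def __init__(self, A: np.ndarray, mu: float):
        self.A = A
        self.mu = mu
        m, n = A.shape
        self.woodbury = m < n
        if self.woodbury:
            self.chol = cho_factor(A @ A.T + mu * np.eye(m))
        else:
            self.chol = cho_factor(A.T @ A + mu * np.eye(n))

    def solve(self, b: np.ndarray) -> np.ndarray:
        if self.woodbury:
            return (b - self.A.T @ cho_solve(self.chol, self.A @ b)) / self.mu
        return cho_solve(self.chol, b)


def _shrink(w: np.ndarray, thresh: float, nonneg: bool) -> np.ndarray:
    if nonneg:
        return np.maximum(w - thresh, 0.0)
    return np.sign(w) * np.maximum(np.abs(w) - thresh, 0.0)


def salsa_l1(
    A: np.ndarray,
    y: np.ndarray,
    cfg: SolverConfig,
    ridge: _RidgeSolver | None = None,
) -> SalsaResult:
    """Minimize ||Ax - y||^2 + lam ||x||_1 (s.t. x >= 0 when nonneg).

    ADMM splitting x = z: the x-update solves (A^T A + mu I)x = A^T y +
    mu (z - u) through a one-time factorization; the z-update is
    (one-sided) soft-thresholding with threshold lam/(2 mu).  Starts from
    the zero vector and stops when the relative change of the objective
    drops below cfg.tol.  A frozen sparse iterate (z bit-identical to the
    previous one, which makes the objective change exactly zero while the
    splitting variables are still moving) only counts as converged once
    the split has closed, ||x - z|| <= tol * max(1, ||z||); otherwise the
    transient plateau of an all-zero early iterate would stop the solver
    before it has done any work.  ``ridge`` lets callers reuse the
    factorization across lambda values.

    Returns the sparse iterate z (exact zeros, exact nonnegativity).
    """
    if cfg.lam < 0:
        raise ValueError("lam must be nonnegative")
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    mu = cfg.admm_mu
    if ridge is None:
        ridge = _RidgeSolver(A, mu)
    Aty = A.T @ y
    n = A.shape[1]
    z = np.zeros(n)
    u = np.zeros(n)
    thresh = cfg.lam / (2.0 * mu)

    def objective(v: np.ndarray) -> float:
        r = A @ v - y
        return float(r @ r + cfg.lam * np.abs(v).sum())

    trace = [objective(z)]
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        x = ridge.solve(Aty + mu * (z - u))
        z_new = _shrink(x + u, thresh, cfg.nonneg)
        u = u + x - z_new
        f = objective(z_new)
        trace.append(f)
        denom = max(abs(trace[-2]), np.finfo(float).tiny)
        if abs(f - trace[-2]) / denom < cfg.tol:
            moved = not np.array_equal(z_new, z)
            split_closed = np.linalg.norm(x - z_new) <= cfg.tol * max(
                1.0, float(np.linalg.norm(z_new))
            )
            if moved or split_closed:
                z = z_new
                converged = True
                break
        z = z_new
    if not converged:
        warnings.warn(
            f"SALSA did not converge within {cfg.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return SalsaResult(z, np.asarray(trace), n_iter=it, converged=converged)


def tikhonov(A: np.ndarray, y: np.ndarray, gamma: float) -> np.ndarray:
    """Closed-form l2-regularized solution x = A^T (A A^T + gamma I)^-1 y.

    The underdetermined (dual) form — the minimizer of
    ||Ax - y||^2 + gamma ||x||^2.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive (system singular at 0)")
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    m = A.shape[0]
    return A.T @ cho_solve(cho_factor(A @ A.T + gamma * np.eye(m)), y)


def select_lambda(
    A: np.ndarray,
    y: np.ndarray,
    sigma2: float,
    alphas: np.ndarray,
    cfg: SolverConfig,
):
    """Discrepancy-principle selection of the l1 weight.

    Maps each sparsity parameter alpha_i to lambda_i = 2 sigma^2 alpha_i,
    solves the l1 problem at every lambda_i, and returns the lambda whose
    per-channel mean squared residual ||y - A x||^2 / len(y) is closest
    to sigma^2 (ties toward smaller lambda).

    Returns
    -------
    lam : float
    info : dict with ``lambdas``, ``discrepancies``, ``solutions`` and the
        winning index ``best``.
    """
    if not sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    grid = LambdaGrid(alphas, sigma2)
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    ridge = _RidgeSolver(A, cfg.admm_mu)
    mq = len(y)
    discs = np.empty(grid.lambdas.size)
    sols = []
    for i, lam in enumerate(grid.lambdas):
        cfg_i = SolverConfig(
            lam=lam,
            admm_mu=cfg.admm_mu,
            tol=cfg.tol,
            max_iter=cfg.max_iter,
            nonneg=cfg.nonneg,
        )
        res = salsa_l1(A, y, cfg_i, ridge=ridge)
        r = y - A @ res.x
        discs[i] = r @ r / mq
        sols.append(res)
    best = int(np.argmin(np.abs(discs - sigma2)))  # first min = smallest lambda
    return float(grid.lambdas[best]), {
        "lambdas": grid.lambdas,
        "discrepancies": discs,
        "solutions": sols,
        "best": best,
    }


def tikhonov_gamma_by_discrepancy(
    A: np.ndarray,
    y: np.ndarray,
    sigma2: float,
    rel_tol: float = 1e-3,
    max_iter: int = 200,
) -> float:
    """Bisection on gamma so the Tikhonov mean squared residual hits sigma^2.

    The residual is monotone nondecreasing in gamma, from ~0 (gamma -> 0,
    full-row-rank A) up to ||y||^2/mq (x -> 0), so bisection in log gamma
    converges.  If sigma^2 lies outside the achievable range, the nearest
    endpoint is returned with a warning.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    mq = len(y)
    scale = float(np.linalg.norm(A, ord=2) ** 2)

    def resid(g: float) -> float:
        x = tikhonov(A, y, g)
        r = y - A @ x
        return float(r @ r / mq)

    lo, hi = 1e-12 * scale, 1e12 * scale
    r_lo, r_hi = resid(lo), resid(hi)
    if sigma2 <= r_lo:
        warnings.warn(
            "target sigma^2 below achievable residual; returning smallest gamma",
            RuntimeWarning,
            stacklevel=2,
        )
        return lo
    if sigma2 >= r_hi:
        warnings.warn(
            "target sigma^2 above achievable residual; returning largest gamma",
            RuntimeWarning,
            stacklevel=2,
        )
        return hi
    for _ in range(max_iter):
        mid = float(np.sqrt(lo * hi))
        r_mid = resid(mid)
        if abs(r_mid - sigma2) <= rel_tol * sigma2:
            return mid
        if r_mid < sigma2:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))
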