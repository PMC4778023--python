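"""Independent reference implementations used to cross-check the solvers.

Everything here is deliberately written from the textbook definitions,
sharing no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


def half_space_green_oracle(r1, r2, mua, musp, boundary_A=2.0):
    """Semi-infinite-medium CW Green's function, written out longhand."""
    D = 1.0 / (3.0 * (mua + musp))
    mu_eff = math.sqrt(mua / D)
    z_b = 2.0 * boundary_A * D

    def g_inf(dist):
        return math.exp(-mu_eff * dist) / (4.0 * math.pi * D * dist)

    r1 = np.asarray(r1, float)
    r2 = np.asarray(r2, float)
    mirror = r2.copy()
    mirror[2] = -2.0 * z_b - r2[2]
    return g_inf(float(np.linalg.norm(r1 - r2))) - g_inf(
        float(np.linalg.norm(r1 - mirror))
    )


def fista_l1(A, y, lam, nonneg, tol=1e-12, max_iter=100_000):
    """Accelerated proximal-gradient (FISTA) for
    min ||Ax - y||^2 + lam * ||x||_1  (s.t. x >= 0 when nonneg).

    Gradient of the smooth part is 2 A^T (Ax - y); Lipschitz constant
    L = 2 ||A||_2^2; the prox of (1/L) * lam * |.|_1 is soft-thresholding
    at lam/L (one-sided when nonneg).  Stops on the proximal-gradient
    fixed-point residual ||x - prox(x - step grad f(x))||, which vanishes
    exactly at minimizers (objective-change stops can fire on transient
    plateaus).
    """
    A = np.asarray(A, float)
    y = np.asarray(y, float)
    L = 2.0 * np.linalg.norm(A, ord=2) ** 2
    step = 1.0 / L
    thresh = step * lam

    def prox(v):
        if nonneg:
            return np.maximum(v - thresh, 0.0)
        return np.sign(v) * np.maximum(np.abs(v) - thresh, 0.0)

    def obj(v):
        r = A @ v - y
        return float(r @ r + lam * np.abs(v).sum())

    def pg_step(v):
        return prox(v - step * 2.0 * (A.T @ (A @ v - y)))

    x = np.zeros(A.shape[1])
    z = x.copy()
    t = 1.0
    for _ in range(max_iter):
        x_new = pg_step(z)
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t * t))
        z = x_new + (t - 1.0) / t_new * (x_new - x)
        x, t = x_new, t_new
        resid = float(np.linalg.norm(x - pg_step(x)))
        if resid <= tol * max(1.0, float(np.linalg.norm(x))):
            break
    return x, obj(x)


def tikhonov_normal_equations(A, y, gamma):
    """Primal (normal-equations) Tikhonov solution (A^T A + g I)^-1 A^T y."""
    A = np.asarray(A, float)
    n = A.shape[1]
    return np.linalg.solve(A.T @ A + gamma * np.eye(n), A.T @ y)
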