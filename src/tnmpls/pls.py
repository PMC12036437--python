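"""Two-block partial least squares with per-domain L1 sparsity.

The model decomposes two row-aligned data blocks, connectivity X (n, p)
and phenotype Y (n, q), as X = Phi P + E_X and Y = Psi C + E_Y, choosing
per-component weight vectors (u, v) that maximize the covariance between
the latent scores phi = X u and psi = Y v. The unregularized solution is
the leading singular pair of the cross-covariance M = X^T Y.

Sparsity is imposed per domain by an L1-ball radius lambda_D combined
with the unit L2 norm, ``||w||_2 = 1, ||w||_1 <= lambda_D`` with
``1 <= lambda_D <= |D|``; lambda_D = 1 forces a single nonzero weight
(maximal regularization) and lambda_D >= sqrt(|D|) is vacuous. The
constrained maximizer of z^T w is obtained by soft-thresholding z and
renormalizing, with the threshold found by bisection. Subsequent
components are fitted on residuals after projecting each block onto its
own latent scores (projection deflation), which makes within-domain
scores orthogonal across components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted


# ---------------------------------------------------------------------------
# constrained projection


def _soft_threshold(z: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - delta, 0.0)


def project_l1_ball_unit_sphere(
    z: np.ndarray, c: float, tol: float = 1e-10
) -> np.ndarray:
    """Maximize ``z^T w`` over ``||w||_2 = 1, ||w||_1 <= c``.

    Solved as ``w = S(z, delta) / ||S(z, delta)||_2`` where ``S`` is
    elementwise soft-thresholding and ``delta >= 0`` is the smallest
    threshold that meets the L1 bound (found by bisection; `tol` is the
    bisection tolerance on delta). With tied maximal entries and
    ``c`` below the reachable L1/L2 ratio, the lowest-index maximal
    coordinate is kept as a one-hot solution.
    """
    z = np.asarray(z, dtype=float)
    if not np.any(z):
        raise ValueError("cannot project the zero vector")
    if c < 1.0:
        raise ValueError(f"L1 radius must be >= 1, got {c}")
    w = z / np.linalg.norm(z)
    if np.abs(w).sum() <= c * (1 + 1e-12):
        return w
    a = np.abs(z)
    lo, hi = 0.0, a.max()
    while hi - lo > tol * max(1.0, a.max()):
        mid = 0.5 * (lo + hi)
        s = _soft_threshold(z, mid)
        nrm = np.linalg.norm(s)
        if nrm == 0 or np.abs(s).sum() / nrm > c:
            lo = mid
        else:
            hi = mid
    s = _soft_threshold(z, hi)
    nrm = np.linalg.norm(s)
    if nrm > 0 and np.abs(s).sum() / nrm <= c * (1 + 1e-8):
        return s / nrm
    # tied maxima below the reachable ratio: deterministic one-hot
    w = np.zeros_like(z)
    k = int(np.argmax(a))
    w[k] = np.sign(z[k])
    return w


# ---------------------------------------------------------------------------
# single components


@dataclass
class PLSComponent:
    """One fitted component: weights, latent scores, covariance."""

    u: np.ndarray  # connectivity weights, unit L2 norm
    v: np.ndarray  # phenotype weights, unit L2 norm
    x_scores: np.ndarray  # phi = X u
    y_scores: np.ndarray  # psi = Y v
    covariance: float  # u^T X^T Y v
    converged: bool = True
    n_iter: int = 0


def _fix_sign(u, v, phi, psi):
    # flip jointly so the largest-magnitude phenotype weight is positive;
    # ties resolve to the lowest index via argmax
    if v[int(np.argmax(np.abs(v)))] < 0:
        return -u, -v, -phi, -psi
    return u, v, phi, psi


def pls_svd_component(X: np.ndarray, Y: np.ndarray) -> PLSComponent:
    """Leading singular pair of the cross-covariance ``M = X^T Y``.

    Inputs must be column-centered; the covariance score equals the
    leading singular value of M.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0] or X.shape[0] < 2:
        raise ValueError("X and Y must share n >= 2 rows")
    M = X.T @ Y
    if not np.any(M):
        raise ValueError("cross-covariance is identically zero")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    u, v = U[:, 0], Vt[0]
    phi, psi = X @ u, Y @ v
    u, v, phi, psi = _fix_sign(u, v, phi, psi)
    return PLSComponent(u=u, v=v, x_scores=phi, y_scores=psi,
                        covariance=float(s[0]))


def rpls_component(
    X: np.ndarray,
    Y: np.ndarray,
    lambda_x: float | None = None,
    lambda_y: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    v_init: np.ndarray | None = None,
) -> PLSComponent:
    """One sparse component by alternating constrained power iterations.

    Alternates ``u <- proj(M v, lambda_x)`` and
    ``v <- proj(M^T u, lambda_y)`` until the max-norm weight change
    drops below `tol`. The constrained objective is non-convex, so the
    iterations are started from each right singular vector of
    ``M = X^T Y`` (up to the first eight) and the start with the
    highest covariance wins — a deterministic multistart with no
    randomness. `v_init`, when given, is tried as an additional start
    (used by the selection sweeps to warm-start along a lambda grid).
    ``lambda_* = None`` means no constraint for that domain (equivalent
    to lambda = |D|), in which case the leading singular pair is the
    exact solution and a single start suffices.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    p, q = X.shape[1], Y.shape[1]
    lam_x = float(p) if lambda_x is None else float(lambda_x)
    lam_y = float(q) if lambda_y is None else float(lambda_y)
    if not 1.0 <= lam_x <= p:
        raise ValueError(f"lambda_connectivity must lie in [1, {p}], got {lam_x}")
    if not 1.0 <= lam_y <= q:
        raise ValueError(f"lambda_phenotype must lie in [1, {q}], got {lam_y}")
    M = X.T @ Y
    if not np.any(M):
        raise ValueError("cross-covariance is identically zero")
    _, s, Vt = np.linalg.svd(M, full_matrices=False)
    unconstrained = lam_x >= np.sqrt(p) and lam_y >= np.sqrt(q)
    n_starts = 1 if unconstrained else min((s > 1e-12 * s[0]).sum(), 8)
    starts = [Vt[k] for k in range(n_starts)]
    if v_init is not None and not unconstrained:
        starts.append(np.asarray(v_init, dtype=float))

    best = None
    for v in starts:
        u = project_l1_ball_unit_sphere(M @ v, lam_x)
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            u_new = project_l1_ball_unit_sphere(M @ v, lam_x)
            v_new = project_l1_ball_unit_sphere(M.T @ u_new, lam_y)
            change = max(np.abs(u_new - u).max(), np.abs(v_new - v).max())
            u, v = u_new, v_new
            if change < tol:
                converged = True
                break
        cov = float(u @ M @ v)
        if best is None or cov > best[0] * (1 + 1e-12):
            best = (cov, u, v, converged, n_iter)
    cov, u, v, converged, n_iter = best
    if not converged:
        warnings.warn(
            f"sparse PLS component did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    phi, psi = X @ u, Y @ v
    u, v, phi, psi = _fix_sign(u, v, phi, psi)
    return PLSComponent(u=u, v=v, x_scores=phi, y_scores=psi,
                        covariance=cov,
                        converged=converged, n_iter=n_iter)


def deflate(X: np.ndarray, Y: np.ndarray, comp: PLSComponent):
    """Remove a component by projecting each block off its own scores.

    ``X_res = X - phi (phi^T phi)^{-1} phi^T X`` and likewise for Y, so
    residuals are exactly orthogonal to the removed latent scores.
    """
    phi, psi = comp.x_scores, comp.y_scores
    phi2, psi2 = phi @ phi, psi @ psi
    if phi2 == 0 or psi2 == 0:
        raise ValueError("zero-norm latent scores; cannot deflate")
    X_res = X - np.outer(phi, (phi @ X) / phi2)
    Y_res = Y - np.outer(psi, (psi @ Y) / psi2)
    return X_res, Y_res


# ---------------------------------------------------------------------------
# estimator


def _center_scale(A: np.ndarray, scale: bool, what: str):
    mean = A.mean(axis=0)
    if scale:
        sd = A.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"{what} column {int(bad[0])} is constant")
    else:
        sd = np.ones(A.shape[1])
    return (A - mean) / sd, mean, sd


class RegularizedPLS(BaseEstimator):
    """Sparse two-block PLS estimator.

    Parameters
    ----------
    n_components : int, default=4
        Number of deflation steps (components) to extract.
    lambda_connectivity : float or None, default=None
        L1 radius for the X-domain weights; None disables the
        constraint. Must lie in [1, p] when given.
    lambda_phenotype : float or None, default=None
        L1 radius for the Y-domain weights; None disables it.
    scale : bool, default=True
        Z-score the columns of both blocks (sample SD) before fitting;
        when False, columns are centered only.
    tol : float, default=1e-6
        Convergence tolerance on the max-norm weight change.
    max_iter : int, default=500
        Iteration cap per component.

    Attributes
    ----------
    x_weights_, y_weights_ : ndarray of shape (p, K) and (q, K)
        Unit-norm weight vectors per component.
    x_scores_, y_scores_ : ndarray of shape (n, K)
        Latent scores (phi, psi).
    covariances_ : ndarray of shape (K,)
        Covariance score per component (nonnegative after sign fixing).
    covariance_percentages_ : ndarray of shape (K,)
        Covariance scores relative to component 1, in percent
        (component 1 is 100 by definition).
    converged_ : ndarray of bool, shape (K,)
    x_residual_, y_residual_ : ndarray
        Post-deflation residual blocks (the implicit error terms).

    The solver is deterministic: initialization is the SVD of the
    cross-covariance and there is no randomness, so identical inputs
    produce bit-identical models.
    """

    def __init__(
        self,
        n_components: int = 4,
        lambda_connectivity: float | None = None,
        lambda_phenotype: float | None = None,
        scale: bool = True,
        tol: float = 1e-6,
        max_iter: int = 500,
    ):
        self.n_components = n_components
        self.lambda_connectivity = lambda_connectivity
        self.lambda_phenotype = lambda_phenotype
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, Y):
        X = check_array(np.asarray(X, dtype=float))
        Y = check_array(np.asarray(Y, dtype=float))
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        n, p = X.shape
        q = Y.shape[1]
        K = int(self.n_components)
        if K < 1 or K > min(p, q, n - 1):
            raise ValueError(
                f"n_components={K} exceeds min(p, q, n-1)={min(p, q, n - 1)}"
            )
        Xs, self.x_mean_, self.x_std_ = _center_scale(X, self.scale, "X")
        Ys, self.y_mean_, self.y_std_ = _center_scale(Y, self.scale, "Y")

        comps: list[PLSComponent] = []
        Xr, Yr = Xs, Ys
        for _ in range(K):
            comp = rpls_component(
                Xr, Yr,
                lambda_x=self.lambda_connectivity,
                lambda_y=self.lambda_phenotype,
                tol=self.tol, max_iter=self.max_iter,
            )
            comps.append(comp)
            Xr, Yr = deflate(Xr, Yr, comp)

        self.components_ = comps
        self.x_weights_ = np.column_stack([c.u for c in comps])
        self.y_weights_ = np.column_stack([c.v for c in comps])
        self.x_scores_ = np.column_stack([c.x_scores for c in comps])
        self.y_scores_ = np.column_stack([c.y_scores for c in comps])
        self.covariances_ = np.array([c.covariance for c in comps])
        self.covariance_percentages_ = (
            100.0 * self.covariances_ / self.covariances_[0]
        )
        self.converged_ = np.array([c.converged for c in comps])
        self.n_iter_ = [c.n_iter for c in comps]
        self.x_residual_, self.y_residual_ = Xr, Yr
        return self

    def transform(self, X, Y=None):
        """Project new observations onto the fitted weight vectors."""
        check_is_fitted(self, "x_weights_")
        Xs = (np.asarray(X, dtype=float) - self.x_mean_) / self.x_std_
        x_scores = Xs @ self.x_weights_
        if Y is None:
            return x_scores
        Ys = (np.asarray(Y, dtype=float) - self.y_mean_) / self.y_std_
        return x_scores, Ys @ self.y_weights_

    def fit_transform(self, X, Y):
        return self.fit(X, Y).x_scores_


def fit_rpls(
    X, Y,
    n_components: int = 4,
    lambda_connectivity: float | None = None,
    lambda_phenotype: float | None = None,
    **kwargs,
) -> RegularizedPLS:
    """Functional wrapper around :class:`RegularizedPLS`."""
    return RegularizedPLS(
        n_components=n_components,
        lambda_connectivity=lambda_connectivity,
        lambda_phenotype=lambda_phenotype,
        **kwargs,
    ).fit(X, Y)


# ---------------------------------------------------------------------------
# regularization selection


def _first_component_nnz(Xs, Ys, lambda_x, lambda_y, tol, max_iter,
                         v_init=None):
    comp = rpls_component(Xs, Ys, lambda_x=lambda_x, lambda_y=lambda_y,
                          tol=tol, max_iter=max_iter, v_init=v_init)
    return int(np.count_nonzero(comp.u)), int(np.count_nonzero(comp.v)), comp


def select_lambda_phenotype(
    X, Y,
    max_features: int = 3,
    grid_step: float = 0.1,
    lambda_connectivity: float | None = None,
    scale: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
):
    """Weakest phenotype regularization keeping component 1 sparse.

    Sweeps lambda over the grid ``1, 1+step, ..., q`` and returns the
    largest value for which the first component has at most
    `max_features` nonzero phenotype weights, together with the nonzero
    counts over the whole grid.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    q = Y.shape[1]
    Xs, _, _ = _center_scale(X, scale, "X")
    Ys, _, _ = _center_scale(Y, scale, "Y")
    grid = np.round(np.arange(1.0, q + grid_step / 2, grid_step), 10)
    nnz = np.empty(len(grid), dtype=int)
    prev = None
    for k, lam in enumerate(grid):
        # warm-start each fit from the previous grid point's solution
        _, nnz[k], comp = _first_component_nnz(
            Xs, Ys, lambda_connectivity, lam, tol, max_iter, v_init=prev
        )
        prev = comp.v
    ok = np.flatnonzero(nnz <= max_features)
    if ok.size == 0:
        raise ValueError(
            f"no grid value keeps the first component at <= {max_features} "
            "features"
        )
    record = pd.DataFrame({"lambda_phenotype": grid, "nnz_v1": nnz})
    return float(grid[ok[-1]]), record


def select_lambda_connectivity(
    X, Y,
    target_density: float = 0.5,
    n_grid: int = 100,
    lambda_phenotype: float | None = None,
    scale: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
):
    """Connectivity regularization matching a target coefficient density.

    Sweeps a log-spaced grid of `n_grid` values over ``[1, sqrt(p)]``
    (values above sqrt(p) are vacuous) and returns the lambda whose
    first-component nonzero fraction is closest to `target_density`;
    ties resolve to the smaller lambda.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    p = X.shape[1]
    Xs, _, _ = _center_scale(X, scale, "X")
    Ys, _, _ = _center_scale(Y, scale, "Y")
    grid = np.geomspace(1.0, np.sqrt(p), n_grid)
    density = np.empty(len(grid))
    prev = None
    for k, lam in enumerate(grid):
        nnz_u, _, comp = _first_component_nnz(Xs, Ys, lam, lambda_phenotype,
                                              tol, max_iter, v_init=prev)
        density[k] = nnz_u / p
        prev = comp.v
    best = int(np.argmin(np.abs(density - target_density)))
    record = pd.DataFrame({"lambda_connectivity": grid, "density_u1": density})
    return float(grid[best]), record
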