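"""Pathwise coordinate descent for the l1-penalized patch approximation.

For a fixed dictionary D the subproblem per patch is

    min_a  1/2 ||x - D a||^2 + lam ||a||_1

solved by cyclic coordinate descent with soft-thresholding updates on the
Gram matrix G = D'D, warm-started along a log-spaced lambda grid from
lambda_max (null solution) down to eps. The path is terminated early once
the objective stops changing between consecutive lambdas.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from numba import njit

__all__ = [
    "LassoPath",
    "lambda_max",
    "lasso_cd",
    "lasso_path",
    "kkt_violation",
]


@dataclasses.dataclass
class LassoPath:
    """Regularization path for one patch: per-lambda solutions and diagnostics."""

    lambdas: np.ndarray  # strictly decreasing, log-spaced
    alphas: np.ndarray  # (n_lambdas, p)
    objectives: np.ndarray  # 1/2 ||x - D a||^2 + lam ||a||_1
    rss: np.ndarray  # ||x - D a||^2
    dfs: np.ndarray  # nonzero counts
    converged: bool = True

    def __len__(self) -> int:
        return len(self.lambdas)


@njit(cache=True)
def _sweep(G, q, alpha, lam, active_only):  # pragma: no cover - jitted
    """One cyclic pass of soft-thresholding updates; q = D'x - G alpha is
    maintained in place so a coordinate visit costs O(1) plus O(p) only when
    the coefficient actually moves. Returns the largest coefficient change."""
    p = alpha.shape[0]
    max_delta = 0.0
    for j in range(p):
        if active_only and alpha[j] == 0.0:
            continue
        gjj = G[j, j]
        if gjj <= 1e-300:
            alpha[j] = 0.0
            continue
        u = q[j] + gjj * alpha[j]
        if u > lam:
            a_new = (u - lam) / gjj
        elif u < -lam:
            a_new = (u + lam) / gjj
        else:
            a_new = 0.0
        d = a_new - alpha[j]
        if d != 0.0:
            alpha[j] = a_new
            for k in range(p):
                q[k] -= G[j, k] * d
            ad = abs(d)
            if ad > max_delta:
                max_delta = ad
    return max_delta


@njit(cache=True)
def _cd_gram(G, q, alpha, lam, tol, max_sweeps):  # pragma: no cover - jitted
    """Cyclic coordinate descent with the active-set strategy: after every
    full pass, iterate on the current nonzero set until it is stable, then
    confirm with another full pass. Converged when a full pass moves no
    coefficient by more than tol. Inner iterations are capped between full
    passes so a slowly converging (e.g. rank-deficient) active subproblem
    cannot starve the full passes of the sweep budget. Returns sweeps used,
    or -1 if the budget ran out."""
    sweeps = 0
    inner_cap = 50
    while sweeps < max_sweeps:
        max_delta = _sweep(G, q, alpha, lam, False)
        sweeps += 1
        if max_delta < tol:
            return sweeps
        inner_used = 0
        while sweeps < max_sweeps and inner_used < inner_cap:
            inner = _sweep(G, q, alpha, lam, True)
            sweeps += 1
            inner_used += 1
            if inner < tol:
                break
    return -1


@njit(cache=True)
def _path_gram(G, c, xtx, lambdas, stop_tol, tol, max_sweeps, null_first):  # pragma: no cover
    """Warm-started path over an explicit lambda grid.

    ``null_first`` marks grids anchored at this problem's own lambda_max,
    where the first solution is exactly zero by construction. Returns the
    number of grid points actually computed (early termination)."""
    n_lam = lambdas.shape[0]
    p = c.shape[0]
    alphas = np.zeros((n_lam, p))
    objs = np.zeros(n_lam)
    rss = np.zeros(n_lam)
    dfs = np.zeros(n_lam, dtype=np.int64)
    alpha = np.zeros(p)
    q = c.copy()
    converged = True
    n_done = 0
    for s in range(n_lam):
        if not (null_first and s == 0):
            res = _cd_gram(G, q, alpha, lambdas[s], tol, max_sweeps)
            if res < 0:
                converged = False
        r2 = xtx - np.dot(c, alpha) - np.dot(q, alpha)
        if r2 < 0.0:
            r2 = 0.0
        l1 = np.abs(alpha).sum()
        objs[s] = 0.5 * r2 + lambdas[s] * l1
        rss[s] = r2
        dfs[s] = (alpha != 0.0).sum()
        alphas[s] = alpha
        n_done = s + 1
        if s >= 1 and stop_tol > 0.0:
            denom = max(1.0, abs(objs[s - 1]))
            if abs(objs[s] - objs[s - 1]) / denom < stop_tol:
                break
    return alphas, objs, rss, dfs, n_done, converged


def _atoms(D) -> np.ndarray:
    atoms = getattr(D, "atoms", D)
    return np.ascontiguousarray(np.asarray(atoms, dtype=np.float64))


def lambda_max(D, x) -> float:
    """Smallest lambda whose lasso solution is exactly zero: max_j |d_j' x|."""
    atoms = _atoms(D)
    x = np.asarray(x, dtype=np.float64)
    if atoms.shape[0] != x.shape[0]:
        raise ValueError(f"dimension mismatch: D is {atoms.shape}, x has {x.shape[0]}")
    return float(np.abs(atoms.T @ x).max())


def lasso_cd(
    D,
    x,
    lam: float,
    warm_start: np.ndarray | None = None,
    tol: float = 1e-8,
    max_sweeps: int = 1000,
) -> np.ndarray:
    """Solve one l1-penalized least squares problem by coordinate descent.

    Deterministic given inputs (cyclic coordinate order). On non-convergence
    after ``max_sweeps`` sweeps the current iterate is returned with a warning.
    """
    atoms = _atoms(D)
    x = np.asarray(x, dtype=np.float64)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    p = atoms.shape[1]
    alpha = (
        np.zeros(p) if warm_start is None else np.array(warm_start, dtype=np.float64)
    )
    G = atoms.T @ atoms
    c = atoms.T @ x
    q = c - G @ alpha
    res = _cd_gram(G, q, alpha, float(lam), float(tol), int(max_sweeps))
    if res < 0:
        warnings.warn(
            f"coordinate descent did not converge in {max_sweeps} sweeps",
            RuntimeWarning,
            stacklevel=2,
        )
    return alpha


def lambda_grid(lam_max: float, n_lambdas: int, eps_ratio: float) -> np.ndarray:
    if n_lambdas < 2:
        raise ValueError("n_lambdas must be at least 2")
    return np.geomspace(lam_max, eps_ratio * lam_max, n_lambdas)


def lasso_path(
    D,
    x,
    n_lambdas: int = 100,
    eps_ratio: float = 1e-3,
    stop_tol: float = 1e-5,
    tol: float = 1e-8,
    max_sweeps: int = 1000,
) -> LassoPath:
    """Full regularization path with warm starts and early termination.

    The grid is log-spaced from lambda_max(D, x) down to eps_ratio times it;
    the first entry is the exact null solution. The path stops once the
    relative objective change between consecutive lambdas drops below
    ``stop_tol``.
    """
    atoms = _atoms(D)
    x = np.asarray(x, dtype=np.float64)
    lam0 = lambda_max(atoms, x)
    if lam0 == 0.0:
        # degenerate input (x orthogonal to all atoms or zero): null path
        p = atoms.shape[1]
        xtx = float(x @ x)
        return LassoPath(
            lambdas=np.array([0.0]),
            alphas=np.zeros((1, p)),
            objectives=np.array([0.5 * xtx]),
            rss=np.array([xtx]),
            dfs=np.array([0]),
        )
    lambdas = lambda_grid(lam0, n_lambdas, eps_ratio)
    G = atoms.T @ atoms
    c = atoms.T @ x
    alphas, objs, rss, dfs, n_done, converged = _path_gram(
        G, c, float(x @ x), lambdas, float(stop_tol), float(tol), int(max_sweeps), True
    )
    if not converged:
        warnings.warn(
            "coordinate descent hit the sweep budget along the path",
            RuntimeWarning,
            stacklevel=2,
        )
    return LassoPath(
        lambdas=lambdas[:n_done],
        alphas=alphas[:n_done],
        objectives=objs[:n_done],
        rss=rss[:n_done],
        dfs=dfs[:n_done],
        converged=converged,
    )


def kkt_violation(D, x, alpha, lam: float) -> float:
    """Worst-case violation of the lasso stationarity conditions.

    For zero coefficients |d_j'r| must not exceed lam; for active ones
    d_j'r must equal lam * sign(alpha_j). Returns the largest deviation.
    """
    atoms = _atoms(D)
    x = np.asarray(x, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    corr = atoms.T @ (x - atoms @ alpha)
    active = alpha != 0.0
    viol = 0.0
    if np.any(~active):
        viol = max(viol, float(np.max(np.abs(corr[~active])) - lam))
    if np.any(active):
        viol = max(
            viol, float(np.max(np.abs(corr[active] - lam * np.sign(alpha[active]))))
        )
    return max(viol, 0.0)
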