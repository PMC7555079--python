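"""Per-patch choice of the l1 weight along a lasso path, by AIC or K-fold CV.

The AIC for normally distributed errors in least-squares problems is

    AIC(lam) = m * log(||x - D a(lam)||^2 / m) + 2 * df(lam)

with m the number of elements of the patch and df the exact nonzero count of
the coefficients (an unbiased estimator of the model degrees of freedom).
Cross-validation holds out random subsets of the *elements* of the patch,
predicting them from the rows of D that were retained, with a lambda grid
shared across folds (anchored at the full-data lambda_max) so the per-lambda
errors are comparable.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .sparse_coding import (
    LassoPath,
    _atoms,
    _path_gram,
    lambda_grid,
    lambda_max,
)

__all__ = ["SelectionResult", "aic_select", "cv_select"]

_RSS_FLOOR = 1e-300  # floor on ||r||^2 / m before the log, for exact fits


@dataclasses.dataclass
class SelectionResult:
    chosen_lambda: float
    chosen_alpha: np.ndarray
    criterion_values: np.ndarray  # per-lambda AIC value or CV mean squared error
    criterion: str  # "aic" or "cv"
    df: int
    chosen_index: int


def _argmin_prefer_sparser(values: np.ndarray, lambdas: np.ndarray) -> int:
    """Index of the minimum; exact ties resolve to the largest lambda."""
    best = np.min(values)
    tied = np.flatnonzero(values == best)
    return int(tied[np.argmax(lambdas[tied])])


def aic_values(path: LassoPath, m: int) -> np.ndarray:
    scaled = np.maximum(path.rss / m, _RSS_FLOOR)
    return m * np.log(scaled) + 2.0 * path.dfs


def aic_select(path: LassoPath, x, D=None) -> SelectionResult:
    """Pick the path point minimizing the AIC.

    Selection is invariant to permutation of the path entries; ties go to the
    sparser (larger lambda) model.
    """
    if len(path) == 0:
        raise ValueError("empty path")
    m = len(np.asarray(x))
    values = aic_values(path, m)
    idx = _argmin_prefer_sparser(values, path.lambdas)
    return SelectionResult(
        chosen_lambda=float(path.lambdas[idx]),
        chosen_alpha=path.alphas[idx].copy(),
        criterion_values=values,
        criterion="aic",
        df=int(path.dfs[idx]),
        chosen_index=idx,
    )


def cv_select(
    D,
    x,
    n_folds: int = 3,
    n_lambdas: int = 100,
    eps_ratio: float = 1e-3,
    rng_seed: int = 0,
    tol: float = 1e-8,
    max_sweeps: int = 1000,
) -> SelectionResult:
    """Pick lambda by K-fold cross-validation over the elements of the patch.

    The m rows of x are partitioned into ``n_folds`` seeded random folds; for
    each fold a path is fit on the retained rows over the shared lambda grid
    and the held-out rows are predicted as (D_heldout) a. The lambda with the
    smallest mean held-out MSE wins (ties to the larger lambda) and the final
    coefficients are refit on all rows at that lambda.
    """
    atoms = _atoms(D)
    x = np.asarray(x, dtype=np.float64)
    m = len(x)
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if m < n_folds:
        raise ValueError(f"cannot split {m} elements into {n_folds} folds")

    lam0 = lambda_max(atoms, x)
    if lam0 == 0.0:
        p = atoms.shape[1]
        return SelectionResult(0.0, np.zeros(p), np.array([0.0]), "cv", 0, 0)
    lambdas = lambda_grid(lam0, n_lambdas, eps_ratio)

    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(m)
    folds = np.array_split(perm, n_folds)
    if any(len(f) == 0 for f in folds):
        raise ValueError("a cross-validation fold received zero rows")

    mse = np.zeros(len(lambdas))
    for held in folds:
        keep = np.setdiff1d(np.arange(m), held)
        D_f = np.ascontiguousarray(atoms[keep])
        x_f = x[keep]
        G = D_f.T @ D_f
        c = D_f.T @ x_f
        # no early stop and no assumed null first point: the shared grid is
        # anchored at the full-data lambda_max which may differ from the fold's
        alphas, _, _, _, _, _ = _path_gram(
            G, c, float(x_f @ x_f), lambdas, 0.0, float(tol), int(max_sweeps), False
        )
        pred = alphas @ atoms[held].T  # (n_lambdas, n_held)
        mse += np.mean((x[held][None, :] - pred) ** 2, axis=1)
    mse /= n_folds

    idx = _argmin_prefer_sparser(mse, lambdas)
    # refit on all rows, warm-started down the grid to the chosen lambda
    G = atoms.T @ atoms
    c = atoms.T @ x
    alphas, _, _, dfs, _, _ = _path_gram(
        G, c, float(x @ x), lambdas[: idx + 1], 0.0, float(tol), int(max_sweeps), True
    )
    alpha = alphas[idx]
    return SelectionResult(
        chosen_lambda=float(lambdas[idx]),
        chosen_alpha=alpha.copy(),
        criterion_values=mse,
        criterion="cv",
        df=int(dfs[idx]),
        chosen_index=idx,
    )
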