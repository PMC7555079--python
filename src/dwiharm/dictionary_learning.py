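"""Online dictionary learning with per-batch adaptive l1 regularization.

The dictionary D (m x p, unit-norm columns, p = 2m by default) is learned by
alternating, over randomly drawn batches of patch columns, (i) sparse coding
of each column along its own lasso path with the regularization weight chosen
by AIC or cross-validation, and (ii) the parameter-free closed-form
block-coordinate dictionary update of Mairal-style online learning, driven by
the running accumulators A = sum a a' and B = sum x a'.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from numba import njit

from .model_selection import aic_values, _argmin_prefer_sparser, cv_select
from .patching import PatchMatrix
from .sparse_coding import _path_gram, lambda_grid

__all__ = [
    "Dictionary",
    "LearningState",
    "init_dictionary",
    "dictionary_update",
    "train",
    "downsample_dictionary",
]


@dataclasses.dataclass
class Dictionary:
    """An m x p dictionary with the block geometry needed to resize its atoms.

    ``atoms`` columns have unit l2 norm. ``patch_shape`` and ``n_angular``
    (volumes per block) describe how each column folds back into a
    spatial-angular block. ``atom_scales`` holds the per-atom normalization
    factors introduced by downsampling (None for trained dictionaries).
    """

    atoms: np.ndarray
    patch_shape: tuple[int, int, int]
    n_angular: int
    provenance: dict = dataclasses.field(default_factory=dict)
    atom_scales: np.ndarray | None = None

    @property
    def m(self) -> int:
        return self.atoms.shape[0]

    @property
    def p(self) -> int:
        return self.atoms.shape[1]

    def validate(self) -> None:
        if int(np.prod(self.patch_shape)) * self.n_angular != self.m:
            raise ValueError(
                f"block geometry {self.patch_shape} x {self.n_angular} volumes "
                f"does not match atom length {self.m}"
            )
        norms = np.linalg.norm(self.atoms, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("dictionary columns must have unit norm")


@dataclasses.dataclass
class LearningState:
    """Running accumulators of the online update: A = sum a a', B = sum x a'."""

    A: np.ndarray  # (p, p), symmetric PSD
    B: np.ndarray  # (m, p)
    iteration: int = 0


def _patch_columns(patches) -> np.ndarray:
    if isinstance(patches, PatchMatrix):
        return patches.data
    return np.asarray(patches, dtype=np.float64)


def init_dictionary(patches, p: int | None = None, rng_seed: int = 0) -> Dictionary:
    """Initialize D from p distinct randomly chosen patch columns, normalized.

    Zero-norm draws are replaced by redrawing from the unused pool.
    """
    X = _patch_columns(patches)
    m, n = X.shape
    if p is None:
        p = 2 * m
    if n < p:
        raise ValueError(f"need at least p={p} patches to initialize, got {n}")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n)
    atoms = np.empty((m, p))
    filled = 0
    for idx in order:
        col = X[:, idx]
        nrm = np.linalg.norm(col)
        if nrm < 1e-12:
            continue
        atoms[:, filled] = col / nrm
        filled += 1
        if filled == p:
            break
    if filled < p:
        raise ValueError("not enough nonzero patches to initialize the dictionary")

    if isinstance(patches, PatchMatrix):
        patch_shape = patches.patch_shape
        n_angular = patches.n_block_volumes
    else:
        patch_shape, n_angular = (m, 1, 1), 1
    return Dictionary(
        atoms=atoms,
        patch_shape=patch_shape,
        n_angular=n_angular,
        provenance={"seed": int(rng_seed), "init": "random_patches"},
    )


@njit(cache=True)
def _update_atoms(atoms, A, B):  # pragma: no cover - jitted
    """One block-coordinate pass of the closed-form dictionary update.

    u_j = (B_j - D A_j + A_jj d_j) / A_jj, then d_j <- u_j / ||u_j||, keeping
    every active column exactly on the unit sphere (the equality constraint of
    the learning objective). Columns never selected by the sparse codes
    (A_jj = 0) and degenerate updates (u_j = 0) are left unchanged.
    """
    m, p = atoms.shape
    for j in range(p):
        ajj = A[j, j]
        if ajj <= 0.0:
            continue
        u = np.empty(m)
        for i in range(m):
            s = 0.0
            for k in range(p):
                s += atoms[i, k] * A[k, j]
            u[i] = (B[i, j] - s) / ajj + atoms[i, j]
        nrm = 0.0
        for i in range(m):
            nrm += u[i] * u[i]
        nrm = math.sqrt(nrm)
        if nrm <= 1e-300:
            continue
        for i in range(m):
            atoms[i, j] = u[i] / nrm


def dictionary_update(D: Dictionary, state: LearningState) -> Dictionary:
    """Apply the closed-form update, returning a new Dictionary."""
    atoms = np.ascontiguousarray(D.atoms.copy())
    _update_atoms(atoms, np.ascontiguousarray(state.A), np.ascontiguousarray(state.B))
    return dataclasses.replace(D, atoms=atoms)


def _code_column(
    atoms,
    G,
    x,
    criterion: str,
    n_lambdas: int,
    eps_ratio: float,
    stop_tol: float,
    tol: float,
    max_sweeps: int,
    n_folds: int = 3,
    cv_seed: int = 0,
):
    """Sparse-code one column against a fixed dictionary with adaptive lambda.

    Returns (alpha, objective at the selected lambda). ``G`` is the
    precomputed Gram matrix shared across columns.
    """
    c = atoms.T @ x
    lam0 = float(np.abs(c).max()) if c.size else 0.0
    if lam0 == 0.0:
        return np.zeros(atoms.shape[1]), 0.5 * float(x @ x)
    if criterion == "cv":
        sel = cv_select(
            atoms,
            x,
            n_folds=n_folds,
            n_lambdas=n_lambdas,
            eps_ratio=eps_ratio,
            rng_seed=cv_seed,
            tol=tol,
            max_sweeps=max_sweeps,
        )
        resid = x - atoms @ sel.chosen_alpha
        obj = 0.5 * float(resid @ resid) + sel.chosen_lambda * float(
            np.abs(sel.chosen_alpha).sum()
        )
        return sel.chosen_alpha, obj
    if criterion != "aic":
        raise ValueError(f"unknown criterion {criterion!r}; expected 'aic' or 'cv'")
    lambdas = lambda_grid(lam0, n_lambdas, eps_ratio)
    alphas, objs, rss, dfs, n_done, _ = _path_gram(
        G, c, float(x @ x), lambdas, stop_tol, tol, max_sweeps, True
    )
    m = len(x)
    path = _PathView(rss[:n_done], dfs[:n_done])
    values = aic_values(path, m)
    idx = _argmin_prefer_sparser(values, lambdas[:n_done])
    return alphas[idx].copy(), float(objs[idx])


class _PathView:
    """Minimal rss/dfs view for aic_values on raw path arrays."""

    def __init__(self, rss, dfs):
        self.rss = rss
        self.dfs = dfs


def train(
    patches,
    n_iters: int = 500,
    batch_size: int = 32,
    criterion: str = "aic",
    rng_seed: int = 0,
    p: int | None = None,
    n_lambdas: int = 100,
    eps_ratio: float = 1e-3,
    stop_tol: float = 1e-5,
    tol: float = 1e-8,
    max_sweeps: int = 1000,
    n_folds: int = 3,
    patch_shape: tuple[int, int, int] | None = None,
    n_angular: int | None = None,
) -> Dictionary:
    """Learn a dictionary over random batches of patch columns.

    Per iteration, ``batch_size`` columns are sampled with replacement, each
    is sparse-coded with its own adaptively chosen lambda, the accumulators
    are updated and the closed-form dictionary update applied. Deterministic
    given ``rng_seed``. The per-iteration mean objective is stored in
    ``provenance['objective_trace']``.
    """
    X = _patch_columns(patches)
    m, n = X.shape
    if n == 0:
        raise ValueError("no patches to train on")
    rng = np.random.default_rng(rng_seed)
    D = init_dictionary(patches, p=p, rng_seed=int(rng.integers(0, 2**31 - 1)))
    if patch_shape is not None:
        D = dataclasses.replace(D, patch_shape=tuple(int(v) for v in patch_shape))
    if n_angular is not None:
        D = dataclasses.replace(D, n_angular=int(n_angular))
    atoms = np.ascontiguousarray(D.atoms)
    p_eff = atoms.shape[1]

    A = np.zeros((p_eff, p_eff))
    B = np.zeros((m, p_eff))
    trace = []
    for it in range(n_iters):
        idx = rng.integers(0, n, size=batch_size)
        cv_seeds = rng.integers(0, 2**31 - 1, size=batch_size)
        G = atoms.T @ atoms
        alphas = np.empty((batch_size, p_eff))
        objs = np.empty(batch_size)
        for b in range(batch_size):
            x = np.ascontiguousarray(X[:, idx[b]])
            alphas[b], objs[b] = _code_column(
                atoms,
                G,
                x,
                criterion,
                n_lambdas,
                eps_ratio,
                stop_tol,
                tol,
                max_sweeps,
                n_folds=n_folds,
                cv_seed=int(cv_seeds[b]),
            )
        A += alphas.T @ alphas
        B += X[:, idx] @ alphas
        _update_atoms(atoms, A, B)
        trace.append(float(objs.mean()))

    provenance = {
        "seed": int(rng_seed),
        "n_iters": int(n_iters),
        "batch_size": int(batch_size),
        "criterion": criterion,
        "p": int(p_eff),
        "n_patches": int(n),
        "objective_trace": trace,
    }
    return dataclasses.replace(D, atoms=atoms, provenance=provenance)


def _resize_weights(src: int, dst: int) -> np.ndarray:
    """Volume-weighted block-mean resize operator along one axis.

    Target cell i covers the source interval [i*r, (i+1)*r) with r = src/dst;
    weights are fractional interval overlaps divided by r, so rows sum to one
    and the operator reduces to exact block means for integer ratios.
    """
    r = src / dst
    W = np.zeros((dst, src))
    for i in range(dst):
        lo, hi = i * r, (i + 1) * r
        for j in range(int(np.floor(lo)), min(src, int(np.ceil(hi)))):
            W[i, j] = max(0.0, (min(hi, j + 1) - max(lo, j))) / r
    return W


def downsample_dictionary(D: Dictionary, target_patch_shape) -> Dictionary:
    """Resize each atom's per-volume 3D sub-block to a smaller spatial shape.

    The angular dimension is untouched. Columns are renormalized to unit norm
    and the normalization factors are kept in ``atom_scales`` so that the
    coupled low/high-resolution reconstruction can share one coefficient
    vector per patch.
    """
    target = tuple(int(v) for v in target_patch_shape)
    src = tuple(D.patch_shape)
    if any(target[a] > src[a] for a in range(3)):
        raise ValueError(
            f"cannot upsample dictionary atoms: target {target} exceeds source {src}"
        )
    Wx, Wy, Wz = (_resize_weights(src[a], target[a]) for a in range(3))
    blocks = D.atoms.T.reshape(D.p, D.n_angular, *src)
    small = np.einsum("ax,by,cz,nvxyz->nvabc", Wx, Wy, Wz, blocks, optimize=True)
    cols = small.reshape(D.p, -1).T
    scales = np.linalg.norm(cols, axis=0)
    safe = np.where(scales < 1e-12, 1.0, scales)
    cols = cols / safe[None, :]
    return Dictionary(
        atoms=cols,
        patch_shape=target,
        n_angular=D.n_angular,
        provenance={**D.provenance, "downsampled_from": list(src)},
        atom_scales=safe,
    )
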