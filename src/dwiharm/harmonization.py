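"""Reconstruct a source data set in the feature space of a target dictionary.

Matched-resolution harmonization sparse-codes every source patch against a
dictionary trained on the target scanner (or on patches pooled from several
scanners, the "scanner-space") and rebuilds the volume as D_target a.
Resolution enhancement codes against a spatially downsampled copy of the
target dictionary while reconstructing with the full-size atoms, the implicit
mapping being guaranteed by sharing one coefficient vector per patch.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import zoom

from .dictionary_learning import Dictionary, _code_column, downsample_dictionary, train
from .io_formats import DWIDataset
from .patching import PatchMatrix, extract_patches, reassemble

__all__ = ["harmonize_matched", "harmonize_upsample", "build_scanner_space"]


def _check_geometry(source: DWIDataset, D: Dictionary, patch_shape) -> int:
    n_neighbors = D.n_angular - 2  # center DWI + neighbors + one b0
    if n_neighbors < 0:
        raise ValueError(f"dictionary block has too few volumes ({D.n_angular})")
    n_dwi = int((~source.is_b0).sum())
    if n_dwi < n_neighbors + 1:
        raise ValueError(
            f"geometry mismatch: dictionary expects blocks of {D.n_angular} volumes "
            f"({n_neighbors} angular neighbors) but the source data set has only "
            f"{n_dwi} diffusion-weighted volumes"
        )
    if int(np.prod(patch_shape)) * D.n_angular != D.m:
        raise ValueError(
            f"geometry mismatch: source blocks are {tuple(patch_shape)} x "
            f"{D.n_angular} volumes (m={int(np.prod(patch_shape)) * D.n_angular}) "
            f"but the dictionary has m={D.m}"
        )
    return n_neighbors


def _code_patches(
    patches: PatchMatrix,
    coding_atoms: np.ndarray,
    recon_atoms: np.ndarray,
    atom_scales: np.ndarray | None,
    criterion: str,
    rng_seed: int,
    n_lambdas: int,
    eps_ratio: float,
    stop_tol: float,
    tol: float,
    max_sweeps: int,
    n_folds: int,
) -> np.ndarray:
    """Sparse-code every column against ``coding_atoms`` and reconstruct with
    ``recon_atoms``; ``atom_scales`` undoes the downsampling normalization so
    that the shared coefficients are consistent between the two dictionaries."""
    coding_atoms = np.ascontiguousarray(coding_atoms)
    G = coding_atoms.T @ coding_atoms
    rng = np.random.default_rng(rng_seed)
    cv_seeds = rng.integers(0, 2**31 - 1, size=patches.n_patches)
    recon = np.empty((recon_atoms.shape[0], patches.n_patches))
    for i in range(patches.n_patches):
        x = np.ascontiguousarray(patches.data[:, i])
        alpha, _ = _code_column(
            coding_atoms,
            G,
            x,
            criterion,
            n_lambdas,
            eps_ratio,
            stop_tol,
            tol,
            max_sweeps,
            n_folds=n_folds,
            cv_seed=int(cv_seeds[i]),
        )
        if atom_scales is not None:
            alpha = alpha / atom_scales
        recon[:, i] = recon_atoms @ alpha
    return recon


def harmonize_matched(
    source: DWIDataset,
    D_target: Dictionary,
    criterion: str = "aic",
    rng_seed: int = 0,
    stride=1,
    n_lambdas: int = 100,
    eps_ratio: float = 1e-3,
    stop_tol: float = 1e-5,
    tol: float = 1e-8,
    max_sweeps: int = 1000,
    n_folds: int = 3,
    clip_negative: bool = False,
    origin_mask: np.ndarray | None = None,
) -> DWIDataset:
    """Map a source data set toward the target scanner at matched resolution.

    Volume count, b-values and b-vectors of the source are preserved; only the
    signal content is rebuilt from the target dictionary's features.
    ``origin_mask`` restricts reconstruction to the patches touching a
    subregion (all blocks covering its voxels are still included); voxels
    covered by no patch keep the source signal.
    """
    n_neighbors = _check_geometry(source, D_target, D_target.patch_shape)
    patches = extract_patches(
        source,
        patch_shape=D_target.patch_shape,
        n_neighbors=n_neighbors,
        stride=stride,
        rng_seed=rng_seed,
        origin_mask=origin_mask,
    )
    recon = _code_patches(
        patches,
        D_target.atoms,
        D_target.atoms,
        D_target.atom_scales,
        criterion,
        rng_seed,
        n_lambdas,
        eps_ratio,
        stop_tol,
        tol,
        max_sweeps,
        n_folds,
    )
    return reassemble(patches, recon, source, clip_negative=clip_negative)


def harmonize_upsample(
    source: DWIDataset,
    D_target: Dictionary,
    target_voxel_size=None,
    criterion: str = "aic",
    rng_seed: int = 0,
    source_patch_shape=(3, 3, 3),
    stride=1,
    n_lambdas: int = 100,
    eps_ratio: float = 1e-3,
    stop_tol: float = 1e-5,
    tol: float = 1e-8,
    max_sweeps: int = 1000,
    n_folds: int = 3,
    clip_negative: bool = False,
) -> DWIDataset:
    """Harmonize while enhancing spatial resolution via atom downsampling.

    Coefficients are computed against D_small = downsample(D_target) and the
    final patches are D_target a (with the downsampling normalization undone),
    placed on the enlarged lattice and averaged. Voxels covered by no patch
    are filled by trilinear interpolation of the source.
    """
    source_patch_shape = tuple(int(v) for v in source_patch_shape)
    ratios = np.array(
        [D_target.patch_shape[a] / source_patch_shape[a] for a in range(3)]
    )
    if target_voxel_size is not None:
        vox_ratio = np.asarray(source.voxel_size) / np.asarray(
            target_voxel_size, dtype=np.float64
        )
        if np.any(np.abs(ratios / vox_ratio - 1.0) > 0.25):
            raise ValueError(
                f"patch-size ratio {ratios} does not match the voxel-size ratio "
                f"{vox_ratio} within 25% on every axis"
            )
    factor = np.maximum(np.rint(ratios).astype(int), 1)
    if np.any(np.abs(ratios - factor) > 1e-9):
        warnings.warn(
            f"non-integer lattice ratio {ratios}; reassembling on the "
            f"nearest-integer lattice {factor}",
            RuntimeWarning,
            stacklevel=2,
        )
    if np.all(factor == 1) and tuple(D_target.patch_shape) == source_patch_shape:
        return harmonize_matched(
            source,
            D_target,
            criterion=criterion,
            rng_seed=rng_seed,
            stride=stride,
            n_lambdas=n_lambdas,
            eps_ratio=eps_ratio,
            stop_tol=stop_tol,
            tol=tol,
            max_sweeps=max_sweeps,
            n_folds=n_folds,
            clip_negative=clip_negative,
        )

    n_neighbors = _check_geometry(source, D_target, D_target.patch_shape)
    D_small = downsample_dictionary(D_target, source_patch_shape)
    patches = extract_patches(
        source,
        patch_shape=source_patch_shape,
        n_neighbors=n_neighbors,
        stride=stride,
        rng_seed=rng_seed,
    )
    recon = _code_patches(
        patches,
        D_small.atoms,
        D_target.atoms,
        D_small.atom_scales,
        criterion,
        rng_seed,
        n_lambdas,
        eps_ratio,
        stop_tol,
        tol,
        max_sweeps,
        n_folds,
    )
    background = np.stack(
        [
            zoom(source.signal[..., v], factor.astype(float), order=1, grid_mode=True, mode="nearest")
            for v in range(source.n_volumes)
        ],
        axis=-1,
    )
    return reassemble(
        patches,
        recon,
        source,
        factor=tuple(factor),
        background=background,
        clip_negative=clip_negative,
    )


def build_scanner_space(
    datasets: list[DWIDataset],
    rng_seed: int = 0,
    patch_shape=(3, 3, 3),
    n_neighbors: int = 5,
    stride=1,
    n_patches_per_dataset: int | None = None,
    **train_kwargs,
) -> Dictionary:
    """Learn a pooled "scanner-space" dictionary from several data sets.

    Patch matrices from all data sets are concatenated with equal per-data-set
    patch counts (each subsampled to the smallest count, or to
    ``n_patches_per_dataset``) before training, so no scanner dominates.
    """
    if len(datasets) < 2:
        raise ValueError("scanner-space training needs at least two data sets")
    if np.isscalar(patch_shape):
        patch_shape = (int(patch_shape),) * 3
    rng = np.random.default_rng(rng_seed)
    all_patches = []
    for ds in datasets:
        pm = extract_patches(
            ds,
            patch_shape=patch_shape,
            n_neighbors=n_neighbors,
            stride=stride,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        all_patches.append(pm)
    counts = [pm.n_patches for pm in all_patches]
    k = min(counts)
    if n_patches_per_dataset is not None:
        k = min(k, int(n_patches_per_dataset))
    pooled = []
    for pm in all_patches:
        take = rng.choice(pm.n_patches, size=k, replace=False)
        pooled.append(pm.data[:, take])
    X = np.concatenate(pooled, axis=1)

    n_angular = n_neighbors + 2
    D = train(
        X,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        patch_shape=tuple(int(v) for v in patch_shape),
        n_angular=n_angular,
        **train_kwargs,
    )
    D.provenance.update(
        {
            "scanner_space": True,
            "n_datasets": len(datasets),
            "patches_per_dataset": int(k),
            "pool_seed": int(rng_seed),
        }
    )
    return D
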