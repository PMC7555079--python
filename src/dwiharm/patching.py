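"""Spatial-angular patch decomposition and exact reassembly.

A block couples a small 3D patch from one diffusion-weighted volume with the
patches at the same location in its closest angular neighbors (angle between
b-vectors on the sphere, antipodally symmetric) plus one randomly chosen
b = 0 volume. Blocks are vectorized into columns of a matrix, one scalar mean
per volume is subtracted beforehand and every column is scaled to unit
variance; reassembly inverts the whole pipeline and averages overlapping
contributions voxelwise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import DWIDataset

__all__ = ["PatchMatrix", "angular_neighbors", "extract_patches", "reassemble"]

#: Column standard deviations below this are treated as exactly zero
#: (constant patches are kept with a recorded scale of 1).
_ZERO_STD = 1e-12


@dataclasses.dataclass
class PatchMatrix:
    """Vectorized spatial-angular blocks with the bookkeeping to undo them.

    ``data`` is an (m, n_patches) matrix, each column one block laid out
    volume-major: for each of the ``block_volumes`` entries in order, the
    C-order raveled 3D patch. ``m = prod(patch_shape) * n_volumes_per_block``.
    """

    data: np.ndarray
    patch_shape: tuple[int, int, int]
    block_volumes: np.ndarray  # (n_patches, n_vols_per_block) volume indices
    origins: np.ndarray  # (n_patches, 3) corner voxel indices
    scales: np.ndarray  # (n_patches,) unit-variance scaling factors
    volume_means: np.ndarray  # (n_volumes,) per-volume means over the mask
    spatial_shape: tuple[int, int, int]
    n_volumes: int

    @property
    def n_patches(self) -> int:
        return self.data.shape[1]

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n_block_volumes(self) -> int:
        return self.block_volumes.shape[1]


def angular_neighbors(
    bvecs: np.ndarray, n_neighbors: int, is_b0: np.ndarray | None = None
) -> dict[int, list[int]]:
    """Closest angular neighbors of every DWI under antipodal symmetry.

    Distances are theta = arccos(clamp(|u.v|, 0, 1)); b0 volumes are excluded
    both as queries and as candidates; ties break toward the lower volume
    index. Returns ``{volume_index: [neighbor indices]}`` for every DWI.
    """
    bvecs = np.asarray(bvecs, dtype=np.float64)
    if is_b0 is None:
        is_b0 = np.zeros(len(bvecs), dtype=bool)
    dwi = np.flatnonzero(~np.asarray(is_b0))
    if len(dwi) < n_neighbors + 1:
        raise ValueError(
            f"requested {n_neighbors} angular neighbors but only {len(dwi)} "
            "diffusion-weighted volumes are available"
        )
    vecs = bvecs[dwi]
    cos = np.clip(np.abs(vecs @ vecs.T), 0.0, 1.0)
    theta = np.arccos(cos)
    out: dict[int, list[int]] = {}
    for row, v in enumerate(dwi):
        order = sorted((theta[row, k], dwi[k]) for k in range(len(dwi)) if k != row)
        out[int(v)] = [int(idx) for _, idx in order[:n_neighbors]]
    return out


def _as_triple(value) -> tuple[int, int, int]:
    if np.isscalar(value):
        return (int(value),) * 3
    t = tuple(int(v) for v in value)
    if len(t) != 3:
        raise ValueError(f"expected a scalar or 3 extents, got {value}")
    return t


def _lattice_origins(spatial_shape, patch_shape, stride, mask) -> np.ndarray:
    """Origins on the stride grid whose patch overlaps the mask."""
    grids = [
        np.arange(0, spatial_shape[a] - patch_shape[a] + 1, stride[a])
        for a in range(3)
    ]
    windows = sliding_window_view(mask, patch_shape)
    hit = windows[np.ix_(*grids)].any(axis=(3, 4, 5))
    keep = np.argwhere(hit)
    origins = np.column_stack([grids[a][keep[:, a]] for a in range(3)])
    return origins.astype(np.intp).reshape(-1, 3)


def extract_patches(
    data: DWIDataset,
    patch_shape=(3, 3, 3),
    n_neighbors: int = 5,
    stride=1,
    rng_seed: int = 0,
    origin_mask: np.ndarray | None = None,
) -> PatchMatrix:
    """Decompose a data set into scaled spatial-angular block columns.

    Every DWI serves once as block center at every stride-grid origin whose
    patch touches the brain mask; its block stacks the center patch, the
    patches of its ``n_neighbors`` closest angular neighbors, and one b = 0
    patch drawn with the seeded generator. Deterministic given ``rng_seed``
    and the patch count does not depend on the seed (only the b0 choice does).

    ``origin_mask`` restricts the lattice to patches touching a subregion
    (partial reconstruction); per-volume means are still taken over the full
    brain mask so the scaling pipeline is independent of the restriction.
    """
    patch_shape = _as_triple(patch_shape)
    stride = _as_triple(stride)
    if any(patch_shape[a] > data.spatial_shape[a] for a in range(3)):
        raise ValueError(
            f"patch shape {patch_shape} exceeds volume shape {data.spatial_shape}"
        )
    if not data.mask.any():
        raise ValueError("brain mask is empty")
    b0_idx = np.flatnonzero(data.is_b0)
    if len(b0_idx) == 0:
        raise ValueError("data set has no b = 0 volume to include in blocks")

    neighbors = angular_neighbors(data.bvecs, n_neighbors, data.is_b0)
    dwi_idx = np.flatnonzero(~data.is_b0)

    volume_means = np.array(
        [data.signal[..., v][data.mask].mean() for v in range(data.n_volumes)]
    )
    centered = data.signal - volume_means[None, None, None, :]

    lattice_mask = data.mask if origin_mask is None else np.asarray(origin_mask, bool)
    if lattice_mask.shape != data.spatial_shape:
        raise ValueError("origin_mask shape must match the spatial shape")
    origins = _lattice_origins(data.spatial_shape, patch_shape, stride, lattice_mask)
    n_orig = len(origins)
    if n_orig == 0:
        raise ValueError("no patch origin overlaps the brain mask")

    # windows over the spatial axes only: (gx, gy, gz, nvol, px, py, pz)
    windows = sliding_window_view(centered, patch_shape, axis=(0, 1, 2))
    flat = windows[origins[:, 0], origins[:, 1], origins[:, 2]]
    flat = flat.reshape(n_orig, data.n_volumes, -1)

    rng = np.random.default_rng(rng_seed)
    n_block = n_neighbors + 2
    n_patches = len(dwi_idx) * n_orig
    m = int(np.prod(patch_shape)) * n_block

    cols = np.empty((m, n_patches))
    block_volumes = np.empty((n_patches, n_block), dtype=np.intp)
    all_origins = np.empty((n_patches, 3), dtype=np.intp)
    psz = int(np.prod(patch_shape))
    pos = 0
    for d in dwi_idx:
        vols = [int(d)] + neighbors[int(d)]
        b0_choice = b0_idx[rng.integers(0, len(b0_idx), size=n_orig)]
        block = np.empty((n_orig, n_block, psz))
        for k, v in enumerate(vols):
            block[:, k, :] = flat[:, v, :]
        block[:, n_block - 1, :] = flat[np.arange(n_orig), b0_choice, :]
        cols[:, pos : pos + n_orig] = block.reshape(n_orig, m).T
        block_volumes[pos : pos + n_orig, : n_block - 1] = np.asarray(vols)[None, :]
        block_volumes[pos : pos + n_orig, n_block - 1] = b0_choice
        all_origins[pos : pos + n_orig] = origins
        pos += n_orig

    scales = cols.std(axis=0)
    scales[scales < _ZERO_STD] = 1.0
    cols /= scales[None, :]

    return PatchMatrix(
        data=cols,
        patch_shape=patch_shape,
        block_volumes=block_volumes,
        origins=all_origins,
        scales=scales,
        volume_means=volume_means,
        spatial_shape=data.spatial_shape,
        n_volumes=data.n_volumes,
    )


def reassemble(
    patches: PatchMatrix,
    reconstructed: np.ndarray,
    target: DWIDataset,
    factor=(1, 1, 1),
    background: np.ndarray | None = None,
    clip_negative: bool = False,
) -> DWIDataset:
    """Recombine (possibly harmonized) block columns into a volume.

    Columns are unscaled by their recorded factors, scattered back to their
    origins (scaled by ``factor`` for resolution enhancement) and averaged
    voxelwise with uniform weights; per-volume means are re-added afterwards.
    Voxels covered by no patch keep the source value (or ``background`` when
    reassembling onto an enlarged lattice).
    """
    factor = _as_triple(factor)
    if reconstructed.shape[1] != patches.n_patches:
        raise ValueError(
            f"reconstructed matrix has {reconstructed.shape[1]} columns, "
            f"expected {patches.n_patches}"
        )
    big_shape = tuple(patches.patch_shape[a] * factor[a] for a in range(3))
    n_block = patches.n_block_volumes
    m_out = int(np.prod(big_shape)) * n_block
    if reconstructed.shape[0] != m_out:
        raise ValueError(
            f"reconstructed matrix has {reconstructed.shape[0]} rows, expected "
            f"{m_out} for block geometry {big_shape} x {n_block} volumes"
        )
    out_shape = tuple(patches.spatial_shape[a] * factor[a] for a in range(3))

    cols = reconstructed * patches.scales[None, :]
    acc = np.zeros(out_shape + (patches.n_volumes,))
    cnt = np.zeros(out_shape + (patches.n_volumes,), dtype=np.int64)
    for i in range(patches.n_patches):
        block = cols[:, i].reshape(n_block, *big_shape)
        o = patches.origins[i] * factor
        sl = (
            slice(o[0], o[0] + big_shape[0]),
            slice(o[1], o[1] + big_shape[1]),
            slice(o[2], o[2] + big_shape[2]),
        )
        for k in range(n_block):
            v = patches.block_volumes[i, k]
            acc[sl + (v,)] += block[k]
            cnt[sl + (v,)] += 1

    covered = cnt > 0
    out = np.where(covered, acc / np.maximum(cnt, 1), 0.0)
    out += patches.volume_means[None, None, None, :]
    if background is None:
        if out_shape != patches.spatial_shape:
            raise ValueError("a background volume is required when upsampling")
        background = target.signal
    out = np.where(covered, out, background)
    if clip_negative:
        out = np.clip(out, 0.0, None)

    if out_shape == tuple(target.spatial_shape):
        affine, mask = target.affine, target.mask
    else:
        f = np.asarray(factor, dtype=np.float64)
        affine = target.affine.copy()
        affine[:3, :3] = affine[:3, :3] / f[None, :]
        affine[:3, 3] = target.affine[:3, 3] + target.affine[:3, :3] @ (0.5 / f - 0.5)
        mask = target.mask
        for a in range(3):
            mask = np.repeat(mask, factor[a], axis=a)
    return DWIDataset(
        signal=out,
        bvals=target.bvals.copy(),
        bvecs=target.bvecs.copy(),
        affine=affine,
        mask=mask,
        b0_threshold=target.b0_threshold,
    )
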