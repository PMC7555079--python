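"""Synthetic multi-scanner diffusion phantoms and the free-water alteration.

The phantom is a piecewise tensor anatomy (a CSF sphere at free-water
diffusivity, two anisotropic white-matter slabs, isotropic gray matter
elsewhere) sampled with electrostatically spread gradient directions and a
mono-exponential tensor signal. Scanner effects are emulated as a smooth
multiplicative gain field plus Gaussian or Rician noise at a target SNR.
The free-water alteration adds, per voxel of a rectangular region,

    S_altered = S_b + f * S0 * exp(-b * D_csf)

with one fraction f ~ U(f_low, f_high) per voxel shared across volumes and
D_csf = 3e-3 mm^2/s, mimicking infiltration of edema.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_formats import DWIDataset

__all__ = [
    "AlterationSpec",
    "ScannerModel",
    "disperse_directions",
    "make_phantom",
    "make_gain_field",
    "apply_scanner",
    "apply_free_water",
]

#: Nominal free-water diffusivity at body temperature, mm^2/s.
D_CSF = 3.0e-3


@dataclasses.dataclass
class AlterationSpec:
    """Free-water alteration of a rectangular voxel region."""

    corner: tuple[int, int, int]
    extents: tuple[int, int, int] = (15, 20, 10)
    f_low: float = 0.7
    f_high: float = 0.9
    d_csf: float = D_CSF
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_low <= self.f_high <= 1.0):
            raise ValueError("need 0 <= f_low <= f_high <= 1")
        if self.d_csf <= 0:
            raise ValueError("d_csf must be positive")


@dataclasses.dataclass
class ScannerModel:
    """Multiplicative gain field plus additive noise of a synthetic scanner."""

    gain_field: np.ndarray | None = None
    noise_sigma: float | None = None
    noise_type: str = "rician"
    snr_b0: float | None = None

    def __post_init__(self) -> None:
        if self.gain_field is not None and np.any(np.asarray(self.gain_field) <= 0):
            raise ValueError("gain field must be strictly positive")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.noise_type not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise type {self.noise_type!r}")


def disperse_directions(n: int, rng_seed: int = 0, n_iter: int = 200) -> np.ndarray:
    """Spread n unit vectors on the half-sphere by electrostatic repulsion.

    Antipodal pairs repel as point charges; a fixed number of damped gradient
    steps gives a deterministic, well-spread set for any seed.
    """
    rng = np.random.default_rng(rng_seed)
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    step = 0.1
    for _ in range(n_iter):
        forces = np.zeros_like(pts)
        for sign in (1.0, -1.0):
            diff = pts[:, None, :] - sign * pts[None, :, :]  # (n, n, 3)
            dist = np.linalg.norm(diff, axis=-1)
            np.fill_diagonal(dist, np.inf)
            dist = np.maximum(dist, 1e-6)
            forces += (diff / dist[..., None] ** 3).sum(axis=1)
        # tangential component only
        forces -= (forces * pts).sum(axis=1, keepdims=True) * pts
        pts += step * forces / np.maximum(np.linalg.norm(forces, axis=1, keepdims=True), 1e-12)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        step *= 0.97
    # canonical hemisphere for reproducibility of sign conventions
    flip = pts[:, 2] < 0
    pts[flip] *= -1
    return pts


def _tensor_from_eigs(eigs, axis: int) -> np.ndarray:
    T = np.diag([eigs[1], eigs[1], eigs[1]]).astype(float)
    T[axis, axis] = eigs[0]
    return T


def make_phantom(
    shape=(24, 24, 24),
    n_dirs: int = 12,
    bval: float = 1200.0,
    rng_seed: int = 0,
    n_b0: int = 2,
    s0: float = 500.0,
) -> DWIDataset:
    """Noiseless piecewise-tensor phantom with a CSF sphere and WM slabs.

    CSF is isotropic at 3e-3 mm^2/s, gray matter isotropic at 0.8e-3, and two
    white-matter slabs carry prolate tensors along x and y with FA about 0.87
    and 0.64. Signal is S0 * exp(-b g' T g); deterministic given the seed
    (which controls the gradient directions).
    """
    if n_dirs < 6:
        raise ValueError("need at least 6 directions for a tensor phantom")
    shape = tuple(int(v) for v in shape)
    rng = np.random.default_rng(rng_seed)
    dirs = disperse_directions(n_dirs, rng_seed=int(rng.integers(0, 2**31 - 1)))

    center = (np.asarray(shape) - 1) / 2.0
    xx, yy, zz = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    radii = 0.45 * np.asarray(shape)
    ellip = (
        ((xx - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((zz - center[2]) / radii[2]) ** 2
    )
    mask = ellip <= 1.0

    csf_center = center + np.asarray(shape) * np.array([0.15, -0.1, 0.1])
    csf_r = 0.16 * min(shape)
    csf = (
        (xx - csf_center[0]) ** 2
        + (yy - csf_center[1]) ** 2
        + (zz - csf_center[2]) ** 2
    ) <= csf_r**2

    third = [s // 3 for s in shape]
    wm1 = np.zeros(shape, dtype=bool)
    wm1[:, third[1] : 2 * third[1], :] = True  # slab running along x
    wm2 = np.zeros(shape, dtype=bool)
    wm2[:, :, third[2] : 2 * third[2]] = True  # slab running along y
    wm1 &= mask & ~csf
    wm2 &= mask & ~csf & ~wm1

    tensors = np.empty(shape + (3, 3))
    tensors[...] = np.eye(3) * 0.8e-3  # gray matter
    tensors[csf] = np.eye(3) * D_CSF
    tensors[wm1] = _tensor_from_eigs((1.7e-3, 0.2e-3), axis=0)  # FA ~ 0.87
    tensors[wm2] = _tensor_from_eigs((1.5e-3, 0.45e-3), axis=1)  # FA ~ 0.64

    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(bval))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])

    # S = S0 exp(-b g' T g) per voxel and direction
    quad = np.einsum("di,xyzij,dj->xyzd", dirs, tensors, dirs, optimize=True)
    dwi = s0 * np.exp(-float(bval) * quad)
    signal = np.concatenate(
        [np.full(shape + (n_b0,), s0), dwi], axis=-1
    )
    signal[~mask] = 0.0

    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    return DWIDataset(signal=signal, bvals=bvals, bvecs=bvecs, affine=affine, mask=mask)


def make_gain_field(
    shape, amplitude: float = 0.1, length_scale: float = 8.0, rng_seed: int = 0
) -> np.ndarray:
    """Smooth strictly positive multiplicative field 1 + amplitude * z(x).

    z is unit-peak smoothed white noise, so the field stays within
    [1 - amplitude, 1 + amplitude].
    """
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must lie in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    noise = rng.standard_normal(tuple(int(v) for v in shape))
    smooth = gaussian_filter(noise, sigma=length_scale)
    peak = np.abs(smooth).max()
    if peak == 0:
        return np.ones(shape)
    return 1.0 + amplitude * smooth / peak


def apply_scanner(
    data: DWIDataset, model: ScannerModel, rng_seed: int = 0
) -> DWIDataset:
    """Imprint a scanner on a data set: gain field, then seeded noise.

    Rician noise takes the magnitude of a complex Gaussian perturbation, which
    raises the mean background signal above zero (noise floor).
    """
    signal = data.signal.copy()
    if model.gain_field is not None:
        gain = np.asarray(model.gain_field, dtype=np.float64)
        if gain.shape != data.spatial_shape:
            raise ValueError(
                f"gain field shape {gain.shape} does not match {data.spatial_shape}"
            )
        signal = signal * gain[..., None]
    sigma = model.noise_sigma
    if sigma is None:
        if model.snr_b0 is not None:
            b0_mean = float(signal[..., data.is_b0].mean(axis=-1)[data.mask].mean())
            sigma = b0_mean / model.snr_b0
        else:
            sigma = 0.0
    if sigma > 0:
        rng = np.random.default_rng(rng_seed)
        if model.noise_type == "gaussian":
            signal = signal + rng.normal(0.0, sigma, signal.shape)
        else:
            n1 = rng.normal(0.0, sigma, signal.shape)
            n2 = rng.normal(0.0, sigma, signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return data.copy_with(signal=signal)


def apply_free_water(data: DWIDataset, spec: AlterationSpec) -> DWIDataset:
    """Add a free-water compartment in a rectangular region (edema mimic).

    One fraction f per voxel (uniform in [f_low, f_high], seeded) is shared
    across all volumes of that voxel; S0 is the per-voxel mean over b0
    volumes. Voxels outside the region are untouched.
    """
    corner = np.asarray(spec.corner, dtype=int)
    extents = np.asarray(spec.extents, dtype=int)
    shape = np.asarray(data.spatial_shape)
    if np.any(corner < 0) or np.any(corner + extents > shape):
        raise ValueError(
            f"region corner {tuple(corner)} extents {tuple(extents)} exceeds "
            f"volume bounds {tuple(shape)}"
        )
    if not np.any(data.is_b0):
        raise ValueError("free-water alteration needs at least one b = 0 volume")
    sl = tuple(slice(corner[a], corner[a] + extents[a]) for a in range(3))
    if not data.mask[sl].all():
        warnings.warn(
            "alteration region extends outside the brain mask",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.rng_seed)
    f = rng.uniform(spec.f_low, spec.f_high, size=tuple(extents))
    s0 = data.signal[..., data.is_b0].mean(axis=-1)
    signal = data.signal.copy()
    decay = np.exp(-data.bvals * spec.d_csf)  # (n_volumes,)
    signal[sl] = signal[sl] + f[..., None] * s0[sl][..., None] * decay[None, None, None, :]
    return data.copy_with(signal=signal)
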