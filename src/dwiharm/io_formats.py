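"""Readers and writers for diffusion MRI volumes, gradient tables and dictionaries.

Volumes and masks use NIfTI-1 (``.nii``/``.nii.gz``); b-values and b-vectors use
FSL-style whitespace-delimited text (one value or one 3-vector per volume).
Learned dictionaries are serialized in a self-describing JSON container with
explicit shape fields so that geometry metadata can never silently go missing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

#: Volumes with a b-value below this threshold (s/mm^2) count as b = 0 images.
DEFAULT_B0_THRESHOLD = 50.0


@dataclasses.dataclass
class DWIDataset:
    """A 4D diffusion-weighted data set with its gradient table and brain mask.

    Attributes
    ----------
    signal : ndarray, shape (x, y, z, n_volumes)
        Non-negative diffusion-weighted signal in arbitrary scanner units.
    bvals : ndarray, shape (n_volumes,)
        Diffusion weighting per volume, s/mm^2.
    bvecs : ndarray, shape (n_volumes, 3)
        Unit gradient directions; zero vectors for b = 0 volumes.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform.
    mask : ndarray of bool, shape (x, y, z)
        Brain mask; only voxels inside it participate in patch extraction.
    b0_threshold : float
        b-values strictly below this count as b = 0 images.
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=np.float64))
        self.bvecs = np.asarray(self.bvecs, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        self.validate()

    # -- derived views -------------------------------------------------
    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.signal.shape[:3])

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[3]

    @property
    def is_b0(self) -> np.ndarray:
        """Boolean flag per volume, True for b = 0 images."""
        return self.bvals < self.b0_threshold

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def validate(self) -> None:
        if self.signal.ndim != 4:
            raise ValueError(f"signal must be 4D, got shape {self.signal.shape}")
        n = self.n_volumes
        if self.bvals.shape != (n,):
            raise ValueError(
                f"gradient table mismatch: image has {n} volumes but "
                f"{self.bvals.shape[0]} b-values were given"
            )
        if self.bvecs.shape != (n, 3):
            raise ValueError(
                f"gradient table mismatch: image has {n} volumes but bvecs "
                f"has shape {self.bvecs.shape}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite voxel values")
        norms = np.linalg.norm(self.bvecs, axis=1)
        bad = ~((np.abs(norms - 1.0) <= 1e-3) | (norms == 0.0))
        if np.any(bad):
            raise ValueError(
                f"bvecs must be unit norm or zero; offending volumes {np.flatnonzero(bad)}"
            )
        if self.mask.shape != self.spatial_shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match spatial shape "
                f"{self.spatial_shape}"
            )

    def copy_with(self, **kwargs) -> "DWIDataset":
        fields = dict(
            signal=self.signal,
            bvals=self.bvals,
            bvecs=self.bvecs,
            affine=self.affine,
            mask=self.mask,
            b0_threshold=self.b0_threshold,
        )
        fields.update(kwargs)
        return DWIDataset(**fields)


def _load_bvecs(path) -> np.ndarray:
    raw = np.atleast_2d(np.loadtxt(path, dtype=np.float64))
    if raw.shape[0] == 3 and raw.shape[1] != 3:
        raw = raw.T
    elif raw.shape[1] != 3:
        raise ValueError(f"bvec file {path} has shape {raw.shape}; expected 3xN or Nx3")
    return raw


def read_dwi(
    image_path,
    bval_path,
    bvec_path,
    mask_path,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
) -> DWIDataset:
    """Load a NIfTI volume with FSL-style bvals/bvecs and a binary mask.

    b-vectors are accepted in both 3xN and Nx3 text layouts (auto-detected from
    the array shape) and are normalized to unit norm where nonzero.
    """
    img = nib.load(str(image_path))
    signal = np.asarray(img.get_fdata(), dtype=np.float64)
    if signal.ndim == 3:
        signal = signal[..., None]
    bvals = np.atleast_1d(np.loadtxt(bval_path, dtype=np.float64))
    bvecs = _load_bvecs(bvec_path)
    n = signal.shape[3]
    if bvals.shape[0] != n or bvecs.shape[0] != n:
        raise ValueError(
            f"gradient table mismatch: image has {n} volumes, bval file has "
            f"{bvals.shape[0]} entries, bvec file has {bvecs.shape[0]} rows"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    nonzero = norms > 0
    bvecs[nonzero] = bvecs[nonzero] / norms[nonzero, None]
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.get_fdata()) > 0
    return DWIDataset(
        signal=signal,
        bvals=bvals,
        bvecs=bvecs,
        affine=img.affine,
        mask=mask,
        b0_threshold=b0_threshold,
    )


def write_dwi(
    data: DWIDataset,
    image_path,
    bval_path=None,
    bvec_path=None,
    mask_path=None,
) -> None:
    """Write a data set back to NIfTI (+ optional FSL gradient table and mask)."""
    data.validate()
    img = nib.Nifti1Image(data.signal.astype(np.float64), data.affine)
    nib.save(img, str(image_path))
    if bval_path is not None:
        np.savetxt(str(bval_path), data.bvals[None, :], fmt="%.8g")
    if bvec_path is not None:
        # FSL convention: three rows of N entries
        np.savetxt(str(bvec_path), data.bvecs.T, fmt="%.10g")
    if mask_path is not None:
        nib.save(
            nib.Nifti1Image(data.mask.astype(np.uint8), data.affine), str(mask_path)
        )


def read_mask(mask_path) -> np.ndarray:
    return np.asarray(nib.load(str(mask_path)).get_fdata()) > 0


# -- dictionary container ----------------------------------------------

_DICT_FORMAT = "dwiharm-dictionary"


def save_dictionary(dictionary, path) -> None:
    """Serialize a learned dictionary losslessly to a JSON container."""
    payload = {
        "format": _DICT_FORMAT,
        "version": 1,
        "m": int(dictionary.atoms.shape[0]),
        "p": int(dictionary.atoms.shape[1]),
        "patch_shape": [int(v) for v in dictionary.patch_shape],
        "n_angular": int(dictionary.n_angular),
        "atoms": dictionary.atoms.tolist(),
        "atom_scales": (
            None
            if dictionary.atom_scales is None
            else np.asarray(dictionary.atom_scales).tolist()
        ),
        "provenance": dictionary.provenance,
    }
    Path(path).write_text(json.dumps(payload))


def load_dictionary(path):
    """Load a dictionary container; hard error on missing or corrupt geometry."""
    from .dictionary_learning import Dictionary

    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _DICT_FORMAT:
        raise ValueError(f"{path} is not a {_DICT_FORMAT} container")
    for key in ("m", "p", "patch_shape", "n_angular", "atoms"):
        if key not in payload or payload[key] is None:
            raise ValueError(f"dictionary container {path} is missing field '{key}'")
    atoms = np.asarray(payload["atoms"], dtype=np.float64)
    if atoms.shape != (payload["m"], payload["p"]):
        raise ValueError(
            f"corrupted dictionary: atoms shape {atoms.shape} does not match "
            f"declared ({payload['m']}, {payload['p']})"
        )
    patch_shape = tuple(payload["patch_shape"])
    n_angular = int(payload["n_angular"])
    if int(np.prod(patch_shape)) * n_angular != atoms.shape[0]:
        raise ValueError(
            "corrupted dictionary: block geometry inconsistent with atom length"
        )
    scales = payload.get("atom_scales")
    return Dictionary(
        atoms=atoms,
        patch_shape=patch_shape,
        n_angular=n_angular,
        provenance=payload.get("provenance", {}),
        atom_scales=None if scales is None else np.asarray(scales, dtype=np.float64),
    )
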