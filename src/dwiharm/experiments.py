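"""Self-contained desk-scale harmonization experiments on synthetic scanners.

Two studies, each deterministic given one integer seed:

* :func:`two_scanner_kl` — the same anatomy imaged by a low-quality source
  scanner (strong gain field, SNR 15) and a higher-quality target scanner
  (mild gain field, SNR 35); a dictionary is trained on the target and used
  to reconstruct the source. Reports the symmetric KL divergence between the
  two scanners' ADC and RISH 0 distributions before and after harmonization.

* :func:`effect_size_preservation` — a free-water-altered copy of the source
  data set is created, a pooled scanner-space dictionary is trained on the
  two unaltered scanners, and both the original and altered source are
  reconstructed against it. Reports Hedges' g between original and altered
  metrics in the affected region before harmonization (with a percentile
  bootstrap interval) and after.

Problem sizes are deliberately small (24^3 phantom, 12 directions, blocks of
3x3x3 voxels with 2 angular neighbors plus one b0, 100 training iterations,
16-point lambda grids down to 1e-2) so a study of several seeds runs on one
CPU in minutes; the package defaults used for real data are larger.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .dictionary_learning import train
from .evaluation import fit_dti_metrics, fit_rish, hedges_g, kl_symmetric
from .harmonization import build_scanner_space, harmonize_matched
from .io_formats import DWIDataset
from .patching import extract_patches
from .phantom import (
    AlterationSpec,
    ScannerModel,
    apply_free_water,
    apply_scanner,
    make_gain_field,
    make_phantom,
)

__all__ = [
    "ExperimentConfig",
    "make_scanner_pair",
    "two_scanner_kl",
    "effect_size_preservation",
]


@dataclasses.dataclass
class ExperimentConfig:
    """Scaled study conditions shared by both experiments."""

    shape: tuple[int, int, int] = (24, 24, 24)
    n_dirs: int = 12
    bval: float = 1200.0
    snr_source: float = 15.0
    snr_target: float = 35.0
    gain_source: float = 0.25
    gain_target: float = 0.08
    patch_shape: tuple[int, int, int] = (3, 3, 3)
    n_neighbors: int = 5
    n_iters: int = 100
    batch_size: int = 32
    criterion: str = "aic"
    n_lambdas: int = 12
    eps_ratio: float = 1e-2
    cd_tol: float = 3e-4
    cd_max_sweeps: int = 120
    recon_stride: int = 3
    region_corner: tuple[int, int, int] = (6, 6, 8)
    region_extents: tuple[int, int, int] = (12, 12, 8)
    n_bootstrap: int = 400

    @property
    def solver_kwargs(self) -> dict:
        return dict(
            criterion=self.criterion,
            n_lambdas=self.n_lambdas,
            eps_ratio=self.eps_ratio,
            tol=self.cd_tol,
            max_sweeps=self.cd_max_sweeps,
        )


def _metric_samples(data: DWIDataset, region=None) -> dict[str, np.ndarray]:
    """ADC/FA/RISH0/RISH2 samples inside the mask (or a region box)."""
    adc, fa = fit_dti_metrics(data)
    rish0, rish2 = fit_rish(data)
    out = {}
    for mp in (adc, fa, rish0, rish2):
        if region is None:
            out[mp.metric] = mp.samples()
        else:
            corner, extents = region
            sl = tuple(slice(c, c + e) for c, e in zip(corner, extents))
            out[mp.metric] = mp.values[sl][mp.mask[sl]]
    return out


def make_scanner_pair(
    seed: int, config: ExperimentConfig | None = None
) -> tuple[DWIDataset, DWIDataset]:
    """One phantom imaged by the source and target synthetic scanners."""
    cfg = config or ExperimentConfig()
    ss = np.random.SeedSequence(seed)
    s = [int(v) for v in ss.generate_state(6) % (2**31 - 1)]
    ph = make_phantom(shape=cfg.shape, n_dirs=cfg.n_dirs, bval=cfg.bval, rng_seed=s[0])
    gain_a = make_gain_field(
        cfg.shape, amplitude=cfg.gain_source, length_scale=5.0, rng_seed=s[1]
    )
    gain_b = make_gain_field(
        cfg.shape, amplitude=cfg.gain_target, length_scale=9.0, rng_seed=s[2]
    )
    source = apply_scanner(
        ph,
        ScannerModel(gain_field=gain_a, snr_b0=cfg.snr_source, noise_type="rician"),
        rng_seed=s[3],
    )
    target = apply_scanner(
        ph,
        ScannerModel(gain_field=gain_b, snr_b0=cfg.snr_target, noise_type="rician"),
        rng_seed=s[4],
    )
    return source, target


def two_scanner_kl(seed: int, config: ExperimentConfig | None = None) -> dict:
    """Train on the target scanner, harmonize the source, compare KL_sym.

    Returns ``{metric: {"before": .., "after": ..}}`` for ADC and RISH0.
    """
    cfg = config or ExperimentConfig()
    ss = np.random.SeedSequence(seed)
    s = [int(v) for v in ss.generate_state(9) % (2**31 - 1)]
    source, target = make_scanner_pair(seed, cfg)
    patches = extract_patches(
        target,
        patch_shape=cfg.patch_shape,
        n_neighbors=cfg.n_neighbors,
        stride=1,
        rng_seed=s[6],
    )
    D = train(
        patches,
        n_iters=cfg.n_iters,
        batch_size=cfg.batch_size,
        rng_seed=s[7],
        stop_tol=1e-5,
        **cfg.solver_kwargs,
    )
    harmonized = harmonize_matched(
        source, D, rng_seed=s[8], stride=cfg.recon_stride, **cfg.solver_kwargs
    )
    src = _metric_samples(source)
    tgt = _metric_samples(target)
    har = _metric_samples(harmonized)
    return {
        metric: {
            "before": kl_symmetric(src[metric], tgt[metric]),
            "after": kl_symmetric(har[metric], tgt[metric]),
        }
        for metric in ("ADC", "RISH0")
    }


def effect_size_preservation(
    seed: int, config: ExperimentConfig | None = None
) -> dict:
    """Free-water alteration, scanner-space harmonization, Hedges' g check.

    Returns per metric ``{"g_before", "ci_low", "ci_high", "g_after",
    "preserved"}`` where the interval is the percentile bootstrap of
    g_before over paired voxel resamples.
    """
    cfg = config or ExperimentConfig()
    ss = np.random.SeedSequence(seed)
    s = [int(v) for v in ss.generate_state(12) % (2**31 - 1)]
    source, target = make_scanner_pair(seed, cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        altered = apply_free_water(
            source,
            AlterationSpec(
                corner=cfg.region_corner, extents=cfg.region_extents, rng_seed=s[6]
            ),
        )
    D = build_scanner_space(
        [source, target],
        rng_seed=s[7],
        patch_shape=cfg.patch_shape,
        n_neighbors=cfg.n_neighbors,
        stride=2,
        n_iters=cfg.n_iters,
        batch_size=cfg.batch_size,
        stop_tol=1e-5,
        **cfg.solver_kwargs,
    )
    # rebuild only the blocks touching the altered region: voxels inside it
    # receive every contribution a full-brain run would give them
    region_mask = np.zeros(source.spatial_shape, dtype=bool)
    sl = tuple(
        slice(c, c + e) for c, e in zip(cfg.region_corner, cfg.region_extents)
    )
    region_mask[sl] = True
    kw = dict(
        rng_seed=s[8],
        stride=cfg.recon_stride,
        origin_mask=region_mask,
        **cfg.solver_kwargs,
    )
    harmonized = harmonize_matched(source, D, **kw)
    harmonized_alt = harmonize_matched(altered, D, **kw)

    region = (cfg.region_corner, cfg.region_extents)
    before = _metric_samples(source, region)
    before_alt = _metric_samples(altered, region)
    after = _metric_samples(harmonized, region)
    after_alt = _metric_samples(harmonized_alt, region)

    rng = np.random.default_rng(s[9])
    out = {}
    for metric in ("ADC", "FA", "RISH0", "RISH2"):
        a, b = before[metric], before_alt[metric]
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        g_before = hedges_g(a, b)
        boots = np.empty(cfg.n_bootstrap)
        for k in range(cfg.n_bootstrap):
            idx = rng.integers(0, n, n)
            boots[k] = hedges_g(a[idx], b[idx])
        lo, hi = np.percentile(boots, [2.5, 97.5])
        g_after = hedges_g(after[metric], after_alt[metric])
        out[metric] = {
            "g_before": g_before,
            "ci_low": float(lo),
            "ci_high": float(hi),
            "g_after": g_after,
            "preserved": bool(lo <= g_after <= hi),
        }
    return out
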