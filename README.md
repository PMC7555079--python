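# dwiharm

Harmonization of diffusion MRI data sets with adaptive dictionary learning.

Diffusion-weighted MRI metrics such as the apparent diffusion coefficient
(ADC), fractional anisotropy (FA) and the rotationally invariant spherical
harmonic energies (RISH 0, RISH 2) differ systematically between scanners —
hardware, gradients, reconstruction and noise all leave their imprint — and
those instrumental differences can masquerade as biology in multicenter
studies. `dwiharm` removes scanner-attributable variability directly in the
diffusion-weighted signal, without paired subjects, spatial registration or
matched spatial resolution, while preserving genuine signal changes (tested
here with a simulated free-water/edema alteration). It is aimed at
researchers pooling single-shell dMRI acquired on different systems.

## Method in brief

Local spatial-angular blocks `X_n` (a 3x3x3 patch from one DWI, its five
closest angular neighbors by b-vector angle, and one b = 0 patch) are
vectorized and an overcomplete dictionary `D` (p = 2m unit-norm atoms) is
learned online by alternating sparse coding and a closed-form dictionary
update over random batches:

    min_{D, a}  1/N sum_n  1/2 ||X_n - D a_n||_2^2 + lambda_n ||a_n||_1
    subject to  ||d_j||_2 = 1

The regularization weight `lambda_n` is chosen *per block* along a
warm-started lasso path, by minimizing either the AIC
(`m log(||X_n - D a||^2 / m) + 2 df`) or the three-fold cross-validated
prediction error of held-out signal elements. Harmonization reconstructs a
source data set with the dictionary of a target scanner (or a pooled
"scanner-space" dictionary) held fixed: `X_harmonized = D_target a`.
Features peculiar to the source scanner are absent from `D_target` and are
not reconstructed. Mapping across spatial resolutions fits the coefficients
against a block-averaged (downsampled) copy of the dictionary and
reconstructs with the full-size atoms, sharing one coefficient vector per
block.

See `docs/methods.md` for the full model description, parameter defaults and
limitations.

## Worked example

Two synthetic "scanners" image the same tensor phantom — the source with a
strong gain field and SNR 15, the target with a mild gain field and SNR 35.
A dictionary trained on the target reconstructs the source:

```python
import numpy as np
from dwiharm import (
    apply_scanner, extract_patches, fit_dti_metrics, harmonize_matched,
    kl_symmetric, make_gain_field, make_phantom, train, ScannerModel,
)

phantom = make_phantom(shape=(24, 24, 24), n_dirs=12, rng_seed=0)
source = apply_scanner(
    phantom,
    ScannerModel(gain_field=make_gain_field((24, 24, 24), amplitude=0.25, rng_seed=1),
                 snr_b0=15, noise_type="rician"),
    rng_seed=2,
)
target = apply_scanner(
    phantom,
    ScannerModel(gain_field=make_gain_field((24, 24, 24), amplitude=0.08, rng_seed=3),
                 snr_b0=35, noise_type="rician"),
    rng_seed=4,
)

patches = extract_patches(target, patch_shape=3, n_neighbors=5, rng_seed=5)
dictionary = train(patches, n_iters=100, batch_size=32, criterion="aic",
                   n_lambdas=12, eps_ratio=1e-2, tol=3e-4, max_sweeps=120, rng_seed=6)
harmonized = harmonize_matched(source, dictionary, criterion="aic", rng_seed=7,
                               stride=3, n_lambdas=12, eps_ratio=1e-2, tol=3e-4,
                               max_sweeps=120)

adc_src, _ = fit_dti_metrics(source)
adc_tgt, _ = fit_dti_metrics(target)
adc_har, _ = fit_dti_metrics(harmonized)
print(f"KL_sym(ADC) source vs target:     {kl_symmetric(adc_src.samples(), adc_tgt.samples()):.3f}")
print(f"KL_sym(ADC) harmonized vs target: {kl_symmetric(adc_har.samples(), adc_tgt.samples()):.3f}")
```

Output:

```
KL_sym(ADC) source vs target:     0.522
KL_sym(ADC) harmonized vs target: 0.354
```

The symmetric Kullback-Leibler divergence between the two scanners' ADC
distributions (100 shared histogram bins) drops by about a third after
harmonization: the harmonized source looks more like the target scanner,
without ever pairing or registering the two data sets.

## Command line

The same pipeline is exposed as subcommands operating on NIfTI volumes with
FSL-style `bval`/`bvec` text files:

```sh
dwiharm phantom   --out-prefix ph --shape 24 24 24 --n-dirs 12 --seed 0
dwiharm alter     --input ph.nii.gz ph.bval ph.bvec ph_mask.nii.gz \
                  --corner 6 6 8 --out-prefix ph_alt --seed 1
dwiharm train     --input tgt.nii.gz tgt.bval tgt.bvec tgt_mask.nii.gz \
                  --out-dictionary dict.json --criterion cv --seed 0
dwiharm harmonize --input src.nii.gz src.bval src.bvec src_mask.nii.gz \
                  --dictionary dict.json --out-prefix src_harmonized --seed 0
dwiharm evaluate  --predicted src_harmonized.nii.gz ... --acquired tgt.nii.gz ... \
                  --out-report report.tsv
```

`train` accepts multiple `--input` quadruples to build a pooled scanner-space
dictionary; `harmonize` switches to resolution enhancement automatically when
the dictionary's patch size exceeds 3x3x3. Every command is bit-reproducible
given `--seed`, and options can come from a flat `key = value` file via
`--config` (flags win).

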