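# hkspeckle

Speckle statistics for ultrasonic envelope data: the homodyned-K (HK)
compound model and the three classical single-distribution models (Rayleigh,
Rician, K), maximum-likelihood fitting with BIC model selection, and a fully
synthetic assessment pipeline — gamma-renewal scatterer phantoms folded into
a cube along a Hilbert space-filling curve, a linear convolution pulse-echo
simulator, and grid/bias experiments that probe when each model wins.

## What is inside

| Module | Purpose |
| --- | --- |
| `hkspeckle.models` | Amplitude PDFs, samplers, closed-form intensity SNR. The HK density is evaluated two independent ways: adaptive panel quadrature of the oscillatory Bessel integral (`hk_pdf`) and a fast vectorized gamma-mixture route (`hk_log_pdf`); the test suite cross-checks them. |
| `hkspeckle.fitting` | Histogram/raw log-likelihoods, cyclic Newton-Raphson MLE with bounded Nelder-Mead fallback, BIC, best-single-model (OKRR) selection, HK-vs-OKRR comparison. |
| `hkspeckle.hilbert` | Vectorized Hilbert-curve vertices (Skilling transpose algorithm) and arc-length mapping. |
| `hkspeckle.phantom` | Gamma-renewal scatterer phantoms: shape `alpha` moves the organization continuously from clustered (<1) through Poisson (=1) to regular (>1); density `rho` is scatterers per cubic wavelength. |
| `hkspeckle.simulate` | Separable-PSF convolution imaging: Gaussian-windowed cosine pulse axially, Gaussian beam laterally/elevationally, analytic-signal envelope detection. |
| `hkspeckle.pipeline` | The (alpha, rho) grid experiment with per-cell model selection and section labeling, the SNR table, and the estimator bias/SD study. |
| `hkspeckle.cli` / `hkspeckle.io` | `hkspeckle` command-line interface and CSV/JSON/YAML/TIFF readers and writers. |

## CLI

```bash
# scatterer phantom (CSV + JSON sidecar)
hkspeckle phantom --alpha 0.1 --rho 5 --side-mm 4 --seed 7 --out phantom.csv

# envelope image from a phantom
hkspeckle simulate --phantom-csv phantom.csv --side-mm 4 --out envelope.csv

# fit models to raw amplitudes (one value per line) or a histogram CSV
hkspeckle fit --input amps.csv --models all --out fit.json

# grid experiment (desk scale by default; --scale full for the 12 mm cube)
hkspeckle grid --scale desk --seed 1 --outdir grid_out

# estimator bias study
hkspeckle bias --c 1,3,5 --k 0.3,0.6,1.0 --n 1000 --reps 10 --out fig5_analog.csv

# closed-form intensity SNR for a table of HK parameter triples
hkspeckle snr-table --out snr.csv           # bundled reference parameters
hkspeckle snr-table --from-params my.csv    # epsilon,sigma,c columns
```

## Notes on scale

The default configuration is desk-scale: a 4 mm cube, scatterer counts
capped at 2x10^5, and a 3x3 (alpha, rho) grid with 5 realizations, sized so
the whole suite runs on one CPU in minutes. The full-scale 12 mm cube and
4x5x30 grid are available via `GridSpec.full_grid()` / `--scale full`.
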