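# cortexwave

Simulation and quantification of cortical excitability waves: a
stochastic reaction–diffusion model of active Rho, inactive Rho and
dynamic F-actin with GEF-driven positive feedback and
GAP/F-actin-dependent negative feedback, plus the analysis pipeline
used to characterize the resulting wave patterns.

## What is in the box

| module | contents |
| --- | --- |
| `cortexwave.params` | `ModelParams` / `FullModelParams` containers, YAML/JSON load/save |
| `cortexwave.model` | reaction kinetics, reduced and full right-hand sides, uniform steady states |
| `cortexwave.stability` | analytic Jacobian, dispersion relations λ(q), four-regime classification and β scans |
| `cortexwave.simulator` | explicit finite-difference integration on periodic 2D lattices with a spatially correlated, periodically regenerated noise field |
| `cortexwave.wave_metrics` | box-averaging, autocorrelation period, FWHM temporal width, relative amplitude, cross-correlation shift, kymographs |
| `cortexwave.phase_defects` | analytic-signal phase reconstruction, winding-number defect detection, pair creation/annihilation tracking |
| `cortexwave.feature_catalog` | the 10 morphological wave-pattern features and relative-frequency histograms from binary score tables |
| `cortexwave.synthetic_data` | ground-truthed movie generators (plane waves, spirals, pulses/flickers, lagged follower channels) |
| `cortexwave.io` / `cortexwave.cli` | TIFF movie I/O with provenance manifests; umbrella CLI |

As the GAP level β increases at fixed GEF level α, the model passes
through a higher uniform state, a finite-wavenumber (wave) instability
domain, an oscillatory domain and a lower uniform state; with noise the
simulations produce flickers, spiral turbulence, ordered wave trains
and thin spiral waves across that same sweep.

## CLI

```bash
cortexwave simulate --grid 128 --duration 600 --seed 7 --out run/
cortexwave stability --beta-min 0 --beta-max 6 --n 25 --out stab/
cortexwave metrics --movie run/RT.tif --box 15 --out metrics/
cortexwave defects --movie run/RT.tif --out defects/
cortexwave synth plane --out wave.tif --period 32 --wavelength 20
cortexwave histogram --scores scores.csv --normalize grand
```

Movies are grayscale multi-frame TIFFs, one file per channel, with a
YAML sidecar carrying the frame interval `dt` (s) and pixel size `dx`
(µm); both can also be passed explicitly with `--dt/--dx`.

## Notes

Default model parameters are calibrated (time in seconds, space in µm,
concentrations nondimensional) so that the β sweep at α=1 crosses all
four dynamical regimes with wave periods of ~16–45 s and wavelengths of
~21 µm; regime boundaries for the defaults sit near β ≈ 1.25, 1.95 and
5.15. All stochastic paths are reproducible given a seed.
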