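# filakit

Simulation and analysis of single-molecule recombinase filament assembly
on ssDNA, as observed in optical-tweezers / confocal-fluorescence
experiments.

A kinetic Monte Carlo simulator generates ground-truth filament
trajectories (nucleation, growth, burst dissociation, transient 5'-end
capping by a mediator complex) on a 1-D nucleotide lattice. Renderers
turn event logs into realistic observables — multi-channel kymographs,
force traces, photobleaching staircases — and the analysis modules
recover the underlying kinetics from those observables:

| module | what it does |
| --- | --- |
| `filakit.sim_core` | exact Gillespie simulator, dipping-protocol cluster tables, condition presets |
| `filakit.sim_render` | kymograph / force-trace / bleach-trace rendering with PSF, shot + read noise, bleaching |
| `filakit.mechanics` | Marko–Siggia WLC and extensible FJC models, force-extension fitting, ssDNA gap length, nm↔nt conversion |
| `filakit.kymo_analysis` | displacement-decay fits, nucleation counting (25-frame median filter + 5-px smoothing + peak detection), growth-rate slopes, 3-Hz force downsampling |
| `filakit.step_counting` | photobleaching change points (binary segmentation + BIC), double-Gaussian unit calibration, protomer counts, growth events |
| `filakit.kinetics` | dwell-time extraction, exponential/survival fits, order-statistic median CIs, power-law nucleation fit k = J·cⁿ |
| `filakit.localization` | filament localization from inverted intensity profiles, 5'/3' end-binding classification, colocalization |
| `filakit.io` / `filakit.cli` | TIFF/HDF5 kymograph formats, YAML run configs, end-to-end pipeline |

## CLI

All stages are exposed as subcommands of a single entry point:

```sh
filakit simulate --preset combined --seed 1 --duration-min 10 --out events.csv
filakit render events.csv --out kymo.h5
filakit analyze-displacement kymo.h5 --out displacement.json
filakit count-nucleation kymo.h5 --out counts.csv
filakit growth kymo.h5 --regions regions.json --out growth.csv
filakit steps traces.csv --out steps.json
filakit dwell detections.csv --out dwells.csv
filakit wlc-fit curve.csv --model series-mixture --out fit.json
filakit localize profile.csv --out call.json
filakit run config.yaml          # full simulate -> render -> analyze pipeline
```

Exit codes: 0 success, 2 bad input, 3 fit non-convergence, 4 I/O error.
Condition presets: `none`, `BRC2`, `RFS1RIP1_WT`, `K56A`, `combined`.

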