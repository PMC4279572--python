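# fibercube

Desk-scale toolkit for single-exposure Raman imaging with a fiber-bundle
integral-field spectrograph. It covers the full chain:

1. **bundle geometry** — the 20×20 probe head (0.5 mm pitch, 110/132 μm
   fibers), grid ↔ pseudo-slit mapping, core area / fill-factor figures;
2. **simulator** — synthetic raw CCD frames (bias, flat, arc, science)
   from a forward model with per-fiber traces, dispersion solutions,
   throughput variation, dead fibers, fluorescence background,
   Poisson + read noise and cosmic-ray hits, plus sample phantoms
   (microbeads, tablet halves, three-phase fields);
3. **reduction** — master bias, flat-based trace finding, fiber
   throughput, neon-style arc wavelength calibration, tophat extraction,
   cosmic-ray cleaning;
4. **cube assembly** — Stokes Raman-shift conversion, resampling onto a
   common wavenumber axis, 20×20×N data cube with a dead-fiber mask;
5. **spectral processing** — blank-reference subtraction, per-spaxel
   reference normalization, iterative modified-polyfit fluorescence
   baseline removal (4th order, 15 iterations), Gaussian peak fitting;
6. **chemical mapping** — per-substance peak-height maps, blue→red
   pseudo-color rendering with dead fibers in white, multi-substance
   overlays.

FITS I/O is self-contained (`fibercube.fits` implements the image-HDU
subset of the standard), so the package needs only numpy / scipy /
matplotlib / pyyaml / click.

## CLI

```sh
fibercube run --seed 7 --out out/            # simulate + reduce + map
fibercube simulate --config cfg.yml --out raw/
fibercube reduce --bias raw/bias_0.fits --flat raw/flat.fits \
    --arc raw/arc.fits --science raw/science.fits --out out/
fibercube map --cube out/cube.fits --substance PS --shift 1035 \
    --window 40 --out maps/
fibercube report --out out/
```

`run` executes the full pipeline on a synthetic bead phantom by default
and writes raw frames, the master bias, row-stacked spectra, the data
cube (`cube.fits`), chemical maps (FITS + PNG) and `report.json`
(trace counts, wavelength residuals, replaced cosmics, config hash,
seed). A YAML config (see `fibercube.config.PipelineConfig.to_dict` for
the schema) controls the bundle layout, detector, spectral library,
phantom, baseline and peak-table parameters.

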