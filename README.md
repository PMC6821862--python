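# optij

A tested, reusable Python library and CLI for optical projection tomography
(OPT) reconstruction: projection correction, fiducial-based geometric
calibration, per-angle jitter correction, filtered back-projection, and
resolution/quality metrics — plus a built-in parallel-beam forward simulator
so every algorithm is verifiable by parameter recovery without microscope
data.

## What it does

An OPT scan acquires one 2-D projection per rotation angle over a full
revolution (default geometry: 512 projections over 360°, with a minimum
angular step of 360°/1024 ≈ 0.35°). The toolkit takes such a stack through:

1. **Projection correction** (`optij.preprocess`) — transmission stacks are
   divided by an average bright-field image and log-transformed
   (Beer–Lambert) to line-integrated attenuation; emission stacks get a
   dark/flat correction.
2. **Geometric calibration** (`optij.alignment`) — a fiducial bead is
   tracked through the projections; a closed-form sinusoid fit of its
   motion yields the rotation-axis offset from the detector center, the
   in-plane axis tilt (from the in-phase vertical bead motion), an
   out-of-plane tilt diagnostic (quadrature component), and per-angle
   jitter-correction shifts from the fit residuals.
3. **Sinogram assembly + FBP** (`optij.reconstruct`) — projections are
   de-tilted and de-shifted, one sinogram per image row; each sinogram is
   frequency-filtered (ramp, Hamming, Shepp–Logan, or none) and
   back-projected slice-by-slice into a volume. Results are identical
   regardless of worker count.
4. **Quality metrics** (`optij.metrics`) — split-half Fourier ring
   correlation (even/odd projections → two independent reconstructions →
   FRC threshold crossing at 1/7), profile FWHM, and SNR / brightness-ratio
   region statistics.

The simulator (`optij.opt_sim`) generates phantoms (disks, 3-D head
phantom, branching tree, fiducial bead) and projects them with configurable
axis offset, axis tilt (in-plane and out-of-plane), seeded per-angle
jitter, smooth illumination fields, and Gaussian/Poisson noise — the exact
inverse problems the pipeline solves.

Stacks, sinograms and volumes are multi-page TIFF with a YAML sidecar
manifest (`<file>.manifest.yaml`) carrying angles, pixel size, modality and
processing stage.

## CLI

Every subcommand accepts `--manifest` (YAML geometry) and exits nonzero on
error without writing partial outputs.

```sh
# simulate a jittered, off-axis scan
optij simulate --phantom disks --n-proj 512 --offset 5.25 --jitter 2.0 \
    --seed 7 --out scan/

# transmission correction
optij correct --mode beer-lambert --bright bright.tif raw.tif atten.tif

# calibration chain
optij track scan/projections.tif track.csv --roi 40,8,24,24
optij calibrate track.csv --center-col 31.5 --out geometry.yaml
optij dejitter track.csv corrections.csv

# reconstruction and resolution
optij reconstruct scan/projections.tif --geometry geometry.yaml \
    --jitter corrections.csv --filter ramp --rows 0:16 --workers 4 --out vol.tif
optij frc scan/projections.tif --filter ramp --rows 8 --pixel-size 12.9 \
    --out frc.csv

# the whole chain from one saved config
optij run --manifest config.yaml
```

## Layout

```
src/optij/
  stack_io.py     TIFF + manifest I/O, acquisition geometry, stack type
  opt_sim.py      phantoms and the forward simulator
  preprocess.py   Beer-Lambert and flat-field correction
  alignment.py    bead detection/tracking, sinusoid fit, offset/tilt, jitter
  reconstruct.py  sinograms, frequency filters, FBP, volume assembly
  metrics.py      FRC, FWHM, SNR/BR statistics
  cli.py          click CLI and the end-to-end pipeline
```

## Conventions

* Arrays are `(angle, row, column)`; pixel centers at integer coordinates;
  the detector center column is `(n_columns - 1) / 2`.
* The rotation axis is nominally vertical: one sinogram per image row.
* Bead motion is fit as `A·cos(θ + φ) + c` with φ in degrees in
  `[-180, 180)`.
* FBP accumulates with weight `π / n_angles` (a full revolution covers each
  line twice, which cancels its doubled angular step) and zeroes pixels
  outside the inscribed circle.
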