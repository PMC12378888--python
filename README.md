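# nmrdesk

Headless 2D / pseudo-3D NMR processing, deconvolution, analysis and
plotting toolkit.

`nmrdesk` converts Bruker time-domain data into phased frequency-domain
spectra, reconstructs non-uniformly sampled (NUS) indirect dimensions,
picks and Voigt-fits peaks (including shared-shape pseudo-3D fits with
per-plane heights), derives relaxation rates and CEST profiles, and renders
publication-quality contour and 3D surface/terrace figures — all without a
GUI, so everything is scriptable and reproducible.

## Features

- **Formats** — Bruker `ser`/`fid` + `acqus`/`acqu2s` (int32/float64, both
  byte orders), NMRPipe-style `.ft2` (512-float header, optional
  hypercomplex quadrants), UCSF Sparky `.ucsf` (tiled), TopSpin `totxt`
  text, NMRPipe `.tab` / Sparky `.list` peak lists (with `Z_A0, Z_A1, ...`
  plane-height columns), `nuslist` schedules.
- **Processing** — solvent suppression (boxcar lowpass subtraction),
  NMRPipe-flavoured windows (sine bell / exponential / Gaussian),
  zero-filling by folds, FFT with States / States-TPPI / echo-antiecho
  quadrature, Bruker group-delay compensation, automatic or manual
  zero/first-order phasing, ppm-window extraction, sequential pseudo-3D
  plane processing.
- **NUS** — iterative soft-thresholding (IST) reconstruction of the
  indirect time domain (not a SMILE re-implementation; same contract,
  explicitly no numerical parity), with measured-point consistency and a
  monotone data residual.
- **Peaks** — robust block-MAD noise estimation, local-maximum picking with
  sub-point interpolation, region-clustered least-squares deconvolution
  with separable Voigt/Gaussian/Lorentzian lineshapes, spectrum
  reconstruction, pseudo-3D fits sharing positions/widths across planes
  with per-plane heights.
- **Analysis** — mono-exponential rate fits (R1/R2-style) from plane
  heights, CEST profiles.
- **Viz** — marching-squares contours (saddle cells resolved by the
  cell-center average), deterministic SVG/PNG overlays with per-spectrum
  referencing and label de-overlap, 1D cross-sections/projections, 3D
  surface and terrace renderings.
- **Synthetic** — a ground-truth fixture generator that writes genuine
  Bruker directories from declared peak parameters, so the whole pipeline
  is testable offline.

## CLI

```sh
# generate a synthetic Bruker dataset from a ground-truth JSON
nmrdesk synth --config truth.json --out fixture_dir/

# process (first plane by default; --all-planes for pseudo-3D stacks)
nmrdesk process --in fixture_dir/ --config scheme.cfg --out spec.ft2
nmrdesk process --in fixture_dir/ --nuslist nuslist --out spec.ft2   # NUS
nmrdesk process --in fixture_dir/ --out spec.ft2 --print-phases

# pick / fit / pseudo-3D fit / rates
nmrdesk pick  --in spec.ft2 --threshold 5.5 --out peaks.tab
nmrdesk fit   --in spec.ft2 --peaks peaks.tab --lineshape voigt \
              --out fitted.tab --recon recon.ft2
nmrdesk fit3d --in planes.ft2 --peaks fitted.tab --out fitted3d.tab
nmrdesk rates --peaks fitted3d.tab --delays 0.01,0.1,0.4,0.8 --out rates.tsv

# plotting and format conversion
nmrdesk plot --in a.ft2 --in b.ft2 --colors black,goldenrod \
             --xlim 9.5,6.5 --ylim 132,102 --peaks peaks.tab --out fig.svg
nmrdesk convert --in spec.ft2 --out spec.ucsf
```

A processing scheme file uses NMRPipe-like tokens per dimension:

```ini
[direct]
SP off=0.5 end=0.95 pow=2
ZF folds=1
SOL on
PS auto
EXT lo=6.0 hi=10.0
[indirect]
EM lb=2.0
ZF folds=1
PS p0=90 p1=-180
[global]
FIRST_PLANE_ONLY off
```

Exit codes: 0 success, 1 validation error, 2 I/O error. Each invocation
logs a one-line JSON run summary to stderr.

## Conventions

- Point index 0 is the downfield (highest ppm) edge of every axis; indices
  are 0-based; ranges are half-open.
- First-order phase `p1` is the total sweep across the displayed spectrum,
  pivot at point 0.
- The first time-domain point of each dimension is scaled by 0.5 before
  its transform.
- Bruker group delay is compensated by a first-order phase ramp
  (`360 * group_delay` degrees); a circular-shift variant is available.

## Tests

```sh
python -m pytest tests/
```

The suite is fully self-contained: all fixtures are generated from ground
truth at test time. `tests/test_acceptance.py` holds the acceptance
criteria (format round trips, FFT-oracle equality, autophase recovery,
solvent suppression, NUS properties, Voigt correctness, deconvolution and
pseudo-3D parameter-recovery benchmarks, contour properties, end-to-end
determinism).

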