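# saxskit

FAIR management and analysis of one-dimensional small-angle X-ray scattering
(SAXS) data, aimed at soft-matter groups studying lyotropic liquid crystals
(LLC): surfactant/water mesophases whose nanoscale periodicity shows up as a
handful of Bragg reflections in a 1D scattering curve.

The package covers the whole desk-side data lifecycle:

* **readers** — parse and write the ASCII PDH instrument format (header,
  q/intensity columns, embedded XML metadata), enumerate measurement
  directories, ingest peak-fit tables exported from external software;
* **peakfit** — locate candidate reflections with a continuous-wavelet-
  transform search and fit a composite model of area-parameterized
  Lorentzian/Gaussian/Voigt peaks on a shared baseline by
  Levenberg–Marquardt least squares, with every fit input persisted to JSON
  for exact re-runs;
* **llc** — calibrate scattering vectors against a reference standard,
  convert q ↔ d, and assign the mesophase from d-spacing ratios;
* **animl** — a typed AnIML (Analytical Information Markup Language)
  document model with XML round-tripping, for samples, experiment steps,
  measured series and appended analysis results;
* **omex** — bundle the AnIML master document plus companion files into
  COMBINE/OMEX ZIP archives with manifest and per-file RDF metadata;
* **synth** — a seeded generator of mesophase diffractograms with known
  ground truth, used throughout the test suite.

## The science in brief

A Bragg reflection at scattering vector `q` (nm⁻¹) corresponds to a
lattice-plane distance `d = 2π/q`.  Mesophases are identified from the ratio
pattern `d₁/dᵢ` of their reflections:

| phase | ratio pattern | lattice parameter |
|---|---|---|
| lamellar Lα | 1 : 2 : 3 : … | a = d₁ (layer spacing) |
| hexagonal H1 | 1 : √3 : √4 : √7 : … | a = d_hk · (2/√3)·√(h²+hk+k²) |
| bicontinuous cubic V1 | √(Nᵢ/N₁), N = h²+k²+l² over the space group's allowed reflections | a = d_hkl · √N |

Lamellar and hexagonal patterns are matched contiguously from the first
allowed reflection; cubic matching may skip weak allowed orders, as real V1
patterns often show only a subset (e.g. 211, 220, 310, 321, 611 for a
body-centred lattice).  Peak positions are first corrected with a linear
calibration `q_corr = (q_meas − b)/m` obtained by regressing measured
standard peaks against literature values.

## Worked example

`examples/assign_phase.py` pushes the five reflections of a body-centred
cubic cell with a = 2.17 nm through the assignment pipeline:

```
phase: V1 (Im3m, body-centred)
indices: 211, 220, 310, 321, 611
d ratios: [1.     1.1547 1.291  1.5275 2.5166]
lattice parameter a = 2.1700 nm (spread 4.44e-16 nm)
```

The ratio pattern √(N/6) with N = 6, 8, 10, 14, 38 identifies the
body-centred cubic phase, every reflection yields the same cell edge (the
spread is numerical noise), and the recovered `a` equals the input.

`examples/fit_peaks.py` fits a noisy synthetic hexagonal curve
(a = 2.87 nm, three reflections, signal-to-noise 50):

```
baseline I0 = 1.088 a.u., reduced chi^2 = 0.055
  qc = 2.5276 nm^-1   FWHM = 0.0808 nm^-1   A = 4.989
  qc = 4.3788 nm^-1   FWHM = 0.0790 nm^-1   A = 2.489
  qc = 5.0558 nm^-1   FWHM = 0.0765 nm^-1   A = 1.217
true positions: [2.5279 4.3785 5.0559]
```

All three centers are recovered to better than 0.02% and the generator's
peak width (0.08 nm⁻¹) to a few percent.  The other examples demonstrate
calibration against the bundled cholesteryl palmitate standard and the
PDH → AnIML → OMEX packaging chain.

## Command line

The same pipeline is available as a CLI for shell scripting:

```sh
saxskit convert measurements/ -o dataset.animl
saxskit fit dataset.animl sample01 -o fits/
saxskit analyze dataset.animl sample01 --centers fits/sample01.peak_centers.txt -o fits/
saxskit package dataset.animl fits/sample01.analysis.tsv -o dataset.zip
```

Exit codes: 0 success, 2 validation failure, 3 fit non-convergence, 4 I/O.

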