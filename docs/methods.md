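# Methods

This note records the models, numerical choices and open design decisions
behind `saxskit`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Peak model

Reflections in a background-corrected, line-collimated 1D SAXS curve are
modelled as area-parameterized profiles on a shared constant baseline `I0`:

* Lorentzian (default): `I(q) = I0 + (2A/π)·FWHM / (4(q−qc)² + FWHM²)`.
  Peak maximum `I0 + 2A/(πF)`, half maximum at `qc ± FWHM/2`, full-axis
  integral `A`.
* Gaussian: `I0 + A/(σ√(2π))·exp(−(q−qc)²/2σ²)`.
* Voigt: area-normalized Gaussian⊗Lorentzian evaluated through the Faddeeva
  function `wofz`; it reduces to the pure profiles in the zero-width limits
  (verified to 1e-6 max deviation in the tests).

The persisted width parameter is `sigma`; FWHM is derived per kind
(Lorentzian `2σ`, Gaussian `2σ√(2 ln 2)`, Voigt by the Olivero–Longbothum
approximation `0.5346·F_L + √(0.2166·F_L² + F_G²)`).  A *shared* additive
offset is used for multi-peak fits rather than per-peak offsets: independent
single-peak fits each carry their own offset, but in a simultaneous composite
fit separate offsets would be perfectly collinear.

Fits are Levenberg–Marquardt least squares (lmfit/`leastsq`) with `xtol` =
`ftol` = 1e-8 and an evaluation cap of 1000 per free parameter.  Amplitudes
are bounded below by zero, widths by ~0; optional per-peak center bounds are
honoured.  All settings and initial specs are stored in the persisted fit
result, so re-running a fit from its JSON spec file is bit-identical.

## Peak search

Candidates come from a continuous-wavelet-transform ridge search
(Mexican-hat kernel, scipy `find_peaks_cwt`) over a user width range in
samples (default 2–30, 15 widths, minimum ridge length = half the number of
widths, `min_snr` = 2).  Two deliberate robustness choices:

* candidates within one maximum width of either data boundary are dropped —
  the wavelet response there is dominated by edge ringing and by whatever
  low-q upturn the background has;
* `min_snr` is kept permissive (recall over precision), and insignificant
  fitted peaks are pruned *after* the fit: a peak is kept only if its fitted
  height exceeds 5× the residual standard deviation and its FWHM is at least
  the minimum search width (an ultra-narrow "peak" is a single noise spike).
  Automatic detection feeds initial centers with a bound of ±10 initial
  widths so a spurious model cannot wander across the spectrum.

## Calibration

`prepare_standard` regresses measured standard peak positions (dependent)
against literature positions (independent): `q_meas = m·q_lit + b`
(ordinary least squares; the two-point case uses the exact interpolating
line).  `calibrate` applies the inverse map `(q − b)/m`, so calibrating the
standard's own peaks returns the literature values up to regression
residual.  The bundled constants file ships nominal reference d-spacings for
cholesteryl palmitate (first-order lamellar spacing 5.25 nm with two higher
orders, a reconstruction of commonly quoted values) and silver behenate
(5.838 nm and orders); both are data, user-overridable via a constants file
of the same layout, and no quantitative result in this package depends on
them.

## Phase assignment

Given descending d-spacings, ratios `r_i = d₁/dᵢ` are matched against:

1. lamellar `1, 2, 3, …` — contiguous from the first order;
2. hexagonal `√(h²+hk+k²)` = `1, √3, √4, √7, √9, …` — contiguous;
3. cubic `√(Nᵢ/N₁)` over a space group's allowed `N = h²+k²+l²` list
   (tabulated for Ia3̄d, Pn3̄m and Im3̄m, the latter coinciding with the plain
   body-centred parity rule `h+k+l` even) — skipped allowed orders are
   permitted, since weak cubic reflections are routinely unobserved.

Every observed ratio must match within the relative tolerance (default 2%,
a typical peak-position precision; valid range (0, 0.1]).  Matching is
tolerance-monotone by construction.  Design choices where the field's
conventions leave room:

* **Priority lamellar → hexagonal → cubic.**  Two equally spaced orders
  (ratios 1 : 2) are also consistent with hexagonal (10)/(20) with (11)
  missing, and with several cubic patterns; the sparser interpretation wins.
  Contiguity for lamellar/hexagonal is what makes this tie-break meaningful.
* **Minimum evidence:** two peaks for lamellar/hexagonal, three for cubic;
  below that the result is the indeterminate phase (a value, not an error).
  With skips allowed, a two-peak "cubic match" would be nearly vacuous —
  most ratios can be approximated by √(N₂/N₁) for some allowed pair.
* **Cubic space-group scoring:** among fully matching groups, lowest RMS
  ratio deviation wins, then the fewest skipped allowed orders (this also
  pins the absolute indexing: a pattern starting at 211 is preferred over
  the same pattern read as starting at 222), then name order.  When the
  winning set is discriminated only by the body-centred parity rule the
  result is additionally labelled `body-centred`.  Among same-N index
  triples the conventional largest-h representative is reported (611, not
  532).
* **Lattice parameter:** per-reflection values
  (`a = d·(2/√3)·√(h²+hk+k²)` hexagonal, `a = d·√N` cubic, `a = n·d`
  lamellar) are always reported, with their spread (max − min) as a
  miscalibration diagnostic.  The headline `a` is the arithmetic mean for
  hexagonal/cubic and the first-order spacing for lamellar.

## Synthetic diffractograms

The generator emulates what reaches the analysis after instrument-side
background correction and deconvolution: Bragg peaks from the exact lattice
geometry of a chosen phase, a mild decaying background `c0 + c1·q^(−p)`
(default `c0 = 1`, `c1 = 0.5`, `p = 2`), and seeded Gaussian noise with
variance proportional to the signal (Poisson-like counting statistics),
scaled so the first peak's height-to-noise ratio equals the requested SNR
(default 50; the recovery property suite runs at 20).  Default peak shape is
Lorentzian with FWHM 0.08 nm⁻¹ and areas decaying geometrically by 1/2 per
order — higher orders of real mesophase patterns are weaker.  Default grids
are 2000 points spanning 0.4× the first to 1.15× the last peak.

What it does **not** emulate: instrumental smearing (beam-profile
convolution), detector artefacts, diffuse scattering from coexisting
disordered phases, and non-monotone backgrounds.  Passing recovery tests
therefore demonstrate the correctness of the detection → fit → assignment
chain under idealized but noisy conditions, not robustness to raw
uncorrected instrument output.

Test problem sizes were chosen to keep the whole suite fast while leaving
the statistics meaningful: 20 seeds per phase for the pipeline-recovery
property (hexagonal a = 2.87 nm with 3 reflections, body-centred cubic
a = 2.17 nm with 5, lamellar a = 2.28 nm with 2), at SNR 20.

## AnIML and OMEX dialects

The document model targets the AnIML 0.90 core structure: `SampleSet`,
`ExperimentStepSet` (each step = infrastructure/method/result) and
`AuditTrailSet`.  Scalars carry their kind through serialization (`<I>`,
`<F>`, `<S>`, `<Boolean>`); floats are written with `repr` so round trips
are value-exact.  The PDH mapping is: description → `Sample.name`; data
columns → a `SeriesSet` with q independent (unit 1/nm) and intensity
dependent (a.u.); header integers/reals and the embedded XML block → method
parameters prefixed `pdh.`, preserved verbatim rather than interpreted
(lossless round trip over semantics).  Series IDs follow
`<sampleID>/<column>`, which makes document-wide uniqueness structural.
Audit entries are appended by every mutating operation; because audit
timestamps would otherwise defeat byte-level reproducibility, all mutating
APIs accept an explicit timestamp and the workflow exposes it in
`RunConfig`.

Archives are COMBINE/OMEX ZIP containers written with fixed member
timestamps (again for byte-reproducibility).  The manifest lists every
member including itself; each content file gets its own
`<name>.metadata.rdf` with a minimal Dublin Core description (creator,
description, created).  The more common single-metadata-file convention is
accepted on read; the archive suffix (.zip/.omex) is not semantic.  PDH has
no registered format identifier, so a stable custom URI is used.

## Known limitations

* Intermediate, ribbon and nematic lyotropic phases are not in the pattern
  library; form factors and electron-density reconstruction are out of
  scope.
* Cubic matching with skips is powerful but can rationalize rich ratio sets
  that a human would reject; the reported RMS deviation and skip count
  should be inspected for marginal assignments.
* The fit supports only a constant baseline; strongly sloped residual
  backgrounds should be removed upstream.
* Strict AnIML XSD validation is not performed (structural validation
  only), and AnIML signature/checksum features are not implemented.
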