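# Methods

## Charge-state arithmetic and deconvolution

All m/z values use the adducted-proton convention *m/z = M/z + m_p* with
*m_p* = 1.00728 Da, the convention consistent with one-decimal m/z
reporting of average-mass protein peaks at low resolving power. Proteins
are handled in the average-mass regime throughout; small-molecule ligands
(< 1 kDa) are monoisotopic, since a sub-kDa loss read out as a mass
difference between two high-mass peaks tracks the monoisotopic ligand mass
(361.108 Da for bezafibrate, which rounds to the nominal 361, unlike the
average mass 361.820). Both constants are overridable per call.

`deconvolve_series` enumerates candidate charge assignments for an
ascending peak list — consecutive descending integers by default, any
strictly descending set optionally — up to a ceiling of 50 (covering
native proteins to ~1 MDa below m/z 20 000), scores each by the spread
(max − min) of the implied masses, and keeps the minimum. Ties break to
the lowest maximum charge, then the lowest mass, making the result
deterministic. Assignments with spread above a sanity bound (default 5 Da)
are rejected; a single peak raises an ambiguity error rather than guessing.
The published product pair 2097.5/2446.9 deconvolves to 14 675.40 Da with
0.093 Da spread; the holo α-globin pair 2259.9/2636.3 is self-inconsistent
by 0.49 Da at one printed decimal, which the 5 Da bound tolerates by
design (one-decimal rounding at ~2 500 Th can contribute up to
~0.05 Th × charge per peak, and the printed values appear rounded
independently).

## Targeting and confirmation

A target entry is a precursor (m/z, charge) plus the descending product
charges to monitor; the default table mirrors a four-protein liver
multiplex — free FABP1 (8+), the [FABP1+bezafibrate] complex (8+),
heme-bound α-globin (8+), ACBP (6+) — with 7+/6+ (or 5+/4+) products. The
ACBP intact mass (9 955.6 Da) is a synthetic ~10 kDa placeholder, not a
measured value. Mode validation flags precursors above the isolation
ceiling: 2000 Th for multiplexed quadrupole selection, 8000 Th for
single-precursor ion-trap selection; both are configuration constants.

Product matching is nearest-centroid within ±0.5 Th (one-decimal reporting
at low resolving power; configurable), ties broken to smaller |Δm/z| then
higher intensity. Peaks inside the precursor isolation window (default
4 Th wide) are never counted, and confirmation requires at least two
matched products — the MRM-like rule that makes the readout immune to
precursor-window interference. `confirm_targets` applies this to a
whole-dataset consensus: pixel spectra are averaged and centroided with
the noise floor scaled by 1/sqrt(n_pixels), which is the noise statistics
of the mean spectrum. A species confined to a small region (the vessel's
globin) is diluted in that consensus and may show only its strongest
product there; per-region imaging remains the sensitive readout.

## Neutral-loss analysis

`measure_neutral_loss` computes Δ = z_pre(m/z_pre − m_p) −
z_prod(m/z_prod − m_p), reported to 0.01 Da and as a nominal integer.
A product heavier than its precursor beyond 2 Da tolerance is an
inconsistent pair, not a negative loss. Ligand identification scans
k·mass_L for k = 1..3 at ±0.5 Da tolerance, ranking by |error| then
smaller k, so the stoichiometry falls out of the same search. The
charged-ligand search covers [L+H]+, [L+Na]+, [L+K]+ (adduct masses
1.00728 / 22.98922 / 38.96316 Da); an empty result on an HCD product
spectrum is the signature of neutral loss. Elemental masses come from
pyteomics' formula engine.

## Simulator

The simulator stands in for the dosed animals and the instrument; its
defaults are the study conditions the tests run under.

**Phantom.** A height × width frame (default 16 × 16 with a 1-pixel
background margin) of bulk tissue with an embedded disk vessel (radius
0.18 × min dimension). Free FABP1, the complex, and ACBP live only in
bulk; heme-bound α-globin only in the vessel. Abundances are a base of 100
(arbitrary units) with mild multiplicative lognormal heterogeneity
(σ = 0.1). The complex map is scaled per scenario: dosed_2h = 1.0,
dosed_6h = 0.3, control = 0. The 0.3 factor encodes the qualitative
2 h > 6 h ordering expected from fast drug clearance; no quantitative
ratio is claimed for real tissue, and the recovery tests check the
pipeline against whatever factor is configured.

**Spectra.** Gaussian peaks at each species/charge position with
FWHM = m/z / resolving power (default 1000, the low-resolution regime
tPTCR is designed for), area = abundance × envelope weight ×
accumulation. Default native charge envelopes peak at 8+ for 12–16 kDa
species and 7+ below 12 kDa. Additive Gaussian noise has per-channel
σ = floor + shot·sqrt(signal) (defaults 0.5 and 2.0) — a tractable
stand-in for counting statistics, deliberately left unclipped so that
window integrals are unbiased; ion images clip at zero at the end.
With the shot term dominant, replicate-to-replicate apex SNR grows as
sqrt(accumulation), which is what SIM accumulation buys. Centroiding
picks local maxima above 5 × floor separated by at least one FWHM and
reports intensity-weighted centroids over a ±FWHM/2 window. The profile
grid step is 0.1 Th (0.005 Th and resolving power 10 000 in the HCD
confirmation tests, reflecting the higher-resolution instrument used for
ligand confirmation as opposed to imaging).

**Reactions.** PTCR redistributes each charge-z precursor over z−k,
k = 0..2, with truncated-geometric weights (1−p)p^k renormalized
(p = 0.5 by default; the reaction kinetics are not modeled further), and
product m/z follows the mass-conserving ladder exactly. HCD converts a
fraction (the dissociation efficiency) of complex ions to free protein at
the same charge; the ligand leaves neutral and never appears as an ion.
Both conserve total ion population to machine precision.

**Acquisition.** One spectrum per pixel, unidirectional row-major
(image row 0 = first line, x along the scan direction). In tPTCR mode
each pixel's population is the isolated multiplexed cohort after PTCR.
Per-pixel RNG streams are spawned from the dataset seed, so identical
seeds give bit-identical datasets.

What the simulator does **not** model: liquid-junction extraction
chemistry, ion suppression, space charge, transmission functions, isotope
structure, peak asymmetry, or spatial correlation beyond the region
masks. Passing tests therefore demonstrate the correctness of the
arithmetic and the pipeline logic under a plausible noise model, not
instrument fidelity.

## Imaging

Image extraction integrates profile signal (trapezoid) or sums centroids
within ±match-tolerance of each predicted product m/z and sums over the
entry's product charges; the precursor m/z is not among the windows, so
precursor-window interference cannot change any pixel. Normalization is
raw by default (the normalization used for published tissue images is
rarely stated), with per-pixel TIC (0/0 → 0) and max modes available and
recorded in the image metadata. Composites max-scale each channel
independently and blend additively with clipping, the usual two-color MSI
overlay convention. Region statistics accept a detection threshold so
"fraction nonzero" can be read as a detection fraction against the
window-integrated noise level.

## Problem sizes

Defaults used by the test suite: 16 × 16 phantoms (12 × 12 and smaller in
unit tests), 1500–3000 Th at 0.1 Th steps, 100-replicate SNR estimates,
1000-case deconvolution oracle comparisons. These sizes were chosen as
comfortable desk-scale runs; everything scales linearly in pixels and
grid points if larger scenes are wanted.

## Known limitations

- Deconvolution assumes a single species per ladder; overlapping
  envelopes and untargeted full-spectrum deconvolution are out of scope.
- The isolation model is a hard window; no transmission edge effects.
- The dissociation efficiency is a free parameter, not a model of
  normalized collision energy.
- mzML support is a minimal writer/reader pair (uncompressed or zlib
  64-bit float arrays, unindexed documents) meant for single-spectrum
  exchange; imaging datasets use imzML via pyimzml.
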