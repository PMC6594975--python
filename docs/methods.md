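# Methods

## Signal model

The analysis assumes each unit (voxel, vertex, or ROI average) carries

    y(t) = b + a·r(t − d) + p(t) + e(t)

where `b ≈ 100` after intensity scaling, `a` is the response amplitude in
percent-signal units, `r` is a zero-mean periodic response shape with the
24 s fundamental of the 12 s A / 12 s B alternation, `d` is the response
delay after A-block onset, `p` is a slow scanner drift (polynomial of
order ≤ 2), and `e` is temporally correlated noise.  Only the fundamental
(10 cycles per 240 s scan) is analyzed; harmonics are ignored.

### Sampling convention

Samples sit at TR centers: after dummy removal, sample `n` represents
scan time `n·TR + TR/2` (TR = 2 s), matching data that have been
slice-time corrected to the middle of each TR.  The Fourier step treats
index `n` as time `n·TR`; the residual `+TR/2` offset is corrected
exactly once, by the `slice_time_shift` (default 1 s) term of the
phase-to-delay conversion.  With both conventions in place an injected
delay round-trips exactly through the pipeline (for the sinusoid shape;
the boxcar–HRF shape is recovered to within ~0.5 s because its
fundamental phase slightly leads its peak).

### Spectrum convention

Forward transform with the `e^(−iωt)` kernel; DC omitted; multiplied by 2
(single-sided) and divided by the number of samples, so a pure
`a·cos(2πkn/N + φ)` gives modulus `a` and angle `φ` at bin `k`.  All
delay arithmetic in `phasesign` depends on this one sign convention.

## Synthetic cohort generator

`freqtag.simulate` emulates ROI-average (or per-vertex) time courses with
the statistical structure the analysis assumes, not raw scanner data:

- **Design geometry** (fixed by the emulated study): TR 2 s, 12 s blocks,
  10 cycles per scan, 6 dummy TRs carrying signal that the pipeline
  removes — 126 samples per scan, 120 retained.
- **Response shape**: `sinusoid` (default, analytically tractable) or
  `boxcar_hrf` (A-block boxcar circularly convolved with a canonical
  two-gamma hemodynamic kernel).  Both are normalized to unit
  *fundamental* amplitude so the injected `amplitude` equals the bin-10
  modulus regardless of shape, and circularly shifted so the cycle peak
  falls at the requested delay.
- **Noise**: white Gaussian passed through an AR(1) filter
  (`noise_sd` = marginal SD, default 0.5 %-signal per TR;
  `ar1_coefficient` default 0.4).  The defaults are chosen as a
  realistic noise floor for an ROI-average time course — single-voxel
  noise is several-fold higher, but averaging over ≳50 vertices brings
  the per-TR SD to a few tenths of a percent.
- **Drift**: polynomial of order ≤ 2 on a [−1, 1] time axis (default
  coefficients (0, 1, 0.5) %-signal — about 1 % of mean intensity over a
  scan), fully absorbed by the Legendre detrending.
- **Between-participant variability**: Gaussian on amplitude (default SD
  0.1 %-signal, applied as a shared multiplicative scale across a
  participant's vertices) and wrapped-Gaussian on delay (default SD 1 s).
- **Eccentricity profiles**: piecewise-linear signed amplitude and delay
  vs. eccentricity; the default is positive inside the 2° figure
  boundary, crosses zero near 2.5°, and is negative in the 3–6°
  surround.  A block-order-reversed acquisition is emulated by shifting
  all profile delays by half a period.
- **Default cohort sizes**: 15 participants (14 for the
  attention-diverted replication), 4 scans per condition.

What the generator does **not** emulate: spatial autocorrelation between
vertices, motion artifacts, physiological (cardiac/respiratory) noise
structure, amplitude non-stationarity across cycles, and the 1–3 Hz
within-block stimulus modulations (only the 1/24 Hz fundamental is
simulated).  Passing tests therefore demonstrate correctness of the
analysis machinery under the assumed signal model, not robustness to
every property of real scanner data.

## Preprocessing choices

- Scaling divides each unit by its temporal mean (×100) and clips above
  at 200.  Values are additionally floored at 0 by convention
  (toggleable); scaling precedes detrending.
- Nuisance polynomials are built by QR on the sample grid, so the
  constant/linear/quadratic columns are exactly orthonormal on the
  discrete grid (a discrete Legendre basis).  Motion regressors, when
  supplied, are appended unorthogonalized; the projection handles
  collinearity by rejecting rank-deficient designs.
- Detrending is per scan (motion parameters are per-scan quantities);
  scans are averaged before ROI averaging.  For complete data the two
  averaging orders commute (tested); the stated order matters only under
  NaN padding.
- The Fourier transform is applied to the scan-averaged series (by
  linearity, identical to averaging per-scan spectra for complete data).

## Statistics

- One-sample Hotelling's T² on the (real, imaginary) pairs:
  `T² = n·m̂ᵀS⁻¹m̂`, `F = T²(n−2)/(2(n−1))` on F(2, n−2); two-sample:
  `T² = (n₁n₂/(n₁+n₂))·dᵀS_pooled⁻¹d`, `F = T²(n₁+n₂−3)/(2(n₁+n₂−2))` on
  F(2, n₁+n₂−3).  Exact p-values; no multiple-comparison correction
  anywhere (α = 0.05 per test, matching the emulated analysis); tests
  require n ≥ 3 (one-sample) and nonsingular covariance.
- Error bounds: the 1-SEM contour of the mean (level configurable via
  `sem_scale`) is parametrized via the principal-axis square root of
  S/n; extreme origin distances are found by a 721-point coarse scan plus
  bounded scalar refinement (robust for anisotropic, off-center
  ellipses), and validated in tests against a 10,000-point dense
  parametrization and the closed form for circular covariance.  When the
  origin lies inside the ellipse the lower bound is 0 — the geometric
  description ("shortest vector from the origin") does not cover that
  case, and zero is the attainable minimum.

## Sign and ambiguity rules

Half-open intervals at every boundary: delays in [2, 14) s are A-block
(+1), [14, 24) ∪ [0, 2) B-block (−1); delays in [0, 4) ∪ [12, 16) s are
crossover-ambiguous — signed, but never significant.  An exhaustive 1 ms
sweep verifies that the significance-eligible positive set is exactly
[4, 12), the negative set [16, 24), and their minimum circular separation
4 s (2 TRs).  Exact-boundary ties go to the later block; the emulated
analysis did not specify tie handling and measured delays are continuous,
so ties have measure zero.

## Sub-ROI bookkeeping

Band membership uses closed bounds (|ecc − center| ≤ 0.25°); bands
overlap by construction, so boundary vertices in adjacent bands are
intended.  The data-driven inclusion path (≥ 50 combined-hemisphere
vertices per participant, ≥ 3 surviving participants per band) is
authoritative; `standard_low_ecc_exclusions` is a convenience preset
reproducing the conventional outcome (V1 keeps 24 bands, V2 drops 0.25°,
V3 drops 0.25° and 0.5°; 69 analyzed bands).

## Whole-brain analysis

The identical cross-participant machinery runs per surface node on a
[nodes × participants] complex array.  Nodes with fewer than 3 finite
participant values (or degenerate covariance) are masked out and counted
in the log — the emulated analysis did not state its missing-data rule,
and ≥ 3 is the minimal choice for which the statistics are defined.  The
plotting mask requires p < α *and* a non-ambiguous delay.

## Cycle averages

Series are folded into 12-sample cycles; means and SEMs are computed
per cycle position, ignoring NaNs.  For a block-order-reversed condition,
6 NaN dummy TRs are prepended before folding so cycle positions align
with the other conditions; only complete cycles are folded, so with the
standard pad positions 0–5 average over 9 cycles and positions 6–11 over
10.  Group cycle averages take the SEM across participants, not across
cycles.  Positions observed in no cycle yield NaN with a warning.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at
the sizes the analyses themselves use: 126-sample scans, cohorts of
14–15 participants, 10,000-replicate null calibrations, 20-cohort
recovery sweeps, and a 1,200-node whole-brain surface in the drivers.
The per-vertex drivers simulate ~2,300 vertices over V1–V3 — enough for
every band to clear (or demonstrably fail) the 50-vertex criterion —
rather than full-resolution cortical meshes.

## Known limitations

- Only the stimulus fundamental is modeled and extracted; response
  asymmetries that load on harmonics are invisible.
- The error ellipse is a 1-SEM contour, not a confidence region at a
  stated coverage; `sem_scale` exposes the level.
- The NIfTI/GIFTI adapter surface is limited to the TSV/JSON interchange
  formats; projection from volumes to surfaces is out of scope and
  assumed done upstream.
- Atlas-ROI speckle removal (dropping vertices disconnected from the
  main cluster) requires mesh adjacency, which the pipeline does not
  consume, and is left to upstream tooling.
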