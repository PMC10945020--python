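# Methods

## The measurement model

A push-broom hyperspectral camera records a raw intensity cube
r1(row, col, λ) over 151 bands. Reflectance is obtained by dark/white
calibration, R = (r1 − r2)/(r3 − r2), applied element-wise with the dark
(r2) and white (r3) references broadcast against the cube (single frames,
per-band spectra and full reference cubes are all accepted, since
instruments differ in what they store). Bands where r3 = r2 are a hard
error naming the band: no value can be salvaged there. Reflectance is
**not** clipped to [0, 1] — specular pixels legitimately exceed the white
reference, and clipping would bias the scatter-correction statistics; the
only clamp in the workflow is at absorbance conversion,
A = log10(1/max(R, 1e−6)), which keeps shadowed or negative-calibrated
pixels finite (a fully dark pixel maps to A = 6).

Sausage foreground is a single-band threshold: R(695 nm) > 0.075, strictly.
Named wavelengths (695, 600, 550, 450 nm) use nearest-band lookup because
the camera's band grid is not guaranteed to contain them exactly; a
request outside the covered axis is an error.

Each connected foreground component is treated as one sausage and cut into
15 cross-sections of equal *area*: pixels are ordered by projection onto
the component's principal axis (eigenvector of the pixel-coordinate
covariance, sign-fixed for determinism, projection ties broken by
row/column) and split into contiguous groups whose sizes differ by at most
one pixel. Equal-count slicing, rather than equal-length, keeps tapered
ends from being under-represented. Every cross-section's mean spectrum
becomes one modelling row carrying the whole sausage's reference ATP value
— the bioluminescence assay measures the sausage, not the slice, so the 15
rows are replicate spectra of a single response.

## Pre-treatment chains

Steps: absorbance, SNV (sample n−1 standard deviation), MSC (per-spectrum
OLS against a reference spectrum, corrected = (x − a)/b; the reference is
the mean calibration spectrum), min–max normalisation, Savitzky–Golay
smoothing, and increment derivatives. Choices worth stating:

- The derivative is literally the increment between consecutive bands of
  the smoothed spectrum — not an SG derivative kernel — applied after a
  degree-2, 5-band SG smooth (per application, so a second derivative is
  the composition of two first derivatives). The increment is not divided
  by the band spacing; on an even grid that is a constant factor absorbed
  by the regression. The band axis shrinks by one per order and moves to
  interval midpoints; this bookkeeping is carried through to the
  regression vector so pixel-wise prediction stays aligned.
- SG smoothing is materialised as an explicit band × band linear map:
  interior rows are the centred SG coefficients, edge rows are
  least-squares polynomial fits on the window truncated at the array
  boundary (degree reduced when fewer points than degree+1 remain). A
  single matmul then smooths an entire unfolded pixel table.
- "Normalisation" is per-spectrum min–max scaling to [0, 1]; vector-norm
  and area normalisation are defensible alternatives, min–max was fixed
  here once and is tested as such.
- Chains are fitted on the calibration subset only; the fitted object
  replays identical state on prediction rows and pixels. The leakage test
  perturbs non-calibration rows and asserts the fitted state is unchanged.
- Pixel-wise application uses a guarded variant: a pixel whose spectrum is
  constant (SNV/normalise undefined, MSC slope ≈ 0) is flagged, rendered
  as background and counted, instead of aborting the map.

## Splitting and regression

Kennard–Stone runs on the pre-treated spectra (the alternative — splitting
on raw spectra — is equally defensible; pre-treated was fixed because the
split should see the geometry the model sees). For the MSC chain this
poses a chicken-and-egg problem: the reference needs a calibration set
that does not exist yet. The split therefore uses a provisional reference
fitted on all rows, after which MSC is refit on the selected calibration
subset for all modelling — the provisional fit influences only which rows
are selected, never the model state. The calibration size is
round(2n/3); the greedy selection (seed with the most distant pair, then
add the row maximising its minimum distance to the selected set) is
deterministic with ties broken by lowest row index, so duplicate rows
never raise.

The split operates at cross-section level (15 rows per sausage). This
reproduces how the calibration population was actually expanded, but it
lets replicates of one sausage fall on both sides of the split, so the
prediction set is not fully independent of the calibration sausages —
a known optimism source inherited by design, noted here rather than
hidden.

PLSR uses scikit-learn's NIPALS implementation with no variance scaling
and is collapsed to (b0, b) by probing the fitted affine map at zero and
at the unit vectors — exact, and independent of how the library
parameterises centring. The component count is the smallest minimiser
(ties within 1e−12 go to fewer components) of the leave-one-out RMSECV
over 1..max_components, capped by min(20, n/3) by default and always by
the rank of the centred calibration matrix; each LOO fold caps its own
component count by the deflated fold's rank. LOO folds reuse the
pre-treated matrix (MSC is not refit inside folds by default, matching
common chemometrics practice; refitting would couple fold spectra through
the reference).

Metrics: R² = 1 − SS_res/SS_tot with the evaluated subset's own mean;
RMSE = √(SS_res/n), in log10 mol/L.

## Response-surface analysis

The casing experiment is a 2^(5−1) central composite design: 16 cube
points (±1 coded), 10 axial points (±2), 6 centre replicates; factors and
one-coded-unit steps are soy lecithin 3.33 ± 1.11 g/100 g, soy oil
1.875 ± 0.625 g/100 g, duration 75 ± 15 min, lactic acid 292.5 ± 22.5
µl/15 g NaCl, orange extract 0.28 ± 0.145 g. Coded levels are inferred by
snapping (x − centre)/step to the nearest canonical level with a 0.25
coded-unit tolerance, because published factor settings are rounded (the
same +1 orange-extract level appears as 0.41, 0.42 and 0.43 g); trusting
the printed digits would mis-code runs.

The 21-term coded quadratic is fitted by OLS (statsmodels); standard
errors use σ̂² = SSE/11, p-values two-sided from t(11). A zero-SSE fit
(simulated noise-free responses) is flagged degenerate rather than raising
so exact-recovery tests remain expressible. Uncoded coefficients are
obtained by algebraic substitution z = (x − c)/s and collecting terms, so
coded and natural-unit predictions agree to machine precision — re-deriving
them from rounded settings would not.

The ANOVA is sequential (type-I) with terms entered in the canonical
order: linear, squares, interactions. In this design the linear and
interaction columns are orthogonal to everything else, so their sequential
and adjusted (type-III) SS coincide; only the squares differ. Pure error
is the within-replicate SS of runs with identical coded settings (the 6
centre points, 5 df); lack of fit is the residual remainder (6 df), tested
by F(6, 5). Invariants asserted on every fit: SS and df additivity,
contributions summing to 100 %.

One published summary cell (a pooled "Constant" row with 5 df and SS
6.9374 — numerically the sum of the five linear sequential SS) follows a
Minitab layout convention this package does not reproduce; per-term rows
and the pooled Error/Lack-of-fit/Pure-error/Total rows are the supported
output.

Evaluating the *published, rounded* uncoded equation at the design
settings reproduces the published predicted column only loosely; the refit
model is the normative reproduction, and the published coded coefficients
are carried only as generating ground truth for simulation-recovery
checks.

## The synthetic-scene generator

What it emulates: a 151-band grid (350–1100 nm in 5 nm steps — the band
count is known, the range is this package's assumption; the grid contains
every named wavelength), elongated elliptical sausages on a dark
background (background reflectance 0.02, safely under the 0.075 threshold
at 695 nm), and an ATP→spectrum relationship built as a convex mixture of
two smooth Gaussian-on-baseline endmembers peaking near 410 nm and 680 nm
— the spectral regions where spoilage-driven variation concentrates. The
mixture weight is the sausage's ATP rescaled over a fixed −10…−4 log10
mol/L span, making the map injective and pointwise increasing: spoiled
(high-ATP) sausages reflect more everywhere, most strongly in the red.

Disturbances, all in reflectance units: a multiplicative gain field
(1 + m), a constant-across-bands additive offset field, and independent
band-wise noise. Gain and offset are spatially *smooth* Gaussian fields
(12 px correlation length, per-pixel marginal sd as configured): scatter
on a curved, glossy casing varies with surface geometry, not pixel by
pixel, and smoothness is what lets scatter survive into 400-pixel
segment means — with white per-pixel noise the segment averaging would
remove virtually all scatter and scatter correction would have nothing to
do. Defaults describe a careful but scatter-limited bench acquisition:
gain sd 0.15, offset sd 0.001, band noise sd 0.001. Raw counts are
emitted as dark + R·(white − dark) with smooth synthetic dark/white
spectra, so zero-noise calibration inverts the construction to machine
precision. A generated scene whose realised noise makes foreground and
background overlap at the 695 nm band is rejected as an unusable fixture.

What it does not emulate: wavelength-dependent (tilted) scatter,
specular glare, shadows, casing translucency, temperature drift, sensor
nonlinearity, or realistic lamp/camera spectral responses. Passing tests
on these scenes therefore demonstrate that the algorithms are implemented
correctly and behave as expected under the stated noise model — not that
the published prediction accuracies would be reproduced on real
hypercubes, which were never deposited.

The benchmark recovery scene (ten 220 × 160-px sausages, ATP evenly
spaced −9.4…−4.4, 150 segment spectra) is the standard problem size for
full-pipeline checks; it keeps the whole suite comfortably fast while
leaving enough rows for a meaningful 2/3–1/3 split.

The design-response simulator draws y = M(coded)·β + N(0, σ) per run and
is used to verify that refitting recovers a known β.

## Distribution maps

Masked pixels are unfolded with their coordinates, pre-treated with the
calibration-time chain state, multiplied by the regression vector (plus
intercept), and refolded. Map generation never mutates model or chain
state. The colour scale is linear; default limits span the calibration
ATP range so maps of different sausages are comparable, and out-of-range
pixels clamp to the endpoint colours. For a linear chain the mean pixel
prediction over a segment equals the prediction of the segment-mean
spectrum exactly; for nonlinear chains (SNV) this holds only
approximately and is asserted at 0.2 log-unit tolerance on low-noise
scenes.

## Known limitations

- The published PLSR performance table cannot be reproduced without the
  original hypercubes; the package substitutes exact algorithmic oracles
  plus synthetic-data behaviour (pre-treatment ordering, parameter
  recovery) for it.
- The two-endmember linear mixture makes the spectrum→ATP relationship
  low-rank and nearly noiseless after perfect scatter correction; real
  spectra carry chemical interferents that would lower every R².
- Segment-level splitting leaks replicate structure (see above); a
  sausage-level split option exists for stricter validation.
- The 695 nm/0.075 segmentation assumes a black background; bright or
  reflective backgrounds defeat it.
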