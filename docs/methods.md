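# Methods

`gelquant` automates the "greater than *X* kb" quality standard for genomic
DNA run on agarose gels: the percent of a lane's DNA signal at or above a
chosen ladder-band size, reported in GGBN Gel Image Vocabulary terms
(`DNAThreshold`, `percentAboveThreshold`). This note describes the models and
numerical choices behind each stage, what the synthetic-gel generator does
and does not emulate, and the package's known limitations.

## Scoring model

**Coordinate convention.** Rasters are (row, col), 0-based, wells at row 0;
migration distance increases downward. Input photographs are assumed
light-background with dark DNA; inversion makes DNA bright so density curves
are positive.

**Migration calibration.** Migration distance is modelled as linear in
log10(fragment size), the standard first-order description of agarose
electrophoresis: `d = a + b·log10(bp)`, `b < 0`. The model is least-squares
fitted to matched (band position, band size) pairs from a ladder lane; at
least two pairs are required, per-band residuals are exposed so curvature is
visible, and predictions outside the calibrated size range carry an
explicit extrapolation flag. A monotone-spline alternative was considered
and rejected: the built-in λ/HindIII ladder spans 564–23,130 bp where the
log-linear law is adequate, and residual reporting lets users detect when it
is not. The λ/HindIII catalog entry carries the seven routinely visible
bands (23,130; 9,416; 6,557; 4,361; 2,322; 2,027; 564 bp); the 125 bp
fragment is excluded as routinely invisible. All bands except the smallest
are offered as threshold candidates.

**Background subtraction.** The smooth background (staining gradients,
illumination vignette) is estimated by a grey-level morphological opening
with a paraboloid whose curvature matches a rolling ball of radius *R* under
the 8-bit height convention (curvature `1/(2·R·255)` on a [0, 1] image).
Two numerical choices matter:

- *Pre-smoothing.* The opening of a noisy surface rides the noise minima
  (an envelope bias of roughly 2σ of the pixel noise). The background is
  therefore estimated on a Gaussian-smoothed copy (σ = 2 px) of the image
  and subtracted from the unsmoothed image — the same reason ImageJ smooths
  before rolling its ball.
- *Radius.* The radius must satisfy two competing constraints. The ball
  must not dip laterally into the gaps between lanes, or it shaves faint
  broad smears by `h²/(2·R·255)` (h ≈ the lane half-width plus ramps); for
  24 px lanes this demands R ≳ 1000. It must remain curved enough to follow
  the illumination vignette (curvature ≈ amplitude/σ², ≈ 1e-6 per px² for
  the backgrounds targeted here), demanding R ≲ 1900. The default is
  R = 1200, inside that window; it is exposed as configuration. Each 1-D
  quadratic erosion/dilation pass is computed as a lower-envelope transform
  in O(N) per line (numba-compiled, with a NumPy fallback), so large radii
  cost nothing.

The opening itself is exactly idempotent; with pre-smoothing and sensor
noise a second subtraction can still remove up to ~2e-3 of rectified-noise
pedestal, which is inherent to every rolling-ball implementation.

**Leveling.** The image is rotated about its centre (bilinear resampling)
so the top ladder-band centres in the two flanking ladder lanes share a
row. Pure rotation only — no shear. Leveling is optional in practice
because the threshold line (below) already compensates linear tilt; it
remains useful for visual audit.

**Lane profiles.** A lane is a vertical box; all boxes in one analysis
share the same vertical extent. The 1-D profile is the *mean* intensity
across the box width per row (ImageJ sums; the mean makes profiles
invariant to box width on laterally uniform lanes, and the final percentage
is identical either way). Automatic lane proposal — peaks of the detrended,
smoothed column mean, refined to half-height centroids — is a convenience;
manual layouts are authoritative.

**Threshold line and integration.** Ladder-band apexes are detected as
local maxima with prominence ≥ 5% of the profile maximum, refined to
sub-pixel by parabolic interpolation, and matched to band sizes by an
exhaustive order-preserving assignment that minimises the RMS of a
log-linear migration fit (ties between equal-height candidates therefore
resolve toward the position the migration model expects). With several
ladder dilution lanes per side, the lane with the most assigned bands wins;
ties go to the brightest (least-diluted) lane. The DNA-threshold row for
every sample lane is the straight-line interpolation between the chosen
band's apex in the left and right ladder lanes — this is what makes the
method robust to residual linear skew. Areas above (toward the wells, i.e.
fragments at or above the threshold size) and below are trapezoidal
integrals of the closed profile; the trapezoid cell containing the
(fractional) threshold row is split exactly, so the two areas always sum to
the total integral. Closing a profile whose terminal value exceeds 1% of
its maximum is a recorded vertical drop that adds no area. Artifact masking
replaces a user-specified row interval with the straight chord between its
endpoints — masking is deliberately manual, mirroring the judgment-based
step it automates. Lanes whose total area is below 1e-6 per profile row are
reported as undefined (null), never as 0%.

**Quality annotation.** A lane with ≥ 50% of signal above the 9,416 bp
threshold may be annotated `genomicQuality: true`. This is an optional
candidate indicator, never a filter, and is only defined for the 9,416 bp
threshold.

## Synthetic gels

The generator exists so every pipeline stage can be tested against known
truth. Each sample lane's fragment-size distribution is a two-component
mixture on the log10(bp) scale: a narrow "intact" high-molecular-weight
component (default centred at 30 kb, σ = 0.04) and a broader "degraded"
smear (default centred near 2.8 kb, σ = 0.30). The mixture describes DNA
*mass*, because intercalating stains bind per base pair; the true percent
above any band size is then a closed-form sum of Gaussian tail masses.
Rendering maps mass density through the log-linear migration model (a
Gaussian mixture in row coordinates, with the band spread σ_band = 3 px
added in quadrature — the convolution is exact), broadcasts it across a
flat-top lane cross-section with cosine shoulders, and applies, in order:
artifact specks (Gaussian blobs), gel skew as a small-angle vertical shear,
background (constant 0.08 plus a Gaussian vignette dome of amplitude 0.06),
photographic inversion, and Gaussian sensor noise. The default noise is
σ = 0.005 of full scale, representative of the 16-bit cooled-CCD gel
imagers this workflow targets. The default frame is 400 × 440 px with the
23,130 bp band at row 60 and the 564 bp band at row 340; ladder band masses
scale as √bp — a deliberate stylisation between equimolar mass (∝ bp, which
would render the 564 bp band invisible) and equal masses, keeping all seven
bands detectable as on a well-loaded gel. A seed fully determines the
image.

`degrade(spec, hours)` scales each lane's intact fraction by `exp(-k·t)`
(default k = 0.15 h⁻¹) and drifts the smear centre downward, emulating the
qualitative loss of high-molecular-weight DNA with time since death. The
rate constants are purely synthetic; no quantitative degradation rates are
claimed.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real gels: band saturation and camera nonlinearity,
lane curvature ("smiling") and per-lane vertical warping, well retention
and comet tails, stain-dependent spectral effects, and spatially
correlated background texture. Recovery figures measured on synthetic gels
(mean |error| ≈ 1 point, max ≲ 4 points at default noise) are a lower
bound on real-world error, not an estimate of it.

## Scoring-consistency analysis (Gage R&R)

Repeated scores (sample lanes = parts, scorers = operators) are decomposed
by a balanced two-factor crossed ANOVA with interaction, solved through the
expected mean squares. The part × operator interaction is pooled into
repeatability when its F-test against error gives p > 0.25 (standard MSA
practice); negative variance estimates are truncated to zero and flagged.
Reported percentages are percent of *study variation* (standard-deviation
scale), so repeatability and reproducibility combine in quadrature to the
total Gage R&R — the convention under which the published worked examples
(3.99/5.71 → 6.97; 22/18.1 → 28.5) are internally consistent. The 5.15σ vs
6σ study-variation multiplier question is moot for these ratios. Totals
under 10% classify as acceptable, 10–30% as conditional, ≥ 30% as
unacceptable (boundaries exclusive). A study with zero total variation is
flagged degenerate rather than classified.

One property worth noting: with a truly null operator effect, the
*estimated* reproducibility is exactly zero in just over half of seeded
studies (truncation) but fluctuates up to a few percent of study variation
otherwise, because a null interaction term is retained by the p > 0.25
rule about a quarter of the time. Tests assert that measured distribution
(median 0, ≥ 85% of seeds below 3% SV), and median absolute recovery error
of every % study-variation figure stays ≤ 2 points across 200 simulations.

## Problem sizes

Test and acceptance runs use 400 × 440 px gels with 4 sample lanes (the
40-lane record-count check uses a wider frame), 50 gels for recovery, 100
lanes for the integration-oracle comparison, 10 seeds per arm for the
degradation series, and 200 simulated measurement studies for Gage R&R
recovery — sizes chosen so the whole suite completes in well under a
minute of compute while keeping Monte-Carlo fluctuation far from the
asserted tolerances.

## Known limitations

- The percent-above-threshold statistic inherits every bias of gel
  densitometry: staining nonlinearity, saturation, and background residues
  shift it at the level of a few percent.
- Calibration assumes strict log-linear migration; badly overloaded or
  pulsed-field gels violate it.
- Lane boxes are rectangles; curved lanes need manual, conservative box
  placement.
- Artifact removal is manual by design; there is no automatic speck
  detection.
- The Gage R&R module handles balanced crossed designs only.
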