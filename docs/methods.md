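# Methods

`smpull` reimplements the computational analysis of an aptamer-assisted
single-molecule pull-down (SiMPull) assay for protein aggregates in serum:
diffraction-limited spot counting of α-synuclein and amyloid-β aggregates,
dSTORM-based morphology of individual aggregates, and the cohort-level
statistics that turn both into a PD-vs-control biomarker. Because no raw
patient imaging data are available, every stage is exercised against a
synthetic-data generator with exact ground truth; this note records the
models, the defaults, and what the synthetic results do and do not show.

## Synthetic aggregates and imaging

**Shapes.** An aggregate is a star-convex polygon: a unit circle perturbed by
3–4 random cosine harmonics (relative amplitude ~0.06), squeezed along one
axis until the polygon's circularity `C = 4πA/P²` equals the requested
value (solved by root finding on the exact polygon), then scaled to the
requested perimeter. Perimeter, area and circularity are therefore known
analytically for every simulated aggregate. Binding sites are sampled
uniformly inside the polygon at one site per (20 nm)², so a localization
cloud at the default blink density fills the shape at the rendering
resolution.

**Diffraction-limited acquisition.** Camera model: 103.5 nm pixels, Gaussian
PSF with σ = 1 px (≈ the diffraction limit for a far-red dye on a 1.49 NA
TIRF objective), 50 frames at 50 ms (tests use shorter stacks), uniform
background (50 photons/px/frame), Poisson shot noise, Gaussian read noise
(1.5 e⁻ RMS), linear gain (10 ADU/photon). EMCCD excess noise and pixel
crosstalk are deliberately omitted — detection-stage tests do not need them.
Each aggregate's per-frame brightness (ADU) is split over its binding sites
and splatted with the PSF; with noise disabled the stack conserves assigned
brightness to the PSF-truncation level (<0.1%), which anchors the intensity
tests. Per-spot brightness is lognormal with median 18,000 ADU and σ = 0.5,
placing the 75th percentile at ≈25,000 ADU — the assay's high-intensity cut
sits near the 75th percentile of typical samples.

**Blinking (dSTORM) acquisition.** Each binding site fires
Poisson(20) bursts at uniformly random frames over 6000–8000 frames; each
blink is displaced by the stage drift at its frame plus isotropic Gaussian
localization error (default 20 nm, the assay's working resolution). Burst
photon counts are lognormal around 1000. Dark-state kinetics, bleaching and
multi-frame on-events are not modelled: the analysis chain consumes
(position, frame) pairs and is insensitive to the temporal fine structure,
but this means frame-to-frame blink correlations in real data are not
exercised. Drift defaults to 100 nm accumulated over the acquisition
(linear), with sinusoidal and null variants for testing.

## Detection and measurement

**Spot counting.** Stacks are averaged pixel-wise; pixels above
`median + k·1.4826·MAD` (default k = 4) are grouped into path-connected
components (8-connectivity), and components of 2–100 px become spots.
Labelling is `scipy.ndimage.label`; the test suite checks it against a
brute-force flood fill. Spot intensity is the sum of (pixel − local
background) over the component, floored at 0, with the local background the
median of a 2 px dilated ring around the spot (other detections are excluded
from the ring). Spots touching the image border are kept but flagged.

**Frame fitting.** dSTORM frames are scanned for local maxima above the
robust threshold; candidates closer than 4 px are dropped as collisions, the
rest are fit with a 2-D Gaussian + offset by least squares in a 7×7 window.
The reported uncertainty is the least-squares precision bound
`var = s_a²/N · (16/9 + 8π s_a² b/(N a²))` with `s_a² = s² + a²/12`;
Monte-Carlo scatter agrees with it within a few percent at the default
photon budget.

**Drift correction.** Redundant cross-correlation: localizations are split
into 15 time bins, each bin rendered as a smoothed 20 nm histogram, all bin
pairs registered by sub-pixel phase cross-correlation, and the
overdetermined pairwise shifts solved by least squares (first bin anchored
at zero). Per-frame drift is linear interpolation between bin centres.
Injected 100 nm linear and 50 nm sinusoidal drifts are recovered to ~1–3 nm
residual RMS at the default scene density; bins with fewer than 50
localizations abort the correction with a warning rather than apply a noisy
estimate.

**Rendering and segmentation.** Localizations are rendered at 20 nm — the
working resolution; no rendering pixel is dictated by the assay — either as
a count histogram (conserves counts exactly) or as Gaussian splats with each
localization's own uncertainty. Segmentation binarises the splat density,
fills holes, labels 8-connected components, and discards components
supported by fewer than 10 localizations (isolated single antibodies are
small, round, and sparse). The binarisation is adaptive: a coarse absolute
threshold (1 localization per pixel) finds candidate components, then each
component is re-thresholded at half its robust peak density (95th
percentile). Placing the boundary at the half-maximum of the blurred edge
keeps perimeters unbiased to first order in the ~28 nm effective blur
(20 nm localization error ⊕ 20 nm pixelisation); a fixed absolute threshold
would instead dilate every boundary by a blur-dependent margin.

**Morphology.** Area is pixel count × (20 nm)²; perimeter is the length of
the sub-pixel 0.5-level contour of the σ = 0.8 px Gaussian-smoothed mask
(marching squares); circularity is `4πA/P²` clipped to 1; single-pixel
components are flagged degenerate. The smoothed-contour estimator was chosen
over 4-direction Crofton after benchmarking both on closed forms: Crofton
underestimates an axis-aligned square by ~5% (three-shape oracle: disc,
square, 2:1 ellipse, all within 5% of their closed-form circularities at
20 nm pixels; the ellipse perimeter oracle is Ramanujan's approximation).
Crofton remains available via `SegmentParams(perimeter_method="crofton")`.

Resolution floor: an aggregate with 0.1 µm perimeter is a ~16 nm-radius
object, below the blur floor; its measured perimeter is blur-dominated and
biased high. End-to-end shape recovery is therefore quantified as
correlation with truth (r > 0.9) over perimeters 0.1–1.0 µm but relative
perimeter error (<15% mean) only from 0.3 µm up. Thin sub-resolution
features likewise bias circularity upward.

## Cohort model

Samples are drawn per group (20 PD / 20 control by default, 28
diffraction-limited and 6 dSTORM fields per sample):

* **Counts.** Per-sample mean spots/FoV come from a zero-truncated normal
  whose parent parameters are moment-matched so the *truncated* draw carries
  the study's group moments — α-syn 200±100 (PD) vs 120±60 (control), Aβ
  140±120 vs 150±100. Field-level counts are Poisson around the sample mean.
* **Shared capture efficiency.** Both channels of a sample are multiplied by
  one lognormal efficiency factor (mean 1, CV² = 0.2), with the biological
  spread shrunk so the marginal moments above are preserved. This is the
  mechanism that makes the α/(α+β) ratio outperform raw counts — the shared
  nuisance cancels in the ratio — mirroring why the assay uses the
  proportion rather than absolute counts. The CV is a modelling choice; the
  study gives only the qualitative statement.
* **Morphology.** Log-perimeter is normal with within-sample SD 0.45 and
  between-sample SD 0.06; logit-circularity likewise with 0.8 / 0.12. Group
  centres are derived in closed form from the printed contrasts: the
  group-averaged cumulative difference of two equal-width Gaussians peaks
  midway between centres with height 2Φ(δ/2)−1, so the printed
  (threshold, max difference) pairs — 0.24 µm/3.6% and 0.64/9.5% for α-syn,
  0.31 µm/3.0% and 0.7/5.0% for Aβ — fix the centres exactly. The
  within/between split is a choice: it sets how discriminative the
  per-sample distinct fraction is (here, morphology alone separates groups
  at AUC ≈ 0.85, consistent with the assay's morphology discriminator).
* **Intensities.** Identical across groups (antibody imaging showed no
  intensity difference); per-spot lognormal as above.

Two fidelity levels: `metrics` emits counts/intensities/morphology straight
from this model (used for replicate studies — a full image-level study
cohort is far beyond desk-scale compute); `images` renders every field and
runs the complete detection chain, used on miniature cohorts in the
end-to-end tests.

## Biomarker statistics

Group cumulative histograms average per-sample ECDFs (pooling would
overweight high-count samples) on a 200-point grid spanning the pooled
range. The perimeter threshold P* maximises (control − PD); the circularity
threshold C* is found the same way among aggregates with perimeter > P*
(falling back to all aggregates if the subset loses a group). The distinct
fraction is the proportion of all α-syn aggregates with perimeter > P* and
circularity > C* (strict inequalities; the denominator is all aggregates —
the nested-conditional variant is a one-line change). The combined score is
`R · f_distinct` with `R = α/(α+β)`.

Two-sample comparisons pass each group through a Kolmogorov–Smirnov check
against a normal with the sample moments at α = 0.05; if both pass, Welch's
two-tailed t-test, otherwise the Mann–Whitney U test. (A KS test with
estimated parameters is conservative as a normality gate; the gated
procedure's empirical size is ≈0.045 at n = 15, verified over 1000 null
replicates.) ROC analysis uses the Mann–Whitney AUC estimator (tied pairs
count ½), which equals the trapezoidal area under the full-threshold curve;
the AUC interval is Hanley–McNeil, and Wilson score intervals are attached
to sensitivity and specificity at the Youden-optimal point (Wilson intervals
are the score-based intervals for binomial proportions, which is what an
operating point's sensitivity and specificity are).
No multiple-testing correction is applied across the four
prespecified discriminators. PD is the positive class throughout; the Aβ
count discriminates in the opposite direction, so its reported headline
value is the flipped AUC.

## Problem sizes and numerical choices

Replicate studies run at the study scale (20+20 samples, 28/6 fields) on the
`metrics` level: 25 replicates for the reported AUC/threshold means, 100 for
the discriminator-ordering check. Image-level tests use 96–256 px fields,
4–20 frames, and 300–6000 dSTORM frames. Ties in threshold grids break
toward the smallest threshold; identical CDFs return the first grid point
flagged degenerate; empty samples are excluded from group CDFs with a
warning; constant samples force the nonparametric branch. All randomness
derives from one seed through named, independent sub-streams, so adding a
stage never perturbs another stage's draws; reports are byte-identical
across reruns of the same configuration.

## Limitations

The generator does not model aptamer/antibody binding chemistry, serum
autofluorescence, fluorophore photophysics beyond Poisson blink counts, or
non-specific surface binding; group differences enter only through counts
and morphology. The shared-efficiency CV and the morphology within/between
split are modelling choices constrained by qualitative statements, not
printed numbers — the ratio and combined-score AUCs of real cohorts depend
on exactly these quantities. Passing synthetic tests demonstrates that the
analysis chain recovers known truth under this model, not that the model
captures all serum-imaging artefacts.
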