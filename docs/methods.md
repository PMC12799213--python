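# Methods

This note documents the models, numerical choices and known limitations of
syribbon-quant, in the spirit of a software methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Segmentation and morphometry

**Background subtraction.** Per z-plane rolling-ball subtraction,
implemented as a grayscale opening with a flat disk of the stated physical
diameter (RIBEYE 0.3 µm, Bassoon 0.1 µm, Ca_V1.3 0.08 µm by default).
Opening removes structures smaller than the ball from the background
estimate, so compact puncta survive subtraction essentially intact. The
operation is 2D per plane rather than 3D because at 80/80/200 nm anisotropy
a 3D ball of sub-µm diameter spans at most one or two z-steps; a ball
smaller than one pixel triggers a warning and an identity transform.

**Detection.** The interactive surface-detection stage it replaces exposes a
"surface detail" smoothness scale; we interpret that scale as the σ of a
Gaussian smoothing filter (default 0.16 µm) applied before thresholding.
Thresholding defaults to Otsu on the smoothed volume, with an absolute
override, because the original workflow thresholded manually per channel.
Manual curation (adding missed surfaces, splitting merged ones) is replaced
by deterministic parameters; this is a fidelity limit — equivalence with the
interactive workflow is not claimed. Components are labeled at
26-connectivity (configurable 6/18/26), components with fewer than 10
voxels are discarded, and downstream analysis applies inclusive 0.02–2 µm³
volume bounds. Inclusivity and connectivity defaults are our choices; the
conventions upstream tools use are not documented.

**Volume** is voxel count × voxel volume. **Surface area** comes from a
marching-cubes isosurface of the binary mask (anisotropic spacing honored),
with each facet's area projected onto the local normal of a
Gaussian-smoothed (σ = 1 voxel) copy of the mask. The projection removes
the voxel staircase — plain marching cubes on a binary ball overestimates
area by ~9%, which would bias the Wadell sphericity
Ψ = π^⅓(6V)^⅔/A of a true sphere to ~0.92 — while leaving axis-aligned
planar faces untouched (their smoothed normal coincides with the facet
normal, so projection is the identity there). Against closed forms at 20 nm
voxels this estimator gives Ψ ≈ 0.99 for a digitized ball (analytic 1.0)
and Ψ ≈ 0.82 for a cube (analytic 0.806). Simple voxel-face counting is
retained (`voxel_face_area`) as a brute-force oracle only; it overestimates
smooth-surface area by up to 50% and is never used by the main path.

**Distances.** Spot-to-spot distance is the minimum Euclidean distance
between boundary-voxel centers (0 for overlapping masks). Whether the
interactive tool measures boundary-to-boundary or centroid-based distances
is not documented; boundary-to-boundary is the more literal reading of a
"surface-to-surface" threshold and is what we implement. Proximity
classification pairs each query spot with its nearest reference iff within
the threshold (0.06 µm for pairing, 0.045 µm for the stricter
ribbon-associated class); ties break to the smaller reference id.

## Cell geometry and colocalization

The cell outline is recovered per plane from the membrane channel (Otsu +
hole filling); a thin outline that fails to close raises an error, while a
solid polar cap is accepted. The peripheral ring is the inward band of 1 µm
physical depth (Euclidean distance transform), the interior is the filled
remainder, and analysis uses the central planes — all nonempty planes
excluding the basal and top one, with a warning when fewer than three
remain. The periphery:interior ratio is the per-plane ratio of mean
intensities averaged over central planes; a zero interior mean is reported
as undefined (NaN) rather than inflated.

Pearson correlation is computed over masked voxels (≥10 required). Manders
coefficients are the thresholded variant; auto-thresholds follow the Costes
bisection — ordinary least-squares regression of B on A, then the largest
threshold pair on the regression line whose sub-threshold population has
correlation ≤ 0. The plug-in this mirrors uses orthogonal regression; OLS
is a deliberate simplification, and fixed thresholds can be supplied
instead. The Costes significance test scrambles channel B in blocks
(default 4 px ≈ 3× the PSF σ_xy at the 80 nm pixel) within the mask and
reports the one-sided fraction of scrambles with r ≥ observed; with n
repetitions the p-value has Monte-Carlo resolution 1/n. Line profiles are
resampled at 1-pixel arc-length steps with a 3-pixel perpendicular average;
constant traces yield an undefined (NaN) correlation.

## Calcium analysis

ΔF images are the pixelwise mean of the first three stimulus frames minus
the mean of the five pre-stimulus frames, computed on the
background-subtracted series; the 3×3 unweighted smoothed copy exists for
display only. ROI traces use pixel-center membership in the 2 µm circle;
F₀ is the mean of the five baseline frames, and traces with F₀ ≤ 0 are
flagged invalid. ΔF_max/F₀ averages the three frames starting at the
within-stimulus argmax of ΔF/F₀ ("first three frames of peak signal at
stimulation onset"), falling back to the last three window frames when the
argmax sits too late for a full triplet — the phrase is ambiguous and this
resolution is recorded here. Blinding is enforced by the API:
`assign_roi_classes` accepts only the structural channel.

The paired comparison averages ΔF_max/F₀ per class within each cell and
applies a two-sided paired t-test across cells; each cell must contribute
both classes, and percent difference is mean(with/without − 1) × 100.

## Electrophysiology

Sweeps are stored baseline-subtracted (relative to holding), which makes
p/10 leak subtraction (test − 10 × averaged scaled pulses) exact for an
ohmic cell. Voltages are corrected offline by the liquid junction potential
(21.2 or 18 mV; the default protocol −65…+80 mV command maps to
−86.2…58.8 mV in 5 mV steps, 30 sweeps). IV points average the current
5–10 ms after step onset; the onset index is protocol-defined, with no
onset detection. The activation fit uses the Boltzmann-gated ohmic form —
standard for Ca_V IV relations; no functional form is prescribed by the
workflow this reimplements — with heuristic initialization from the peak
inward current and zero-crossing, and flags non-convergence instead of
returning values.

QC reads the exclusion thresholds on magnitudes with strict inequalities:
|leak| > 50 pA, R_s > 15 MΩ, |offset drift| > 5 mV, |I_peak| < 49 pA
(non-expressing cell), |peak density| > 60 pA/pF (suspect clamp). The last
two rules are printed with signs whose direction is ambiguous ("less than
−49 pA", "greater than −60 pA/pF"); the magnitude reading is our
resolution and the thresholds are module constants. Amplitude rules are
evaluated on leak-corrected currents when p/10 sweeps are available.

## Statistics

Normality requires *both* the Jarque-Bera and the Kolmogorov-Smirnov test
to pass at α = 0.05 in every group (the source workflow names the tests but
not the threshold or conjunction rule; requiring both is the conservative
choice). The KS statistic is computed against a normal with
sample-estimated mean/SD (Lilliefors statistic with the standard KS
p-value, which is conservative). Variance equality uses the two-sided
F-test for two groups and Bartlett's test — its k-group generalization —
for more. The parametric branch runs Student's/paired t or one-way ANOVA
with Tukey HSD; the rank branch runs Mann-Whitney-Wilcoxon (Wilcoxon
signed-rank when paired) or Kruskal-Wallis with Dunn's post hoc. Dunn z
statistics use pooled ranks with tie correction and Bonferroni adjustment
over all pairwise comparisons (the correction family is unnamed upstream;
Bonferroni is the strictest common choice and keeps the familywise error
of the post hoc at or below the nominal level regardless of the omnibus).
Identical samples short-circuit to p = 1. Descriptives report sample SD,
CV = SD/mean (only for positive means), and the 10/25/75/90 percentiles
matching the box-plot convention.

## Synthetic data

The generators define the test conditions; they are not tuned per test.

**Stacks.** An ellipsoidal cell (default semi-axes 4.5 × 4.5 × 3 µm in a
36 × 140 × 140 stack at 80/80/200 nm) with a membrane shell of voxels
within ±thickness/2 (default 0.24 µm total) of the analytic surface,
computed from a first-order signed distance — no meshing. Puncta are
axis-aligned ellipsoids rendered with 3× sub-voxel supersampling, so summed
intensity matches the analytic volume to well under 2%. Membrane anchoring
places the spot boundary a requested gap inside the shell's inner face
along the local surface normal. The PSF is an anisotropic Gaussian
(σ = 0.1/0.1/0.25 µm) — no PSF is documented for the source acquisitions;
these values approximate confocal conditions at the stated voxel size.
Noise is offset + gain·Poisson(signal/gain) + Normal(0, read σ), defaults
gain 2, read σ 2 — simple, unbiased in the mean, and sufficient for
recovery tests. Not simulated: optical sectioning physics, bleaching,
drift, STED PSFs.

**Time series.** Single-plane movies at 20 Hz with a 500 ms (10-frame)
stimulus. The transient is phenomenological: instantaneous rise at onset,
optional exponential decay within the stimulus (τ = ∞, i.e. a flat plateau,
by default) and exponential clearance (τ = 0.25 s) after offset. Indicator
binding kinetics are not modeled — on/off rates for the dye are not
available — so recovery tests validate the ΔF/F₀ arithmetic, not dye
biophysics.

**IV recordings.** Boltzmann-gated ohmic current plus linear leak
(reversal 0 mV) relative to holding, 20 ms steps sampled at 50 kHz with
5 ms pre/post baselines, Gaussian current noise, and p/10 leak pulses
(assumed too small to activate the conductance — valid for the far-negative
holding used). The channel is taken as closed at holding.

What passing tests show: the pipeline's operations are correct on data
satisfying these models at the stated acquisition geometry. What they do
not show: robustness to out-of-focus haze, clustered noise, segmentation
of touching puncta, or manual-curation equivalence on real images.

## Validation problem sizes

The acceptance computations use: 100 digitized spheres spanning
0.02–2 µm³ at 80/80/200 nm; sphericity closed forms at 20 nm isotropic
voxels (sphere r = 0.5 µm, cube side 1.4 µm — sizes chosen so edge voxels
are a small fraction); a 50-spot brute-force proximity instance; 100
simulated null cells × 100 Costes repetitions; 20 noisy movies per
amplitude in {0.1, 0.3, 0.5}·F₀; 200 paired-power replicates of 24 cells
(per-ROI ΔF_max/F₀ SD 0.1 at a 0.5 plateau, 5 ROIs per class — a realistic
regime for 2 µm ROIs at 20 Hz); a 5×5 (V_half, k) recovery grid; and 1000
replicates for each statistical calibration. These sizes are the package's
validation conditions and are fixed in `scripts/acceptance.py`.
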