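# Methods

## Volume model

Volumes are estimated by slice summation: each traced contour contributes
its enclosed area (shoelace formula on the implicitly closed vertex list,
mm² → cm²) times the slice thickness, `V = Σⱼ Aⱼ·tⱼ` with `tⱼ` in mm and
`V` in cm³. There is deliberately no end-cap, interpolation or
partial-volume correction: the estimator's coarse-thickness bias and
offset sensitivity are properties of the method under study. Mixed
thickness within a scan is supported by per-contour thickness overrides;
the stack-level thickness records the most common value (ties broken
toward the smaller).

Contours are ideal polygons: the boundary line width of a PACS freehand
tool is not modelled. They are implicitly closed; an explicitly repeated
first vertex is deduplicated on read, since freehand exports use both
conventions. Coordinates are slice-plane mm with no fixed patient origin —
areas depend only on relative positions. A zero-area (degenerate) contour
is a hard validation error rather than a silent zero-volume slice, so a
corrupt input fails observably instead of biasing a series.

Stack validation reports (rather than throws): duplicate z positions,
slice spacing that is not an integer multiple of the thickness (tolerance
1e-6 mm), zero-area contours, and a partial-coverage warning when the
first or last contour's area exceeds a configurable fraction (default
50%) of the maximum — an area profile that does not taper at the ends
suggests the organ was only partially imaged and the volume truncated.

## Precision statistics

The precision of a test–retest series is its coefficient of variation,
COV = SD/mean, using the sample SD (n−1). The denominator convention is a
choice — repeatability series here are short (5–20 scans), where the
unbiased-variance convention is standard. Cohort COVs aggregate per-patient
COVs unweighted: each patient contributes one value regardless of scan
count, so heavily scanned patients do not dominate.

Inter-observer agreement is the mean over paired scans of
|V₁ − V₂| / pair mean. The absolute value makes the statistic a positive
variability figure, symmetric in the observers and bounded by 2; a
`signed=True` flag exposes the directional version for bias assessment.

Paired organ series (e.g. left vs right gland) are compared with the
squared Pearson correlation of time-matched volumes, paired by scan order.
Low r² between two stable organs measured on the same scans indicates the
fluctuations are independent measurement noise rather than a shared
physiological or protocol signal.

The precision–size relationship is summarised by an OLS fit of COV on
volume. The functional form of such a trend is not identified by 13
points; a straight line in volume is the default, with `log-volume`
available, and only the sign and rough magnitude of the slope should be
interpreted.

## Minimal detectable change

Given a series of n measurements with mean m and SD s, the smallest true
fractional change detectable by a two-sided paired t-test at level α is

    δ = t₍₁₋α/2, n−1₎ · √2 · s / (√n · m).

The model: the post-change series is a second, independent series with the
same measurement SD, so paired differences have SD √2·s with n−1 degrees
of freedom. This is the reading of a "paired t-test on repeated
measurements" that makes the α = 0.01 / α = 0.05 threshold ratio equal the
t-quantile ratio t₍0.995,19₎/t₍0.975,19₎ = 1.367, matching the reference
ratio (17.8/13.0 = 1.369) to rounding. The √2 factor is switchable
(`independent_noise=False` gives the pure-shift alternative, differences
SD = s). For the reference series (m = 3.4, s = 0.64, n = 20) the closed
form gives 12.46% (α = 0.05) and 17.03% (α = 0.01), about half a
percentage point below the published 13.0%/17.8%; the arithmetic behind
the published figures is not stated, so this package documents the gap and
treats those figures as upper bounds rather than forcing agreement.

`significance_of_observed_change` inverts the same model
(t = δ·m·√n/(√2·s), two-sided), so threshold and p-value are mutual
inverses. The classification rule `classify_change` compares |observed
change| with the measurement COV; equality is conservatively classified as
within precision (no response call at exactly the precision limit).
The aging-drift helper scales a slow physiologic growth rate (default
0.03 cm³/year, the reported adult adrenal drift) by follow-up time and
volume, quantifying the main known violation of the stable-organ
assumption: ~0.6%/year for a 5.2 cm³ gland, negligible next to ~18%
measurement COV.

Known inconsistency in the reference values: a 3.4 cm³ sphere has diameter
18.7 mm by the closed form, while the 5.3% one-pixel error figure is
computed from a 12.8 mm diameter. The package reproduces each printed
number from its own stated inputs and does not reconcile them.

## Phantom simulator

The simulator emulates repeated CT measurement of a stable lesion:
sphere, ellipsoid, or bilobed (union of two ellipsoids, an adrenal-like
shape traced as one ROI; if a section is disconnected the dominant
component is traced). Cross-sections are sampled at the slice-centre plane
— the simplest model consistent with the area-times-thickness estimator;
sphere and ellipsoid sections are analytic, bilobed sections use exact
polygon union (shapely) on 256-gon ellipses, accurate well below 0.5% at
these sizes.

Noise model, three sources per scan:

1. **Slice alignment**: the slice grid's z offset is Uniform[0, t). For a
   3.4 cm³ sphere at t = 5 mm this contributes only ~2.3% volume COV.
2. **Boundary band (per scan)**: the traced surface is the true surface
   dilated/eroded by δ ~ Normal(0, σ_w), σ_w = `boundary_bias_sd_mm`.
   This models the session-level systematic over/under-inclusion of a
   blurred edge; its volume effect scales as ≈3δ/r, so it reproduces both
   the magnitude of hand-tracing variability and its inverse dependence
   on object size. Per-vertex jitter alone cannot do this: independent
   vertex errors average out of the enclosed area (relative area SD
   ≈ 2σ/√n_vertices), so no plausible per-vertex noise level yields the
   observed 15–24% series COV.
3. **Vertex jitter (per vertex)**: each radius is multiplied by (1 + ε),
   ε ~ Normal(0, `radial_noise_sd`), the residual waviness of a freehand
   trace (default 0.05).

Vertices are then snapped to the pixel grid (default 0.68 mm = 350 mm
field of view / 512 matrix; `None` disables). Contours are polar polygons
(`n_vertices` default 64, equally spaced angles), hence always simple
while radii stay positive; radii are floored at a small positive value.

**Calibration.** σ_w was fixed once from a 120-replicate sweep: at
σ_w = 0.55 mm (≈0.8 pixel — a sub-pixel, physically plausible band) a
3.4 cm³ sphere at t = 5 mm yields mean series COV 0.178, the adrenal-scale
reproducibility target, with the 1–16 cm³ range spanning ≈26% down to
≈10% median COV. The value is a fixed default, not a fitted parameter.

Reproducibility: every output is a pure function of the `PhantomSpec`,
including its seed. Per-scan RNG streams are spawned from the master seed
with NumPy seed sequences, so the first k scans are unchanged when
`n_scans` grows. Degenerate cases: an object thinner than one slice whose
extent misses every slice centre is traced at its mid-plane as a
single-slice stack with a warning; a trace that collapses below three
distinct pixels (sub-pixel sliver near a pole) is skipped as an empty
slice.

What the simulator does not model: pixel intensities or reconstruction
(no HU, no blur kernel), patient motion, contrast enhancement, observer
learning or fatigue, or non-star-shaped lesions. Passing simulation-based
tests therefore shows the analysis chain behaves correctly under a
realistic noise *structure* and calibrated magnitude — not that the noise
decomposition matches any particular scanner/observer pair.

## Problem sizes and numerical choices

The simulation-based checks use 200 replicate series per object size
(5 sizes, 10 scans per series) for the precision–size trend and 60–120
replicates for calibration-band checks; these sizes give median-COV
standard errors well below the effect sizes being asserted while keeping
the whole suite around ten seconds. Statistical routines come from scipy
(t quantiles/tails, Pearson correlation, OLS); polygon unions from
shapely; all other arithmetic is closed-form. Display rounding (volumes
and percents to 1 decimal, half away from zero) is applied only in the
report layer — every stored table keeps full precision alongside the
display columns.
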