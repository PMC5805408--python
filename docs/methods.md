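# Methods

## Scope and conventions

All analyses operate on maximum-intensity projections of the apical
surface, treated as locally flat: distances are Euclidean in the
projection plane, with no correction for the curvature of the follicle
surface. The image x axis is the anteroposterior (AP) axis and y is
mediolateral (ML) unless a pole pair defines the axis otherwise. Pixel
indices are 0-based; every reported area or length is calibrated (µm,
µm²). Bond and division-axis angles are *axial* (undirected): they are
folded into [0°, 90°] against the AP axis for intensity profiles, into
[0°, 180°) for rose diagrams, and doubled before any circular statistic.

## Synthetic pulsing epithelium

The generator (`synthgen.gen_pulsing_tissue`) emulates two-channel
time-lapse imaging of a pulsing cell sheet. Defaults are the acquisition
and biology the analysis is designed for: 40 frames at 15 s (10 min),
raised-cosine contraction episodes of 180 s separated by exponential
pauses (mean 60 s, because pulsing cells pause for variable times rather
than oscillating periodically), a fractional area amplitude decaying as
`A(d) = baseline + (A_pole − baseline)·exp(−d/λ)` with `A_pole = 0.4`,
`baseline = 0.1` and `λ = 30 µm` from the pole landmark, and a myosin
signal that anticipates the area response by 2 frames (30 s).

**Geometry.** Cells are cells of a power diagram (weighted Voronoi
tessellation) over Lloyd-regularized seed points with mild lognormal
size variation. Per frame, the weights are servoed until every cell's
rendered pixel area matches its prescribed target (tolerance 0.5% with a
3 px absolute floor), so the true label stack and the prescribed area
dynamics are mutually consistent. The pulses are kinematic: no forces or
vertex mechanics are simulated.

**Anisotropy.** An imposed ML/AP pulse-amplitude ratio ρ means the cell's
linear extents contract with log amplitudes in the ratio ρ. Expressing
this through per-cell anisotropic metrics fails in a confluent diagram —
a boundary splits the difference between the two adjacent cells' metrics,
so shear demands of neighbouring cells are zero-sum and the imposed
anisotropy is strongly attenuated (measured transfer ≈ 0.35). Instead,
each cell contributes a pure-shear displacement kernel
`u_i(x) = g·s_i(t)·K_i(x)·(x − c_i, −(y − c_i))` (Gaussian K_i, width
1.3× the cell radius; `s_i` the prescribed deviatoric log-strain), the
diagram is evaluated at `x − u(x)`, and the areas are re-servoed in warp
space. Junctions then move *with* the contracting cell, as attached
membranes do. The scalar gain `g` compensates kernel overlap and is
calibrated per movie, in up to four whole-movie passes, until the
realized anisotropy of the true label stack — judged by the same pooled
covariance statistic the downstream estimator uses — matches ρ within 3%.

**Rendering.** The membrane channel is an analytic junction profile: for
each pixel, the distance to the nearest cell-cell bisector follows from
the best and second-best assignment costs (cost difference over twice
the seed separation), and the signal is a Gaussian ridge (σ = 0.9 px) in
that distance plus a weak Lorentzian tail over a cytoplasmic background
of 0.1. The analytic profile keeps ridge height independent of bond
orientation (a binarized boundary plus blur renders diagonal bonds
dimmer than axis-aligned ones, which would fake planar polarity), and
the tail keeps cell interiors strictly decreasing away from junctions
(an exactly flat interior makes watershed flooding degenerate).
Bond-angle enrichment multiplies the ridge amplitude for boundaries
whose axial angle lies in the stated band. The myosin channel fills each
cell with `0.1 + gain·drive(t + lag)` and is blurred (σ = 1 px). Noise
is Poisson photon noise (200 photons at intensity 1) plus Gaussian read
noise (σ = 0.03), giving SNR ≈ 10 at the membrane — the regime the
segmentation defaults are tuned for.

**What the generator does not emulate.** Tissue rotation and drift,
surface curvature and tilted projection geometry, intensity bleaching,
cell divisions and rearrangements, and mechanical coupling between
pulses. Passing the closure tests therefore shows that the estimators
recover what they claim from data with the *statistical* structure of
the real recordings (amplitudes, gradients, lags, polarity, noise), not
that segmentation or tracking would survive a rotating or curved tissue.

## Segmentation and tracking

Marker-controlled watershed on the membrane channel: Gaussian blur
(σ = 1.5 px), regional minima deeper than h = 0.2 as markers, watershed
with one-pixel dividing lines; regions outside 4–400 µm² and
border-touching cells removed. The h threshold sits well below the
junctional ridge height (~0.8 after blur) and above intra-cell
modulation, so cells are neither merged nor split at default noise.
Tracking is greedy maximal-overlap assignment between consecutive
frames (IoU ≥ 0.3 to continue a track) — adequate at 15 s sampling where
displacement per frame is far below a cell diameter; no global
assignment, gap closing or division handling. Only tracks spanning every
frame enter pulse statistics, mirroring a fixed-length analysis window.

Bond extraction reports, per adjacent cell pair, the boundary pixels
shared by exactly those two cells; pixels where three or more cells meet
are excluded, and intensity is additionally sampled only on the central
50% of the bond's length. Without that vertex exclusion, blur mixes the
intensities of bonds that meet at a vertex and an imposed 2× angular
enrichment reads as ~1.7×. By default intensity is sampled on the bond
pixels themselves (the junctional ridge); a dilated sampling band is
available for misregistered real data but dilutes junctional signal
with cytoplasm.

## Pulse metrics

Pulse intensity is `(max − min)/mean` of the apical-area series, and the
per-follicle amplitude is its mean over at least 10 full-length tracks,
in percent. Pulse isotropy compares AP and ML bounding-box extents
between the frames of maximal and minimal area.

For *population-level* anisotropy the two-frame bounding-box ratio is
biased: bounding boxes are set by tricellular corners, and the jitter of
extremes at the argmax/argmin-area frames inflates both components
additively, which pulls their ratio toward 1 (an imposed ratio 2 reads
as ~1.3). `estimate_anisotropy_ratio` therefore regresses ln(RMS extent)
on ln(area) over whole trajectories — slopes 1/(1+ρ) along AP and
ρ/(1+ρ) along ML, pooled over cells — with the measurement noise in the
dependent variable, where it does not attenuate the slope ratio.

For amplitude *gradients*, `fractional_amplitude` ((max − min)/max,
after a 3-frame moving average) is preferred over pulse intensity: the
mean in the denominator of pulse intensity depends on the time spent
contracted, which varies with amplitude and distorts the spatial
profile, and unsmoothed extremes carry an upward noise bias that is
proportionally worse for weakly pulsing cells, flattening the gradient.

Cross-correlation pairs myosin(t) with area(t + τ) per cell after linear
detrending and z-scoring (raw mode available; detrending keeps slow
growth from masquerading as correlation), normalizes each lag by its
T − |τ| overlapping samples, averages the per-cell curves, and takes the
lag of the most negative mean correlation as the lead-lag — positive
when myosin precedes the area minimum.

## Shape statistics

Follicle axes come from the equivalent ellipse of the mask's second
central moments (axis length = 4·√eigenvalue). The elongation
coefficient is the OLS slope of long on short axis with an intercept
(through-origin mode available), over records below stage 8 by default.
Genotypes are compared by a separate-slopes ANCOVA
(`long ~ short × genotype`); pairwise slope contrasts are t tests on the
fitted coefficients with Bonferroni adjustment — chosen over Tukey for
consistency with the Bonferroni post-hocs used elsewhere in the
pipeline; a flag selects unadjusted p-values.

The eAR chord factor is √3/2: for an ellipse of semi-axes a, b the width
at 25% of the length is 2b·√(1 − 0.25) = √3·b, i.e. √3/2 of the full
width. (A chord can never exceed the full width, so factors above 1 are
geometrically impossible.) The implementation measures on rotated pixel
*coordinates* (no image resampling): length as the pixel-extent coverage
minus the mean grid dilation (0.4 px), width as the overlap-weighted
pixel count in a ±2.5 px band at the 25% station, corrected for the
ellipse profile curvature across the band using the semi-length
estimated from the same mask. On discrete ellipses with semi-minor axis
≥ 10 px and axis ratios in the follicle range (1–3) the recovered eAR is
within 2% of the true axis ratio at any orientation; at extreme ratios
(≥ 5) combined with b = 10 px the discretization error can reach ~3%.
Degenerate follicles should be excluded upstream; a solidity ≥ 0.9
filter stands in for the epithelial-gap exclusion done by staining in
real preparations.

Anterior/posterior eAR tables are compared with a mixed ANOVA (within:
pole, between: genotype) and one paired t test per genotype, Bonferroni
×2.

## Group comparisons

`compare_groups` routes through a D'Agostino-Pearson normality gate at
α = 0.05: both samples normal → unpaired Student t test (equal variances
by default, Welch by flag); otherwise a two-sided Mann-Whitney test.
The normality test requires n ≥ 8; smaller samples go directly to the
rank test.

## Gradients and profiles

`metric_vs_distance` bins a per-cell metric by Euclidean distance to the
pole in fixed-width bins from 0 (trailing partial bin kept only with
≥ 3 cells) and fits `baseline + A·exp(−d/λ)` to the bin means by
weighted least squares (weights from the bin standard errors with a
pooled floor). Recovery of λ within 15% needs the sampled distance range
to reach ~2λ and several bins within one decay length of the pole; the
validation suite uses pole-centred fields sized accordingly, with ~200
(λ = 15 µm) to ~1300 (λ = 60 µm) analyzable cells.

Line profiles resample the path to 1 px steps, average `width_px`
(default 15) nearest-pixel samples along the local perpendicular at each
station, and divide by the profile mean, so the result always has mean 1.
Cell volume is mean apical surface × mean height; heights are measured
inputs (from cross-sections), never inferred from the projections.

## Planar polarity

Bond profiles divide per-angle-bin mean intensity by the global mean
bond intensity, so the bond-count-weighted mean over bins is 1 by
construction. The elongation tensor uses the log-nematic convention:
per-cell magnitude ½·ln(major/minor) — the (r−1)/(r+1) alternative is
config-exposed — and the tissue tensor is the component-wise mean of
(m·cos 2θ, m·sin 2θ), so orthogonal populations cancel. Division
orientation uses the Rayleigh test on doubled angles; p above α means no
detectable bias.

## Numerical and validation choices

Synthetic study sizes were chosen so each closure test isolates one
estimator at realistic cell numbers: ~100-cell fields for lag, isotropy
and segmentation closures; 200-cell single frames (~400 bonds) for
polarity profiles; 200 replicate null cohorts for the ANCOVA type-I
rate. Gradient-recovery runs are noise-free — they certify the gradient
mapping and fit, while segmentation robustness to noise is certified
separately. All generators are seeded; identical specifications produce
bit-identical outputs. The whole validation suite runs in ~10 minutes on
one CPU.
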