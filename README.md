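# follipulse

Quantification of apical pulsatile contractions and follicle shape in
epithelial time-lapse microscopy.

During the early stages of *Drosophila* oogenesis the follicle (egg
chamber) elongates along its anterior-posterior (AP) axis while the cells
of the follicular epithelium undergo transient apical
contraction-relaxation pulses driven by medio-apical Myosin II. The
analyses needed to characterize this process — per-cell pulse metrics
from segmented movies, the myosin-area lead-lag, cohort-level shape
statistics, spatial gradients anchored on the polar cells, and junctional
planar-polarity profiles — are what this package implements, as a tested,
scriptable pipeline. A synthetic-data generator with full ground truth
(`follipulse.synthgen`) emulates the imaging data, so every estimator in
the package is validated end to end against known parameters.

## Core quantities

- **Pulse intensity** of a cell with apical-area series A(t):
  `(max A − min A) / mean A`. The per-follicle *mean percentage apical
  surface variation* is 100× the mean pulse intensity over ≥ 10 cells.
- **Pulse isotropy**: the AP (and ML) bounding-box extent at the frame of
  maximal area divided by the extent at the frame of minimal area; their
  ML/AP ratio is 1 for isotropic pulses.
- **Myosin-area cross-correlation**: per cell, corr[myosin(t), area(t+τ)]
  on detrended, z-scored series; the lag of the most negative population
  mean is the lead-lag (positive = myosin precedes the area minimum).
- **Elongation coefficient**: the OLS slope of follicle long axis on
  short axis across a previtellogenic cohort; 1 means no elongation.
  Cohorts are compared by ANCOVA (`long ~ short × genotype`) with
  Bonferroni-adjusted pairwise slope contrasts.
- **Extrapolated aspect ratio (eAR)**: the follicle width measured at 25%
  of its AP length from a pole is √3/2 of the full width for an ellipse;
  dividing by that chord factor extrapolates a per-pole width and hence a
  per-pole aspect ratio. Poles are compared by a two-way
  repeated-measures ANOVA with Bonferroni post-hocs.
- **Gradient mapping**: any per-cell metric binned by Euclidean distance
  from the polar-cell landmark, with an exponential fit
  `baseline + A·exp(−d/λ)`.
- **Planar polarity**: bond (junction) intensity by axial angle to the AP
  axis, relative to the mean bond intensity; rose diagrams in 10° bins;
  Rayleigh test on doubled angles for division-orientation bias; the
  tissue elongation tensor (magnitude ½·ln(axis ratio), nematic mean).

## Worked example

Simulate a 40-frame movie (15 s/frame) of a pulsing epithelium with a
2-frame myosin lead, then run the full pulse pipeline:

```sh
follipulse simulate --out sim --n-cells 60 --field-size 200 \
    --n-frames 40 --seed 7
follipulse segment  --out seg --stack sim/stack.tiff
follipulse track    --out trk --stack sim/stack.tiff --labels seg/labels.tiff
follipulse pulses   --out pul --tracks trk/tracks.csv
follipulse xcorr    --out xc  --tracks trk/tracks.csv
```

which prints

```
wrote sim/stack.tiff (40 frames)
wrote seg/labels.tiff
wrote trk/tracks.csv (36 tracks)
mean surface variation: 31.9% over 36 cells
lead lag: 2 frames (30 s), n = 36 cells
```

36 interior cells were segmented and tracked over all 40 frames; their
apical surfaces varied by 31.9% on average (the generator imposes a
pulse-amplitude gradient decaying from 40% at the pole), and the myosin
signal leads the apical-area minimum by 2 frames (30 s) — exactly the
lag the simulation imposed. Every stage writes CSV/JSON outputs with a
`provenance.json` echoing the effective configuration.

The same operations are available as a library:

```python
from follipulse.synthgen import TissueSpec, gen_pulsing_tissue
from follipulse import segtrack, pulsedyn

stack, truth = gen_pulsing_tissue(TissueSpec(seed=7))
masks = segtrack.segment_stack(stack)
tracks = segtrack.table_to_tracks(
    segtrack.measure_tracks(segtrack.track_cells(masks), stack),
    full_length_only=True,
)
result = pulsedyn.cross_correlate(tracks, max_lag_frames=8)
print(result.lead_lag_frames)
```

## Layout

| module      | contents |
|-------------|----------|
| `synthgen`  | synthetic cohorts, pulsing-tissue movies with ground truth, ellipse fixtures |
| `segtrack`  | watershed segmentation, overlap tracking, per-cell measurement, bond extraction |
| `pulsedyn`  | pulse intensity/isotropy, cross-correlation, normality-gated group tests |
| `follshape` | follicle axes, elongation coefficient, ANCOVA, eAR, pole comparison |
| `spatialmap`| metric-vs-distance gradients, line profiles, AP-line counts, heat maps |
| `planarpol` | bond-angle profiles, rose diagrams, Rayleigh test, elongation tensor |
| `cli`       | the `follipulse` command-line pipeline |

See `docs/methods.md` for the models, conventions and numerical choices.
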