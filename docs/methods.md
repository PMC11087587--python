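# Methods

This note records the models behind each pipeline stage, the parameter
choices that matter, the numerical decisions taken where the design was
genuinely open, and what the synthetic data do and do not establish.

## Synthetic B-scans

The generator emulates the statistical structure of endoscopic OCT
images of soft tissue rather than simulating wave propagation.

**Forward model.** Column c of the tissue region is

```
I(z, c) = i0 · exp(−μ_c z) · s(z, c) · h(z) + n_f · i0 · (1 + 0.1 ε)
```

with z the depth in mm below the tissue surface (geometric depth by
default; an optional refractive factor converts to optical depth),
`s` a unit-mean multiplicative speckle field, `h` an optional axial
sensitivity (PSF) profile, `n_f` the noise-floor fraction and ε
standard normal. A saturated interface band (default 3 rows at twice
the surface intensity) sits above the tissue, optionally separated by
floor-level gap rows, so ROI extraction has something to find.

**Speckle field.** A complex circular Gaussian white field is low-pass
filtered with a separable Gaussian kernel and its squared magnitude
taken. Grain sizes are specified as the half-width at half maximum of
the intensity autocorrelation in µm (a Gaussian filter of width σ on
the complex field yields an intensity autocorrelation of width σ); a
one-pixel grain means no filtering and recovers fully developed
speckle (exponential intensity, contrast 1). Because filtering leaves
single-pixel intensity statistics exponential but changes the spatial
sample variance, the realized fluctuation is standardized to unit
variance and scaled by the requested contrast before blending with the
constant field 1; negative excursions are clipped at zero and the
field renormalized to unit mean. The empirical std/mean therefore
tracks the contrast parameter to within a few percent.

**Lateral attenuation heterogeneity.** μ_c is the class mean plus
Gaussian-smoothed white noise with correlation length 150 µm — the
typical calibre of a brain vessel, which is what drives attenuation
heterogeneity in tissue — mean-centered and rescaled to the requested
standard deviation, clipped away from zero.

**Cohorts.** Classes hold ≥ 2 patients with ≥ 1 scan each. Per-patient
log-normal jitter (default 5% relative) on attenuation, contrast and
grain makes same-patient scans correlate more than cross-patient
scans; setting it to zero yields exchangeable scans for null
experiments. Seeds are expanded with `SeedSequence(seed, spawn_key=
(class, patient))`, so cohorts are bit-reproducible and insensitive
to generation order.

**Defaults.** 400×256 px covering 1.96 mm × 1 mm (4.9 µm lateral,
~3.9 µm axial pitch, in air), μ = 4 /mm, lateral μ spread 0.5 /mm,
grain 20 µm lateral / 24 µm axial (the system resolution), contrast
0.5, noise floor 1% of surface intensity. Brain-relevant attenuation
spans roughly 1–10 /mm, with white matter at the high end and glioma
low.

**Not emulated:** multiple scattering, focus/roll-off decay (the
emulated time-domain system has none), refraction at the interface,
probe motion, and any claim about the actual speckle statistics of
specific brain tissue types — the per-class parameters are plausible
settings, not measurements. Passing tests therefore demonstrate the
correctness and statistical behaviour of the pipeline, not clinical
performance.

## Preprocessing

Order: divide each row by h(z) (when a PSF calibration is supplied);
normalize by the mean of the probe/glass interface band so the band
mean is exactly 1; locate the tissue–glass interface per column; shift
columns so the surface sits at row 0; crop to the shallowest common
depth and remove 15 px from each lateral edge (the system's distorted
margins; configurable).

The interface detector takes, per column, the first row below the
probe band reaching half the column's maximum, then smooths the row
indices with a 5-column median. Dark surface speckle can still throw
isolated columns tens of rows too deep, which would destroy the
common-depth crop, so detections farther than 10 rows from the
cross-column median are clamped to it. On speckle-free fixtures the
detector is exact; under speckle, residual per-column jitter of a few
rows remains and slightly conditions the surface row on bright
speckle — a small, documented source of bias in downstream fits.

Cross-correlation screening computes the zero-lag Pearson coefficient
between all same-class image pairs (images cropped to their common
shape) and reports within-patient vs cross-patient maxima and means.
The cohort is flagged when the within-patient maximum exceeds 0.9 (an
absolute cap) or the cross-patient maximum by more than a margin
(default 0.05).

## Attenuation estimation

Each column is modelled as exponential decay down to a boundary
`z_noise` where the signal meets the noise floor and becomes flat. For
every admissible boundary b (≥ 5 valid points per segment) the decay is
fitted by least squares on ln I vs z over [0, b), the noise line is
pinned to the decay fit at the boundary, and the objective

```
SSE_decay[0,b) / N_decay + SSE_noise[b,end] / N_noise
```

is minimized over b, ties toward larger b. Three numerical decisions
matter, each adopted after the naive variant failed on speckled data:

1. **Residual domain.** Residuals are evaluated on the log-scale
   A-scan (the decay and noise levels are the sloped and horizontal
   lines of the log profile). In the linear domain, multiplicative
   speckle lets short, spuriously steep segments win the argmin and
   biased image-mean μ by a factor of ~2. A linear-domain objective
   remains available (`domain="linear"`).
2. **Flat-tail admissibility.** A candidate boundary qualifies only if
   the measured log-slope of its tail implies ≤ 0.5 nat of total drop —
   a noise region is flat. When no tail is flat the column is treated
   as pure decay and the maximal decay segment is fitted. Without this
   rule, on columns whose signal never reaches the floor (low μ),
   single dark speckle grains formed perfect 5-point "decays" in up to
   a quarter of columns.
3. **Knee trim.** An additive floor bends the log A-scan smoothly well
   before the boundary, dragging the fitted slope down by 6–16%. After
   boundary selection the decay is refitted on the rows where the
   fitted line sits ≥ 5× above the noise level, provided those rows
   still span ≥ 1.5 nats of predicted decay (otherwise the "noise
   level" is actually signal and the refit would chase noise). The
   reported boundary and objective are always those of the argmin.

Residual accuracy under the stated conditions: noiseless exponentials
are recovered to < 1e-6 relative; with 10% multiplicative noise and a
1% floor the mean absolute error over μ ∈ [1, 10] /mm is ≈ 4.5%; under
contrast-0.5 speckle, image-mean μ is within ≈ 5% at the defaults and
within 10% across the 2–8 /mm range, preserving class rank order. A
small negative bias from the additive floor is inherent to fitting an
abrupt two-segment model to a smooth knee.

σ_μ uses a centered sliding window (truncated at the edges) of
N_A = ⌊150 µm / lateral pitch⌋ columns — 30 at the native pitch — with
population (1/N) normalization. Whether the windows should slide or
tile is not determined by the method definition; sliding makes σ_μ a
translation-covariant local statistic and uses every column. Failed
columns are excluded from both image means, never imputed.

## Speckle features

The ROI (linear normalized intensity by default; a log-intensity
switch exists) is decomposed with `pywt.dwt2` cascades using *bior3.5*
and symmetric boundary extension — a biorthogonal basis avoids edge
distortion, and levels 1–2 carry the speckle-scale texture while
higher levels mostly reflect noise and are excluded. P_a sums the
squared detail coefficients of the three subbands and divides by the
detail-array pixel count at that level, making P_a a per-coefficient
mean power comparable across levels (the alternative, dividing by the
original image size, only rescales each level by a constant). σ_Pa is
the population standard deviation of the per-column mean power around
P_a; the mean of the lateral profile equals P_a identically, which the
tests assert. All features are invariant to DC shifts (the wavelet
annihilates constants) and scale quadratically with intensity.

## Classification

Fisher LDA in closed form: `w` solves `S_W w = m₂ − m₁` with the
within-class scatter summed from per-sample outer products; if the
solve fails, ridge multiples of `1e-8·trace(S_W)/d` are escalated
tenfold until it succeeds. `w` is normalized and oriented so the
positive class projects higher. The decision threshold maximizes
Se + Sp over midpoints between consecutive sorted unique projections
(plus one candidate beyond each extreme); ties resolve toward the
candidate nearest the midpoint of the class medians, which keeps null
thresholds central instead of drifting into a tail.

Cross-validation partitions patients, never scans. `k = "max"` uses
the patient count of the smaller class (leave-one-patient-out with
respect to the limiting class); patients are assigned to folds
round-robin in sorted order, deterministically. Folds whose training
split lacks two samples of either class are skipped with a warning.
Se/Sp/Pr are averaged as unweighted fold means. ROC and AUC are
computed on pooled held-out projections, each fold centered at its own
decision threshold — fold-specific discriminants have incommensurable
offsets, and raw pooling produced AUC 0.69 on a perfectly separated
cohort. AUC uses the trapezoidal rule and equals the normalized
Mann–Whitney statistic with half-credit for ties.

The default evaluation grid is the 15 combinations of
{μ, σ_μ, P₁, σ_P1, P₂, σ_P2}: each of μ, P₁, P₂ alone and with its
dispersion, the attenuation–speckle mixtures [μ,P₁], [μ,P₂],
[μ,σ_μ,P₁], [μ,σ_μ,P₂], [μ,P₁,P₂], [μ,σ_μ,P₁,σ_P1], [μ,σ_μ,P₂,σ_P2],
and the speckle-only sets [P₁,P₂] and [P₁,σ_P1,P₂,σ_P2]. Which class
of a pair plays the positive role is configurable and recorded in the
output; by default the lexicographically later label is positive.

## Pipeline and reproducibility

A YAML config fully determines a run; its SHA-256 hash is embedded in
every output table header. The global seed expands into per-scan child
seeds via `SeedSequence` spawn keys, so stage reruns and full reruns
with the same config are bit-identical; after simulation, scans are
re-read from the written 16-bit TIFFs so fresh and resumed runs see
identical (quantized) intensities. Stages resume from existing
outputs. CSV tables carry a units row under the header.

Problem sizes in the test suite and acceptance script (200–400 lateral
× 128–256 axial px, 2 classes × 3–4 patients × 3–4 scans, 12–20
Monte-Carlo seeds) were chosen so each statistical check has enough
replication for its stated tolerance while the full suite runs in a
few minutes.

## Known limitations

* Per-A-scan μ estimates are noisy under realistic speckle (lateral σ
  of order 1 /mm); only image-level means are quantitatively reliable.
* The additive noise floor leaves a few-percent negative bias in μ
  even after the knee trim; floor subtraction would remove it for
  additive floors but corrupts abrupt-transition signals, so it is not
  used.
* The interface detector assumes a bright, roughly level tissue
  surface; strongly tilted samples exceed the 10-row clamp and would
  need a larger `max_offset`.
* Speckle features depend on the intensity normalization; images must
  be interface-normalized before comparison across scans.
* With few patients per class, grouped CV metrics are coarse-grained
  (multiples of 1/scans-per-fold) and their fold means have high
  variance; the null-cohort tests quantify exactly this.
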