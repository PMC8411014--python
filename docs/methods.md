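# Methods

This note documents the models, numerical choices and known limitations
of `tmeprog`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Stroma-fraction pipeline

The pipeline assumes bright-field H&E imaging obeying Beer–Lambert
absorption: a pixel's RGB intensity is `I = I0 · exp(−(c_h·v_h + c_e·v_e))`
with unit optical-density (OD) stain vectors `v_h` (hematoxylin) and
`v_e` (eosin) and non-negative concentrations. All OD computations use
natural logarithms with `I0 = 255` and intensities floored at 1.

**White balance.** The named method is an iterative grey-point scheme in
YUV (BT.601: Y = 0.299R + 0.587G + 0.114B, U = 0.492(B−Y),
V = 0.877(R−Y)). Its grey-point extraction constants are not published,
so the package's own rule is: candidates are pixels with
(|U|+|V|)/Y ≤ 0.15, luma at least 0.7× the tile's 95th luma percentile,
and not fully saturated (all channels ≥ 254). Each iteration rescales the
R and B gains so candidate means match the candidate luma; convergence at
mean |U|,|V| ≤ 0.5, at most 16 iterations. The luma gate is relative
rather than absolute so that uniformly dark-but-neutral tiles are left
untouched; a fixed gate admits chromatic tissue (e.g. hematoxylin nuclei,
whose chroma ratio is ≈ 0.2) whenever a tile lacks bright glass, which in
development destroyed tiles rather than balancing them. All constants are
in `StromaConfig`. When no candidates exist the tile is returned
unchanged with a warning flag.

**Reference white.** All channels are multiplied by 240 / p95, where p95
is the 95th percentile of the grey conversion (weights 0.3/0.6/0.1);
results are clipped to [0, 255]. A black tile (p95 = 0) is an error.

**Stain estimation.** Macenko-style: pixels with OD vector norm > 0.15
are projected onto the top-2 right-singular-vector plane; the directions
at the 1st and 99th angular percentiles are the stain vectors, clamped
non-negative and normalized. The norm-based tissue rule matters: a
per-channel OD floor would discard pure eosin, whose red/blue OD
components are small. Hematoxylin is identified as the vector with the
larger blue-OD component (0.29 vs 0.11 for the reference vectors). Tiles
with < 500 tissue pixels, a collapsed second singular value, or < 2° of
angular spread fall back to published reference H&E vectors, flagged.

**Deconvolution and masks.** Concentrations are the least-squares
projection of per-pixel OD on the stain basis, clamped at zero, and
re-rendered via Beer–Lambert into a hematoxylin image and a combined H&E
image. Foreground: 7×7 per-channel mean filter (reflect padding), HSV
conversion with S, V on [0, 1], mask = V ≥ 0.2 ∧ S ≥ 0.4 (inclusive).
Stroma mask: grey conversion → 9×9 median filter → 17×17 sample-SD
filter (n−1 denominator) of the median image; both intermediates are
stretched so their 1st/99th percentiles map to 0/255 (clipped); the two
are averaged with the SD component inverted; Otsu's threshold (exhaustive
over 256 integer levels, ties to the lower level) is scaled by 1.15 and
applied; 8-connected components with < 200 pixels are removed (a 200-px
component is retained); 5×5 morphological closing finishes.

*Polarity.* Which Otsu class is stroma, and whether the SD image is
inverted, are genuinely open choices. The package takes stroma as the
class that is bright in the hematoxylin image (hematoxylin-poor) and
smooth in texture (inverted SD), validated against synthetic ground
truth: epithelium is nucleus-dense, hence dark under the median and
SD-rich. The "background mask" combined by logical AND is interpreted as
the tissue-foreground mask.

All filters use reflect padding; percentiles are linear-interpolation
percentiles of the pixel population. These conventions are fixed for
bit-reproducibility.

**Calibration.** `corrected = (raw − cf1)/cf2`, never clamped
(out-of-range values are flagged). The Aperio AT2 constants (0.037,
0.9852) are defaults; `estimate_calibration` performs the defining OLS of
raw fractions on reference fractions over paired scans (≥ 3 pairs,
non-constant predictor). For the synthetic renderer the analogous pair is
estimated at run time against ground truth on a disjoint seed stream
(`pipeline.estimate_renderer_calibration`); development measurements put
the renderer slope near 0.9 — boundary pixels are eroded from the stroma
class by the 1.15-scaled threshold under the 17-px SD window, an affine
effect the calibration absorbs.

## CD8⁺ core quantification

Nuclei are detected by a circular Hough transform over integer radii
(default 4–12 px) on a Canny edge map (σ = 1), with per-radius
normalized accumulators, an absolute peak threshold (`sensitivity`,
default 0.45) and non-maximum suppression at the minimum radius.
Classification uses the median HSV inside the detected disk: hue in
[10°, 50°] is DAB-brown positive, [180°, 280°] is hematoxylin-blue
negative, each requiring S ≥ 0.15 and V in [0.15, 0.95]; nuclei matching
neither range are discarded entirely (not counted as negative), since the
protocol counts positive vs negative nuclei only. The published HSV
ranges and Hough parameterization are proprietary; these defaults were
tuned once on the packaged synthetic fixtures and live in `IhcConfig`.
A core passes QC iff it has ≥ 1000 counted cells; patient values average
QC-passing cores, and patients with none are flagged missing.

## Cutpoint search

Admissible thresholds for each marker are the multiples of the step
(0.001 for CD8, 0.01 for stroma) between the observed extremes that keep
at least 5 patients on each side of the dichotomy (v ≤ t vs v > t). Each
pair classifies patients into the ordinal marker (boundaries adverse:
CD8 ≤ t is low, stroma ≥ t is high) and is scored by Harrell's C-index
against TTR. Because a single ordinal covariate's Cox risk ordering
equals the level ordering whenever the fitted coefficient is positive,
the C-index is computed directly on levels — identical result, ~10⁴×
cheaper over thousands of combinations — and the Cox sign is checked
once on the selected pair (a negative sign would flag a reversed
ordering). Tie conventions: a usable pair has the shorter time carrying
an event (or equal times with exactly one event, the event being the
failer); tied risks score 0.5; no usable pairs yields C = 0.5, which also
covers combinations where the marker collapses to one level. C-index
ties in the argmax break toward the smaller CD8 threshold, then the
smaller stroma threshold, for determinism.

## Survival analysis

Endpoints: TTR events are local/regional recurrence, distant recurrence
and death from the index cancer; deaths from other cancers, non-cancer
deaths, treatment-related deaths and loss to follow-up censor. OS events
are deaths from any cause. Estimation is delegated to lifelines:
Kaplan–Meier with Greenwood variance and log-log (exponential-Greenwood)
95% CIs; Mantel–Cox log-rank (χ², df = groups − 1; statistic 0 and p = 1
when no events exist); Cox proportional hazards with Efron tie handling
and two-sided Wald tests, listwise deletion with reported counts,
zero-variance covariates rejected by name. Five-year survival is read
from the step function at t = 5 (right-continuous).

Risk strata: LOW_RISK = stage II, or stage III pT1–3 pN1 without
lymphatic or venous invasion; HIGH_RISK = stage III with pT4, pN2, or
pT3 pN1 with either invasion. Stage III pT1–2 pN1 *with* invasion falls
outside both published definitions and is UNCLASSIFIED: counted, logged
and excluded from stratified reports. The stratified report mirrors the
published analysis: stroma dichotomy in the low-risk stratum, the
three-level marker in the high-risk stratum, each with group sizes,
5-year survival and CIs, the log-rank test and the extreme-group hazard
ratio.

## Synthetic data

**H&E tiles.** Geometry: white lumina (disks, ~8% of the frame by
default) are carved first — annotated tumor regions contain glass/lumen
in reality, and without near-white pixels the 95th-percentile→240
rescale clips tissue and the foreground mask is vacuous. Epithelial
islands come from thresholding a Gaussian-smoothed random field at the
quantile giving the target stroma share among tissue pixels, so the
realized fraction essentially equals the target. Rendering: stroma is
eosin-rich (c_e ≈ 0.75) and nearly hematoxylin-free with sparse nuclei
(0.3 / 1000 px²); epithelium mixes both stains with dense near-pure
hematoxylin nuclei (20 / 1000 px², radii 3.5–5.5 px) so that a 9×9
median sees a majority-nucleus neighborhood, as in densely cellular
colonic epithelium; lumina carry a faint neutral absorbance (so they are
achromatic, like glass). Gaussian pixel noise (default sd 4) is added
before 8-bit quantization. Ground truth is returned as a three-level
mask (0 lumen, 128 epithelium, 255 stroma).

What the renderer does *not* emulate: out-of-focus blur, scanner
chromatic aberration, stain diffusion gradients, overlapping/touching
nuclei, mucin, necrosis, red cells. Passing recovery tests therefore
demonstrates correctness of the implemented operations under the stated
optical model, not robustness to all real-slide artifacts.

**IHC cores.** Brown/blue anti-aliased disks on a pale background, on a
jittered grid when overlap is disallowed (guaranteeing separation, with
an explicit error when the canvas cannot hold the requested count) or
uniformly at random otherwise. Exact centers, radii and labels are the
ground truth.

**Cohorts.** CD8 fractions are lognormal with median 0.027 and log-sd 1
(≈ 50% of patients at or below the published cutpoint, matching the
reported marginals); stroma fractions are Beta(4, 6) (≈ 15% at or above
0.56). The latent class from the true cutpoints sets an exponential
event hazard — default pattern 1 : 1.75 : 2.86, anchored at 0.0893 /yr
(≈ 64% five-year event-free survival in the favorable group, the
published high-risk favorable figure). Censoring is independent
exponential (0.03 /yr) truncated at 7 years of follow-up. Staging
covariates follow the reported mixes with stage II ⇒ pN0 and stage III ⇒
pN ∈ {1, 2}; covariates are independent of the marker class, so stratum-
conditional hazard contrasts equal the marginal ones. Outcome codes are
assigned consistently with the event/censoring type (recurrence-type
codes for events; administrative "none" at end of follow-up; a mix of
loss and non-index deaths for early censoring). A limitation: follow-up
stops at the TTR event, so OS analyses on simulated data treat
recurrences as censorings rather than observing subsequent death.

## Problem sizes and identifiability

Default problem sizes — 384² tiles (512² for the reference fixture),
20-tile recovery sets, 200-nucleus cores (1000 for QC boundary checks),
n = 600 cohorts, 200 Cox replicates at n = 2000, 1000 log-rank null
replicates — were chosen so the whole suite exercises every stage at
statistically meaningful scale on a single CPU.

A finding the test suite makes explicit: with trial-realistic marginals,
the CD8 cutpoint is sharply identified by the C-index search (its
dichotomy is ~50/50, and recovery lands within a few thousandths across
seeds), while the stroma cutpoint is weakly identified (its dichotomy is
~85/15, the C-index surface is nearly flat in that direction, and the
argmax can wander several grid steps on any single n=600 cohort). This
mirrors the motivation for validating selected cutpoints in an
independent cohort rather than trusting a single training-set argmax.

## Other numerical conventions

- One integer seed per generator spec; all sub-draws derive from it via
  `numpy.random.default_rng`; fixed seed ⇒ byte-identical outputs.
- Otsu operates on values rounded to integer 8-bit levels; constant
  grids are errors (or degenerate-flagged where the protocol continues).
- The percentile stretch maps exactly the 1st percentile to 0; a
  constant grid returns all zeros with a degenerate flag.
- Corrected fractions outside [0, 1] are flagged, never clamped.
- HSV convention throughout: H ∈ [0°, 360°), S, V ∈ [0, 1].
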