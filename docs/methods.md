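# Methods

## Pattern model

A nucleus's 53BP1 immunofluorescence is summarized by three measurements:
its set of discrete foci (each with a physical diameter in µm), and two
diffuse-staining metrics, *coverage* (fraction of nuclear pixels at or
above a focus-level intensity threshold) and *heterogeneity* (coefficient
of variation of nuclear intensity). Classification applies the five-type
rule with fixed precedence **diffuse > large focus > focus counts**:

1. `diffuse` if coverage ≥ 0.4 **and** heterogeneity ≥ 0.3;
2. else `largeFocus` if any focus diameter ≥ 1.0 µm;
3. else `highDDR` (≥ 3 foci), `lowDDR` (1–2), `stable` (0).

The precedence is a design choice: the type definitions do not say how to
score a nucleus satisfying several of them, and ordering the rarer,
higher-grade phenotypes first keeps the abnormal grouping monotone —
adding a focus can never move a nucleus from abnormal to normal (a property
test enforces this). The numeric diffuse thresholds are free parameters of
`ClassifierParams`; "intense and heterogeneous" has no published numeric
definition. The case statistic is the **abnormal fraction**: the percentage
of nuclei classified `highDDR`, `largeFocus` or `diffuse`.

## Segmentation and focus measurement

Nuclei: Otsu threshold on DAPI → hole filling → distance-transform
watershed (marker minimum distance 2 µm) → removal of regions under
15 µm² or touching the field border (partial nuclei bias focus counts).
Labels are assigned in bounding-box order so output is deterministic.

Foci: per nucleus, the 53BP1 channel is normalized by its local dynamic
range (background = 25th percentile; low percentiles are used so that
bright foci and their Gaussian skirts cannot inflate the background
estimate even when foci cover much of the nucleus). Candidates come from
multiscale Laplacian-of-Gaussian detection over diameters 0.2–3.0 µm with
skimage's cross-scale pruning disabled — that pruning replaces a cluster of
resolved foci with one coarse blob, exactly the failure mode a focus
counter cannot afford. Candidates are kept if their peak exceeds both
0.2 × the local dynamic range and a noise floor of 6 robust SDs (estimated
from the 5th–25th percentile spread), then deduplicated with **fine-scale
precedence**: detections with implied FWHM < 1 µm are merged among
themselves (merge radius = larger blob radius, strongest peak kept), and
coarse detections are admitted only where no kept detection already
explains the signal. Focus *size* is the half-maximum diameter from a
16-ray radial profile around the peak, with sub-pixel interpolation of the
half-maximum crossing and the median taken over rays; the median makes the
measure robust to a neighbouring focus bridging the half-maximum level,
which would inflate a connected-component area. For an isolated Gaussian
spot this equals the FWHM, and for rendered spots it recovers the true
diameter within ~10%.

Physical coordinates use the pixel-center convention (µm = index × pixel
size). Intensity scaling leaves all detections unchanged (thresholds are
relative), and whole-pixel translations shift them exactly — both are
property-tested.

## Region gating

With FDC and BCL2 channels present, per-nucleus mean intensities are
thresholded (configurable; default midpoint of the observed range) and
combined: GC = FDC+/BCL2−, PF = FDC+/BCL2+, MM = FDC−/BCL2+ within 30 µm
of a GC nucleus (the "surrounding" ring is geometric but unquantified in
the source; 30 µm is a few lymphocyte diameters), LA = FDC− otherwise.
Missing channels leave nuclei unassigned with a warning rather than
failing the run.

## FISH genotyping

Signals are detected per color channel with the same LoG detector. Within
a nucleus, green–orange pairs with centroid distance ≤ 0.6 µm (about one
signal diameter; "fusion signal" is not quantified in the source) are
matched greedily in increasing distance order, each signal used once; a
brute-force maximum-matching oracle backs this in tests for small nuclei.
Genotype per nucleus: `uninformative` (no signal), `fusion` (1–2 pairs),
`trisomy18q21` (3 orange + 2 green, no pair), `wild` (≤ 2 of each color —
a single signal of a color is allowed, since sectioning truncates nuclei),
`other` otherwise. A slide needs more than 150 informative nuclei to be
scored (else `NS`); case calls use fractions over informative nuclei with
a 10% positivity threshold, matching the convention that sub-threshold
trisomy (< 10%) is flagged as equivocal rather than called.

## Diagnostic statistics

*ROC/AUC.* For a scalar score the ROC of a fitted logistic model equals
the empirical ROC of the score, so the AUC is computed directly via the
Mann–Whitney U relation with ties counted ½; the 95% CI uses DeLong's
placement-variance estimator, clipped to [0, 1]. The operating point
maximizes Youden's J over observed thresholds (predict positive at score ≥
threshold), ties broken toward the lowest threshold (higher sensitivity).

*Exact Wilcoxon rank-sum.* Mid-ranks for ties; the two-sided p-value is
P(|S − E[S]| ≥ |s_obs − E[S]|) under the permutation null. The exact
distribution is built by dynamic programming over doubled (integer)
mid-ranks, equivalent to enumerating all C(n, n₁) assignments, and is used
up to n = 30; beyond that a tie-corrected normal approximation with
continuity correction is used and flagged. Tie handling can shift the
third decimal of p relative to other conventions; the packaged MALT table
yields p = 0.0145 under this one.

*MALT association.* Cases split at the small-cell cutoff (33.6% abnormal,
compared as ≥). The association test contrasts abnormal fractions between
t(11;18)-positive and t(11;18)-negative cases with no-signal (NS) cases
excluded — the grouping that reproduces the published p — while the
descriptive cross-tab counts the sub-threshold-trisomy case as
aberration-positive. The therapy summary excludes cases with no data (ND)
or still under therapy (DT). The decision rules (`diagnose_lesion`)
compare the abnormal fraction against the published cutoffs — 27.2%
(follicular), 33.6% (small cell), 22.9% (large cell) — and route MALT
cases through the FISH call: translocation ⇒ "high-risk" (eradication-
resistant), else "low-risk"; every comparison is recorded in a trace.

## Synthetic data

The generator reproduces the cohort's statistical structure, not its
optics. Per lesion class, the per-case abnormal fraction follows a scaled
Beta distribution fitted so that its quartiles equal the published
(median, IQR) exactly: a two-parameter Beta on [0, 100] cannot represent
the more skewed summaries, so one support endpoint is freed on the
long-tail side, giving three unknowns for the three quantile equations
(solved to machine precision; support stays inside [0, 100]). A zero-width
summary degenerates to a point mass. Within a case, nuclei are abnormal
with probability equal to the case fraction, split (0.6, 0.3, 0.1) over
(highDDR, largeFocus, diffuse) and (0.7, 0.3) over (stable, lowDDR) —
the source reports only pooled abnormal fractions, so the mixes are
configurable defaults. Focus inventories follow the class definitions:
small foci 0.35–0.8 µm, large foci 1.15–1.8 µm.

Rendering: 0.1 µm/pixel (high-magnification oil immersion; the exact scale
is unstated in the source), lymphocyte-sized nuclei (2.5–3.5 µm radius) as
filled ellipses in DAPI, placed by rejection sampling with no overlap and
a ≥ 2 px gap; foci as isotropic Gaussian spots with FWHM equal to the true
diameter, centers ≥ (d/2 + 0.65) µm apart so that rendered foci are
optically resolvable; diffuse nuclei get a smoothed-noise texture covering
55–85% of the nuclear area at focus-level intensity. All channels receive
Poisson shot noise plus Gaussian read noise (default SD 5 against focus
amplitude 150). Z-stacks are not simulated — the analysis operates on
projected 2-D images, and `project_zstack` (max projection) covers stacks
at read time. FISH fields place 2+2 (wild), one colocalized pair + 1+1
(fusion), or 2+3 (trisomy) signals with singletons ≥ 1.3 µm apart.

What this does *not* emulate: optical sectioning and out-of-focus light,
photobleaching, tissue autofluorescence, nuclear crowding/overlap, real
follicle geometry, and segmentation-hostile morphology. Passing recovery
tests therefore demonstrates that the measurement chain is correct and
unbiased under the model's assumptions, not that it would reach the same
accuracy on tissue sections.

Per-case scoring in tests and in the acceptance script uses 300 nuclei per
IF case (rendered as six 1024² fields of 50) and 200 nuclei per FISH
slide — enough for the abnormal fraction's binomial error to sit well
inside the ±3-point recovery tolerance. The per-nucleus count for the
original study is unpublished; 300 is this package's default
(`simulate if --n-nuclei`).

## Numerical notes and limitations

- Beta fitting uses bounded least squares from four starting points; an
  infeasible summary (residual > 0.5 points) raises rather than silently
  approximating.
- Youden ties break toward the lowest cutoff; published cutoffs are
  compared with ≥ (no boundary case occurs in the packaged table).
- The DeLong CI is a package choice; the source states only "logistic
  regression model", and CI reproduction is not asserted anywhere.
- Greedy fusion pairing is not globally optimal for adversarial
  geometries; for the pair/singleton geometries the assay produces it
  equals the brute-force maximum matching (tested).
- The published cohort-level AUCs (0.942 / 0.892 / 0.859) rest on 231
  unpublished per-case fractions and are deliberately not reproduced;
  the synthetic follicular cohort's AUC > 0.90 is a property check of the
  fitted class distributions, not a reproduction.
- Segmentation assumes non-overlapping, roughly convex nuclei; 3-D
  segmentation and learned backends are out of scope.
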