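# Methods

This note documents the models, estimators and numerical choices behind
`cscmap`, what the synthetic-data generator does and does not emulate, and
the problem sizes used by the reproduction script.

## Sensor model and gating

Per-cell sensor intensity is a scalar (mean over the cell disk; the
original acquisition may have thresholded per pixel, which is why the
statistic is a parameter of the workflow rather than hard-coded). A cell is
sensor-positive iff its intensity strictly exceeds the gate, so ties are
negative and raising the gate can never increase the positive count.

Two gates are provided:

- **Control quantile** (default q = 0.995). The control construct lacking
  the stemness response elements defines the background distribution; the
  gate is its empirical 0.995 quantile (linear-interpolation order
  statistic). The quantile trades tolerance of rare control outliers
  against a ~0.5% false-positive rate. That floor matters quantitatively:
  when the true positive rate in some stratum is p, the gated rate is
  ≈ p + 0.005(1 − p), which attenuates ratios between strata with small p
  (visible in the README example).
- **Top fraction** (default 5%). For surrogate markers with no control
  construct, the gate is the (1 − fraction) quantile; the resulting fixed
  range (gate, scale max) is recorded and reused verbatim on comparison
  tissue imaged under identical settings — reuse is by numeric value,
  never refitted.

## Distance profiles

Distances are 2-D Euclidean in µm on the section plane. Distance to a
doorway is measured to the circle *edge* (max(0, ‖c − center‖ − r)), so
cells inside or touching the 60 µm circle fall in a dedicated 0 µm bin;
distance to a vessel mask is read off a Euclidean distance transform.
Bins are half-open (lo, hi] in 40 µm steps to a 300 µm cap, with an open
terminal bin strictly beyond the cap. Per-bin %CSC is CSC count over
all-cell count; bins with zero all-cell count are flagged NaN rather than
reported as 0, to avoid fabricating depletion. The enrichment ratio is
pct(0 µm)/pct(terminal); enrichment over the tumor average is
pct(0 µm)/overall %CSC. Multi-field data can be pooled (concatenate
distances) or averaged per field; the package's own analyses pool counts,
which weights fields by cell number and keeps small-count bins stable.

## Contacts

Macrophage density is the positive-pixel (voxel) fraction of the mask.
"Direct physical contact" is operationalized as boundary-to-mask distance
≤ 0.5 µm (≈1 px at the default 0.5 µm/px), computed as
EDT(cell centroid) − cell radius with cells as 12 µm disks. The choice of
0.5 µm is a resolution-scale tolerance; contact calls are monotone in it.

## Tracking and speed

Detections are per-frame connected components above a threshold (Otsu by
default) with intensity-weighted centroids. Linking is greedy
nearest-neighbor between consecutive frames, gated at a maximum step
(default guidance: 3 × fast speed × frame interval), ties broken by
ascending distance then lowest index; unmatched detections seed new
tracks.

Speed is the mean displacement of the lightly smoothed track (centered
3-frame moving average with linear-extrapolation padding) divided by
elapsed time. The smoothing exists because per-frame localization error ε
inflates the naive step sum: for a cell with true step s·Δt, the expected
measured step is ≈ √((sΔt)² + 4ε²)·(a Rice-distribution factor), which at
s = 0.2 µm/min, Δt = 2 min, ε = 0.3 µm reads 0.33 µm/min — a 65% upward
bias. The smoothed estimator is exact for straight constant-speed motion,
recovers persistent-random-walk speeds within ~3–5% at these noise levels,
and the raw per-step value is still emitted (`speed_raw_um_per_min`)
together with the net/path confinement ratio. Tracks below a motility
floor (default 0.05 µm/min) are excluded from fast/slow comparisons, since
most tumor cells in vivo are stationary.

## Drift

Drift correction is translation-only: each frame is registered to frame 0
by phase correlation (50× upsampled) on a reference channel, and the same
sub-pixel shift is applied to all channels. Residual drift is the mean
frame-to-frame centroid speed of objects known stationary in truth,
localized by background-subtracted intensity-weighted centroids in a
window around their true positions. On the synthetic stationary-cell
movie with 0.3 µm/min injected drift the residual is ~0.006–0.01 µm/min.

## Protrusion periodicity

Events are peaks of the 3-frame-smoothed edge trace with a minimum
prominence (default 0.5 µm, below the 2 µm oscillation amplitude but above
the noise); the rate is peaks per hour. The dominant period is the lag of
the first autocorrelation peak, quantized to the sampling step. For a
clean periodic trace rate × period ≈ 60 min.

## Reporter kinetics, induction, and conversion mapping

The destabilized reporter follows first-order kinetics: after production
switches on at contact time t₀, the noiseless signal is
baseline + (P/k)(1 − e^(−k(t−t₀))) with k = ln2/half-life and half-life in
1–2 h (default 1.5 h). Induction traces are aligned to first contact
(t = 0), background-subtracted by the pre-contact mean and scaled to the
post-contact maximum — which makes normalized values window-dependent, so
the observation window is an explicit property, never a hidden constant.
The induction time is the first time the normalized trace exceeds
2 pre-contact SDs sustained for 3 consecutive frames; 3 frames (not 2)
because the pre-contact SD is estimated from a handful of frames and a
2-frame rule falsely calls ~25% of pure-baseline traces (measured over 400
noise traces), vs ~4.5% at 3 frames, with the reported crossing time
unchanged.

Fate mapping follows cells that start sensor-negative (mean of the first
3 frames at or below the gate) and counts a conversion when the sensor
exceeds the gate for 2 consecutive frames later on; the consecutive-frame
requirement suppresses the ~0.5%/frame false crossings the control gate
admits, which over a 100-frame movie would otherwise fabricate ~20%
conversion. Origin mapping looks backwards: among cells positive at the
end time, the fraction negative at the start time. On a fully observed
movie both recover the same planted conversion count.

## Invadopodia scoring

Puncta are Laplacian-of-Gaussian blobs (σ 0.15–0.6 µm, radius capped at
the 2 µm diffraction scale). The default response threshold (20) was
calibrated on the generator's rendering model to < 1 false positive per
noise-only field at ≥ 95% recall of planted spots; it is exposed because
any real acquisition needs its own calibration. Colocalization is
one-to-one matching within 0.5 µm: exact maximum-cardinality,
minimum-distance assignment for small instances (|A|·|B| ≤ 400), greedy by
ascending distance above that — deterministic and near-optimal at
densities where matches are unambiguous. Stem-cell areas are unions of
36 µm disks (three 12 µm cell diameters, capturing extended protrusions)
around gated stem cells, with a manual-boundary mask variant; the
invadopodia score is colocalized-puncta density per class area.
Degradation is the positive-area fraction per class above a threshold
(default: mean + 3 SD of a negative-control region); gelatin mode inverts
polarity because degradation appears as signal loss.

## Limiting dilution

Takes follow the single-hit model P(take) = 1 − exp(−f·dose). The
frequency f is fitted by maximum likelihood on log₁₀ f with closed-form
handling of boundary tables (all-negative: point estimate 0 with a
one-sided upper bound; all-positive: lower bound only). Confidence
intervals are profile-likelihood (χ²₁ drop of 1.92), which remain
well-defined near boundaries where normal approximations fail; arm ratios
carry a CI from treating log f as normal with the SE read off each profile
interval. At 3 doses × 6 injections a single fit carries ~20–25% median
error by information content (the Cramér–Rao bound is ≈ 0.29 f), so
recovery statements are about the *median* of replicate fits, which is
nearly unbiased: two arms planted at a 7.8-fold frequency ratio give a
median fitted ratio of ≈ 7.8 across replicate simulations.

## Cascade accounting

Compartment tables carry exact (Clopper–Pearson) binomial CIs because
several compartments are small (tens of cells). Fold decomposition is a
plain product of independent enrichment factors, order-invariant, reported
with a one-significant-figure rounding (7 × 2.4 × 3.5 = 58.8 → 60). Lesion
size classes use exact integer boundaries (small ≤ 10 cells, medium
11–300, large > 300); lesions are recovered from cell tables by
single-linkage clustering within 25 µm, which is exact on the generator's
sections because lesion footprints are separated by ≥ 120 µm.
Score–marker association is Pearson's r with a two-sided p, with an
optional natural-log transform of the score for sensitivity analysis;
zero-variance inputs are flagged rather than raised.

## The synthetic-data generator

The generator emulates the *statistical* structure each analysis assumes,
not microscopy physics: cells are 12 µm soft-edged disks (nuclei 8 µm) on
a 0.5 µm/px grid with 8-bit-range intensities and additive Gaussian noise
(SD 2); there is no point-spread function, no photobleaching, no 3-D
structure (single plane per frame), no cell division or death, and no
shape change. Sensor intensities are Gaussian: background mean 20, SD 5
(shared with the control construct, whose distribution the source
protocols do not pin down — it is exposed as a parameter) and positive
mean 120, SD 15, i.e. well-separated classes. Consequently, passing tests
demonstrate that the estimators recover planted parameters under the
stated geometry and noise — they do not certify segmentation or gating
performance on real tissue, where intensity distributions overlap and
shapes vary.

Specific choices:

- **Motility** is a persistent random walk: constant per-cell step
  |v|·Δt with heading diffusion of persistence time 10 min (only mean
  speeds are prescribed by the study conditions; 10 min is a typical
  mesenchymal persistence scale). Truth speeds therefore equal the
  configured class speeds exactly. Global drift adds a constant vector to
  observed positions; localization jitter is optional Gaussian noise on
  rendered positions.
- **CSC placement** uses a per-contour-bin probability profile over
  distance to the nearest doorway. Placement, labels, intensities and
  rendering draw from independent child streams of the seed, so two
  scenes with the same seed share cell positions even when label
  parameters differ — which is how a scene is planted at an exact bin-0
  over scene-average ratio (solve the profile scaling on the realized
  placement, then regenerate).
- **Contacts** are planted geometrically: a macrophage disk (r = 8 µm) is
  stamped overlapping each contacted cell's boundary by ~1 µm, while
  keeping ≥ 1.5 µm clearance from every non-contacted cell's boundary;
  rare cells whose neighborhoods admit no such placement are recorded as
  not contacted, so the truth table always matches the rendered mask.
  Additional coverage blobs respect the same clearance.
- **Puncta** counts are Poisson at the configured per-area densities;
  colocalized partners are planted within 0.3 µm, lone partner-channel
  spots at the complementary rate. A warning is recorded when same-channel
  spots fall close enough to merge. Degradation is planted per-pixel
  Bernoulli per class region (spatially unstructured — adequate for area
  fractions, not for morphology).
- **Lesions** are disks of cells (≈100 µm²/cell) with per-class cell-count
  ranges (small 1–10, medium 11–300, large 301–600) and per-cell stem
  labels at the class fraction, placed with bounded retries to enforce
  separation; an error is raised if placement fails.
- **Dilution tables** draw per-dose takes Binomial(n, 1 − e^(−f·dose)).

Identical seed and configuration give bit-identical output; the seed is
echoed in every truth table and image metadata block.

## Problem sizes in `scripts/acceptance.py`

Stochastic quantities are medians over replicate simulations, with
replicate counts chosen so the median's own sampling error is small
relative to the quantity: 61 fields for the doorway enrichment (each
5000 cells), 7 scenes for contact fractions (~600 non-CSCs each), 61
co-culture movies for fate mapping (~113 contacted cells each), 7 lung
sections for lesion percentages, and 2000 replicate dilution experiments
(the 18-injection MLE distribution is atomically discrete, so a
small-replicate median jumps between atoms). Single runs suffice for the
deterministic-enough quantities (tracking speed median over 20 slow
cells, protrusion period, residual drift). Total runtime ≈ 30 s on one
CPU.

## Known limitations

- 2-D only: live-tissue contact calls and voxel densities in the source
  workflows were 3-D; here 3-D density reduces to a mask fraction.
- The gated enrichment ratio is attenuated by the control gate's
  false-positive floor (see Sensor model); analyses that need exact
  recovery compare against truth labels.
- The greedy colocalizer is not guaranteed maximum-cardinality above the
  exhaustive-fallback size, and linking performs no gap closing or
  split/merge handling.
- Origin-map normalization depends on the observation window by
  construction; comparisons are only meaningful at matched windows.
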