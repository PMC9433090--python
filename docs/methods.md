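# Methods

This note documents the models and procedures implemented in `awapipe`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic-data generators do and do not emulate.

## Differential selection and enrichment

Fold change is the ratio of arithmetic replicate means with a pseudocount,
`r = (mean_fasted + c)/(mean_fed + c)`, `c = 0.5` by default. The
pseudocount keeps ratios finite for genes undetected in one condition; it is
configurable because the exact averaging scheme behind a fold-change figure
is rarely fully specified. Regulated sets use strict inequalities
(`r > t` up, `r < 1/t` down, default `t = 4`): a gene exactly at the
boundary is *not* "more than fourfold" changed.

Family overrepresentation in a selected set is tested one-sided (greater)
with Fisher's exact test on the 2×2 table
[in-set ∩ family, in-set ∖ family; out-of-set ∩ family, out-of-set ∖ family]
over the detected-gene universe. One-sided because the scientific claim is
overrepresentation.

Per-neuron enrichment against a binary neuron × gene atlas reports, for each
neuron, `k` (upregulated family genes expressed), `K` (all upregulated
family genes), `m` (family genes expressed), `M` (family universe), and the
ratio `(k/K)/(m/M)` — >1 means the neuron expresses a disproportionate share
of the upregulated family members. Significance uses a chi-squared test on
[k, K−k; m−k, (M−K)−(m−k)] without Yates correction; when any expected cell
is below 5 the implementation switches to a two-sided Fisher exact test,
since per-neuron counts are often small. Bonferroni correction is over the
neurons actually tested (those expressing at least one family gene); neurons
with `m = 0` are reported as not tested rather than given an undefined
ratio.

## Reporter quantification

A stack is scored as: max-intensity z-projection → box ROI around the soma →
`mean(top 5% of ROI pixels) − mean(bottom 5%)`. Tail size is `ceil(0.05·n)`
over a stable sort, so the score is deterministic, order-invariant, and
invariant to a constant intensity offset. The 5%/5% construction reads the
tails over *all* box pixels; an alternative reading (tails of a 1-D profile
along the box) exists but is not implemented. At least 20 pixels are
required so both tails are non-empty.

ROI localization automates the manual "draw a box around the neuron" step:
3×3 median filter, threshold at median + 5×(MAD-based σ), centroid of the
connected component containing the brightest filtered pixel, weighted by
background-subtracted intensity. Default box half-width is 10 px ≈ 3–4 soma
sigmas at the fixture scale; a flat image raises a detection error.

Scores are normalized per imaging session to the mean raw score of the
fed wild-type control group from the same session, making sessions with
different illumination comparable; group comparisons use two-tailed t-tests
(Welch by default) with Bonferroni correction over the requested pairs.

## Calcium traces

Freely-moving pipeline, in order: background channel subtracted frame-wise;
10-frame (1 s at 10 fps) centered moving median (edge windows truncate to
the available samples — a stated choice, since edge handling is otherwise
ambiguous); baseline = 5th percentile of the *smoothed* trace under the
linear-interpolation percentile convention; ΔF/F₀ = (smoothed − baseline)/
baseline. Baseline positivity is enforced with an explicit error. The
order (subtract, smooth, then take the percentile) is a declared choice.

Peak detection: local maxima above `min_amplitude` (default 0.2 ΔF/F₀)
separated by at least `min_separation` (default 2 s); duration is the full
width at half maximum — the contiguous run of frames at or above half the
peak amplitude. These criteria are declared defaults, configurable, since
peak criteria for this kind of data are conventionally unstated. Note that
a 1-s moving median flattens a sampled transient peak by a few percent;
with the fixture kinetics below the systematic amplitude attenuation is
≈3%, visible in the noise-free recovery tests.

Spatial analysis: signed distance to the lawn boundary (positive outside,
negative inside, continuous across the crossing; the encounter frame is the
first frame with distance ≤ 0), ΔF/F₀ binned into half-open 0.5 mm bins
with per-bin mean/SEM/n (empty interior bins reported with n = 0), and a
two-way fixed-effects ANOVA (state × distance bin, with interaction, type-II
sums of squares) on per-animal bin means.

Microfluidic pipeline: F₀ = mean fluorescence over seconds 2–3 of the
trial; percent change = (F/F₀ − 1)·100; epoch maxima over Pre 0.0–4.9 s,
Stim 5.0–15.0 s, Post 15.1–29.9 s with inclusive bounds exactly as printed.
A sample at exactly 5.0 s belongs to Stim; samples falling in the 4.9–5.0 s
gap (possible at frame rates above 10 fps) belong to no epoch.

## Behavioral endpoints

Chemotaxis index `(n_odor − n_control)/(n_odor + n_control + n_other)` and
food-choice index `n_exp/(n_exp + n_control)` are computed per plate and
summarized as mean ± SEM over plates; both are scale-invariant in the
counts. Exploration coverage rasterizes the track polyline onto a 3.5 mm
grid anchored at the corner of the plate's bounding square, using exact
grid traversal (Amanatides–Woo) so a fast segment cannot skip a square it
crosses. Because the bench assay's manual grid placement is unregistered,
an option averages the count over four quarter-square phase offsets.
Centroid speed is per-interval displacement over the frame interval.

## Synthetic-data generators

All generators are deterministic functions of a single integer seed
(`numpy` `default_rng`); the orchestration layer derives independent
sub-seeds with `SeedSequence.spawn`. What they emulate, and the defaults:

* **Expression tables** — lognormal replicate noise around condition means
  with a stated coefficient of variation (lognormal: positive support and
  simple ratio algebra). 8.5% of genes carry the chemoreceptor label,
  matching the family's prevalence among detected genes; planted
  upregulated genes draw their true fasted/fed ratio uniformly from
  (5, 8) by default. Not emulated: count discreteness, mean–variance
  trends, library-size effects — the pipeline starts from abundances, not
  reads.
* **Neuron atlases** — i.i.d. Bernoulli membership per (neuron, gene), with
  the 12 amphid neuron labels; an optional planted neuron has its
  expression probability for a target gene set multiplied by a stated
  excess (capped at 1). Not emulated: correlated gene modules or realistic
  per-neuron expression breadth.
* **Image stacks** — uniform background plus one isotropic Gaussian soma
  centred on a voxel (so the noise-free peak is exactly background +
  amplitude) plus Gaussian read noise, clipped at zero. Not emulated:
  autofluorescent gut, second neuron of the pair, depth attenuation.
* **GCaMP recordings** — neuron channel = background + F₀·(1 + Σ kernels)
  + noise, with difference-of-exponentials transient kernels normalized to
  unit peak so the planted amplitude is directly comparable to detected
  ΔF/F₀. Kinetics default to rise τ = 0.4 s, decay τ = 2.5 s — GCaMP-like
  fixture parameters, not claims about a specific indicator. The 2-D
  trajectory is a biased random walk toward the lawn center with fixed
  step length (~0.15 mm/s); after entry the radial coordinate is clamped
  inside, so the boundary is crossed exactly once and the encounter frame
  is well defined. Not emulated: locomotion dynamics, reversals, photobleaching.
* **Assay counts** — per-plate multinomials whose cell probabilities are
  solved so the expected computed index equals the planted index
  (chemotaxis requires |θ| ≤ 1 − other_prob).

Because the fixtures are i.i.d.-noise idealizations, passing recovery tests
demonstrates correctness of the estimators and error control under the
stated noise models — not robustness to motion artifacts, bleaching,
segmentation errors, or biological covariance structure.

## Problem sizes and tolerances

Recovery suites use sizes at which the checked properties are properties of
the method rather than of sampling luck: 1,000-gene tables with 20 planted
genes over 100 seeds for DE recovery; the study-scale family (133
upregulated of 1,410 chemoreceptors, 12 neurons) for enrichment
specificity, where the chi-squared test has essentially full power; 1,000
null atlases for family-wise error; 100 stack pairs for the fivefold
reporter readout (tolerance 10%, covering the small percentile-tail noise
bias); 50 recordings × 10 transients at SNR 5 for calcium sensitivity
(≥90%) and amplitude error (<10%, dominated by the ~3% median-flattening
and the baseline-percentile offset under noise); 10,000 simulations for the
t-test type-I rate (0.05 ± 0.01). Monte-Carlo assertions on stochastic
quantities include their own sampling error (e.g. 3 binomial SEs) rather
than treating a noisy estimate as exact.

## Known limitations

* The ROI locator assumes a single dominant soma; two comparably bright
  structures in one projection would need the z-window option or manual
  boxes.
* The moving median is O(n·w); adequate for minutes-long recordings at
  10 fps, not optimized for hours of video.
* The exploration rasterizer counts squares intersected by the centroid
  polyline; a real worm's body width slightly inflates manual counts.
* No bleaching correction beyond the percentile baseline; slow drift
  inflates the baseline and compresses ΔF/F₀.
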