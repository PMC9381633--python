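# Methods

This note documents the models, rules and numerical choices implemented
in `synquant`, the assumptions behind the synthetic-data generators, and
what passing the recovery benchmarks does and does not establish about
real data.

## Fluorescence synapse quantification (`synquant.imaging`)

**Neurite identification.** The dendrite channel is enhanced with a
single-scale Sato (Hessian-eigenvalue) tubeness filter. The scale
defaults to half the expected neurite width (0.5 µm for ~1 µm dendrites);
the method names only the filter family, so the scale is an exposed
parameter. The enhanced image is binarised (Otsu by default; robust
background or a fixed value are accepted), morphologically closed and
hole-filled before thinning: the tubeness response of a ridge wider than
the filter scale peaks at both ridge edges, and skeletonising the raw
binary would double-count such stretches as two parallel lines. Cell
bodies are removed beforehand: Otsu on the lightly smoothed channel, an
opening with a disc wider than the neurite half-width (0.75 µm) so that
thin processes vanish while compact somata survive, a size gate
(≥ 20 µm²) and a 1-pixel rim dilation.

**Length convention.** Dendrite length is the skeleton pixel count ×
pixel size, with no √2 diagonal correction. The synthetic generator
records ground truth in the same convention (unique rasterised path
pixels outside cell bodies) alongside the Euclidean path length.
Skeletonising a band of imaged width cannot follow path wiggles below
the band width, so measured length runs ~5–10% short of the raster
truth; the bias is condition-independent and cancels in density ratios.

**Puncta.** Spot detection is Gaussian smooth (default σ 0.1 µm) →
white tophat (disc radius 0.5 µm, i.e. about twice the punctum radius) →
threshold → 8-connected labelling, with optional area gates. Culture
images default to Otsu on the tophat image, which on sparse-punctum
fields separates signal from the positively biased tophat noise floor
far more reliably than a background-statistics threshold. Per-punctum
area and mean intensity are measured on the original channel.

**Synapses.** Only postsynaptic puncta with ≥ 1 pixel on the neurite
mask are retained (the postsynaptic punctum is the reference object). A
synapse is a retained postsynaptic punctum overlapping ≥ 1 presynaptic
punctum by ≥ 1 pixel; with several partners the largest pixel overlap
wins, ties resolved toward the smallest presynaptic label. Density is
synapse count / dendrite length; images with empty skeletons raise and
are excluded.

**Tissue sections.** The robust-background threshold is the trimmed mean
plus one *sample* (n−1) SD after discarding the dimmest and brightest 5%
of pixels (the conventional default of the named method; only
"mean + 1 SD" is fixed by the procedure). For dual-stain density the
threshold is frozen per experiment: the mean of per-section
robust-background thresholds over the reference group, applied unchanged
to all groups, so no group difference can arise from adaptive
thresholding. A mean + 1 SD cutoff only separates stain from background
when stained structure occupies more than the trimmed tail of the pixel
population; this holds for the densely stained regions the procedure is
used on (and for the generator's tissue fields), not for arbitrarily
sparse images. DAB sections are colour-deconvolved with the standard
H-DAB stain matrix; the DAB channel is triangle-thresholded and
particles under 4 pixels discarded before reporting percent-positive
area. Nuclei density counts size-gated connected components (optional
watershed split) whose centroids fall inside the ROI, per mm².

## PLA (`synquant.pla`)

CTCF is the exact identity integrated density − cell area × mean
background over operator-drawn ROIs; it may be negative and is reported
as-is. Spot counting reproduces prominence-based maxima finding: a
regional maximum of height v counts when the connected superlevel set at
v − tolerance contains nothing brighter, when it stands more than the
tolerance above the image floor, and when it does not touch the 1-pixel
border; connected equal-height maxima count once. The tolerance is a
required analysis parameter; `default_noise_tolerance` proposes 5× the
robust background SD.

## mEPSC analysis (`synquant.minis`)

Baseline is a centred rolling median (200 ms window) — robust to the
events themselves. Candidates are runs below baseline + threshold
(default −5 pA, the midpoint of the −4 to −6 pA range) lasting > 1 ms,
with a 10 ms dead time after each accepted onset. Per event, the local
baseline is the median of the 5 ms before the crossing; the peak is
located on a 3-point-median-smoothed segment and its amplitude read as
the mean of raw samples within ±0.25 ms (averaging rather than taking
the raw extremum removes most of the noise-selection bias that would
otherwise inflate amplitudes by several percent). The 10–90% rise time
interpolates the crossings on the smoothed segment, searching a 2 ms
pre-crossing window because the 10% point precedes threshold. The decay
constant comes from a least-squares single-exponential fit from the peak
(window: 5× an initial 1/e estimate, capped at 100 ms or the next
event); fit failures are recorded as rejections. Because the kernel's
rising component still decays just after the peak, fitted τ runs ~4%
above the generating decay constant — well inside the event-selection
tolerances this quantity feeds.

"Monotonic rising phase" is tested with tolerance: the rise segment is
Gaussian-smoothed (σ 0.25 ms) and flagged non-monotonic when any
counter-excursion (drawback from the running extremum) exceeds one noise
SD. Literal sample-wise monotonicity is measure-zero under noise; with
this rule ~2% of clean noisy events are lost while sustained (≳0.5 ms)
secondary deflections are caught. Acceptance requires all five rules
(amplitude ≤ threshold, duration > 1 ms, monotonic rise, rise < 6 ms,
τ < 25 ms); cell summaries flag frequencies below 0.05 Hz for exclusion
and recordings are expected to last ≥ 2 min.

## MEA analysis (`synquant.mea`)

The stated 2nd-order 200 Hz Butterworth is implemented as a zero-phase
*high-pass* (forward–backward `sosfiltfilt`): spike-band conditioning is
the standard reading, a 200 Hz low-pass would destroy spikes. Spike
detection thresholds both polarities at k × SD (k = 5) with the baseline
SD estimated robustly as MAD/0.6745 (raw SD available by flag), one
spike per suprathreshold run at its extremum, 1 ms refractory.

Burst detection uses the dual start-ISI parameters as: first ISI ≤ 0.1 s
(max beginning ISI), subsequent ISIs ≤ 0.5 s (max ISI to end); the
separate 0.5 s "max ISI to start" is retained in the parameter record
(`strict_beginning=False`) for the alternative vendor semantics, which
the available description does not disambiguate. Bursts closer than the
0.8 s minimum IBI are merged (spanning any spikes between them), then
bursts with < 3 spikes or < 0.05 s duration are discarded. Network
bursts are single-linkage clusters of burst onsets with linkage distance
≤ 0.2 s, at most one burst per channel (earliest wins), with a channel
quorum defaulting to max(2, half the active channels) — the quorum is
not specified by the procedure and is recorded in output metadata.
Active channels default to ≥ 0.1 spikes/s; arrays with < 10 active
channels are flagged excluded. Metrics: mean interval between network
burst onsets (undefined and flagged below two bursts), mean member-burst
spike rate, mean network-burst length.

## EM vesicle pools (`synquant.em`)

Operates on point annotations (vesicle identification in micrographs is
manual upstream). Terminal area by the shoelace formula (nm² → µm²);
docked vesicles are those whose *centre* lies within 125 nm of the
membrane polyline, the exact minimum over point-to-segment distances.
Whether the criterion applies to centres or membrane-proximal edges is
not stated; centre-based is the default because it is reproducible from
point annotations, and an edge-based option (distance − diameter/2) is
provided. The diameter validity band 30–70 nm encodes "~50 nm" and is
configurable.

## Statistics (`synquant.stats`)

Two groups: two-tailed t (classic pooled-variance by default — the
default of the plotting/statistics software such analyses are run in —
Welch by flag); ≥ 3 groups: one-way ANOVA then Tukey HSD on all pairs
(statsmodels); one-sample designs run both the one-sample t and the
Wilcoxon signed-rank (exact for n ≤ 25 without ties, else normal
approximation with continuity correction). Quartiles use linear
interpolation so box-whisker summaries match the usual plotting
convention. ΔΔCt: ΔCt = Ct_target − Ct_reference per sample, referenced
to the control-group mean ΔCt, expression = 2^−ΔΔCt. Per-image and
per-cell values are treated as independent replicates, mirroring the
upstream convention; this is a pseudo-replication caveat, not a feature.

## Synthetic data (`synquant.synthetic`)

The generators define the study conditions for all recovery benchmarks.

*Imaging*: neurites are gently curving random walks (small per-step
turning, initial heading across the field) of stated width from
disc-shaped somata; walks that would run alongside an existing neurite
are redrawn, because parallel runs closer than the imaged width are
physically unresolvable and real dendrite stretches in a field of view
do not double back on themselves. Punctum sites sit on the paths at the
condition-scaled linear density (deterministic count = round(density ×
length)) with ≥ 3 punctum-radii spacing; each site is a matched pre/post
pair with probability `coloc_fraction` (partners offset 1 pixel),
otherwise alternately pre- or post-only. Spots render as Gaussians
(σ = radius/2) convolved with a Gaussian PSF, over constant background
with Gaussian read noise (Poisson shot noise omitted for analytic
tractability). Defaults: 512² px at 0.12 µm/px, 5 neurites, 0.35
synapses/µm, coloc 0.8, punctum radius 0.25 µm, intensity 120 ± 25 on
background 10 with noise SD 4, PSF σ 0.15 µm — a clean 12-DIV culture
field at confocal resolution. The knockdown condition multiplies density
by 0.75.

*Traces*: Poisson event times; each event is A·(1−e^(−t/τr))·e^(−t/τd)
normalised to unit peak; defaults 10 kHz, 120 s, 1 Hz (0.42× for the
test condition), −22 ± 4 pA truncated at −10 pA (sub-threshold events
are not modelled), τr 1 ms, τd 8 ms, noise SD 2 pA. Ground truth stores
per-event onset, amplitude and the kernel's exact 10–90 time.

*Rasters*: array-wide burst onsets follow a gamma renewal process
(shape 5, mean 1/burst_rate) — cultures burst quasi-periodically, and a
Poisson process would make the recovered mean interval needlessly noisy
at the 6-arrays-per-condition design size; channels join each burst with
probability 0.9, jittered by 20 ms, firing Poisson at 100 Hz for 0.3 s
over 0.4 Hz tonic activity; 12 channels, 300–600 s.

*Vesicle annotations*: an irregular convex terminal polygon (star-shaped
octagon scaled to the target area, default 1.2 µm²); the membrane is a
three-vertex stretch of its boundary; a `docked_fraction` of vesicles is
placed within the docking radius of the membrane, the rest uniform in
the polygon; diameters 50 ± 5 nm. Ground truth stores each centre's
exact membrane distance, so the "true docked count" includes reserve
vesicles that land near the membrane by chance.

**What the generators do not emulate**: optical sectioning and
z-projection artefacts, structured background (astrocytes, neuropil),
intensity-dependent shot noise, electrode drift or seal instability,
spike waveform diversity and overlapping units, EM section compression.
Passing recovery benchmarks therefore establishes that the analysis
rules are implemented correctly and are unbiased at realistic SNR — not
that they are robust to every artefact of real acquisitions.

## Benchmark problem sizes

Recovery benchmarks run at the design scale of the corresponding
experiments: 20 images/condition (density factors 1.0, 0.75, 0.66,
recovered within ±0.08), 12 two-minute traces/condition (frequency
ratio 0.42 within ±0.08, amplitudes within 5%), 6 arrays/condition
(mean network intervals of 7.3 s and 22.6 s cultures within 10% of
realized truth), ~100 EM synapses/group (density factor 0.70 within
±0.05). Statistical calibration uses 10,000 null replicates of n = 20
(all implemented tests within [0.04, 0.06] at α = 0.05; the Tukey
family-wise rate is evaluated through the studentized-range critical
value, and the suite separately proves the package's Tukey p-values
match the independent SciPy implementation).

## Known limitations

- Sub-resolution geometry (parallel neurites, merged puncta) biases
  per-image measurements; ratio designs cancel most of it.
- The robust-background threshold needs stained foreground to exceed the
  trim fraction; it is not a general spot-detection threshold.
- Event detection is threshold-based, not template-matched; heavily
  overlapping mEPSCs are merged under the dead-time rule.
- The exact vendor semantics of the dual burst start-ISI parameters and
  of the 5×SD "baseline" are configurable interpretations, not
  resolutions of the ambiguity.
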