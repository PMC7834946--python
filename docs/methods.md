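# Methods

This note documents the models, conventions, and calibration behind
`pupilload`: what each stage computes, which choices were genuinely open,
and what the synthetic generator does and does not emulate.

## Units and conventions

Time is milliseconds from recording start everywhere inside the package
(completion times in the tens of seconds are therefore 5-digit numbers).
Pupil diameters are in pixels, as delivered by screen-based eye trackers
before millimetre calibration. A missing diameter is NaN in memory; on
ingestion any diameter ≤ 0, NaN, or flagged invalid becomes missing,
because trackers emit zeros during blinks and a zero entering a mean would
silently corrupt every downstream feature. Intervals are half-open
`[start, end)` so no boundary sample is double-counted. Latency to peak is
reported in seconds; ties for the maximum resolve to the earliest sample.

## Baseline images by scrambling

`grid_scramble` partitions the frame into *n* columns × *m* rows (floor
division; the rightmost column and bottom row absorb any remainder so the
partition is exact) and permutes pixels uniformly *within* each cell. RGB
pixels move as intact triplets, so the joint colour distribution is
conserved; per-cell pixel multisets — hence global and local mean
intensity — are conserved exactly. The within-cell reading (rather than
permuting whole cells) is adopted because it is the variant that preserves
both mean and local intensity while a coarser grid obscures more content.
One seeded generator per image consumes cells in row-major order, so
outputs are bit-reproducible. Grayscale conversion uses Rec. 709 luma
weights (0.2126, 0.7152, 0.0722).

## Preprocessing

The two eye channels are averaged per sample (one valid channel suffices).
The Hampel filter uses half-window k = 5 (11 samples ≈ 183 ms at 60 Hz)
and a threshold of 3 scaled MADs; the MAD is multiplied by 1.4826
(Gaussian consistency) and floored at 0.01 px so a locally constant signal
does not flag harmless fluctuations. Missing samples are excluded from
window statistics and never replaced; edge windows are truncated. Blink
gaps are filled by linear interpolation only when the unobserved span
between flanking valid samples is ≤ 500 ms; edge gaps are never
extrapolated. Each sample carries a provenance flag
(raw/replaced/interpolated/missing) so cleaning is fully reportable.
Baselines are the mean over the final 2,000 ms of an 8,000 ms fixation and
require ≥ 50% of the expected samples to be valid.

## Statistics

*Wilcoxon signed rank.* Zero differences are dropped; tied magnitudes get
midranks. For n ≤ 12 nonzero differences the two-sided p is exact:
doubling the midranks makes them integers, and the null distribution of
the positive-rank sum is built by convolution over all 2ⁿ sign
assignments (the distribution is symmetric, so the smaller tail is
doubled). Above n = 12 the normal approximation with tie-corrected
variance and continuity correction is used; the z statistic is always
reported from that approximation, signed so that values systematically
larger under the hard condition give negative z.

*Feature selection* pairs participant-level means per world — each
participant contributes one value per world and feature, the mean over
that world's two levels — which respects the repeated-measures structure.
A feature is selected at p < α (α = 0.05 two-sided by default).

*Within-subject ANOVA.* Classical sums-of-squares decomposition with
(k−1, (k−1)(s−1)) degrees of freedom. Mauchly's W is computed from the
eigenvalues of the orthonormally-contrasted covariance, with the standard
chi-square approximation including the second-order correction term (as in
ezANOVA). The Greenhouse–Geisser ε = (Σλ)²/((k−1)Σλ²) is clipped to
[1/(k−1), 1]; with two conditions ε = 1 exactly. The headline p applies
the sequential rule: ε-corrected when Mauchly rejects at α, uncorrected
otherwise. Post hoc comparisons are paired t-tests at α divided by the
k(k−1)/2 pair count; group labels are the connected components of the
graph joining pairs that do *not* differ significantly.

*Classifier.* Random forest with 100 trees, √|features| subsampling per
split, no depth limit, pinned seeds. The split is participant-wise (3 of
20 train, the rest test) so registers of one participant never straddle
the split. Because a 3-participant training set makes single-split
accuracy highly variable, the feature-set comparison repeats the split
over 50 seeds and reports mean ± SD accuracy per set; a single-split run
remains available through `split_by_participant` directly.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes, not
retinal physiology. A participant is (d₀, light gain g ≤ 0, TEPR gain,
skill): d₀ ~ N(30, 3²) px, g ~ −|N(−0.022, 0.005²)| px per effective-
luminance unit, TEPR gain ~ logN(0, 0.15²), skill ~ U(0, 1).

*Light response.* The steady-state shift while viewing an image is
g · (L_eff(image) − L_eff(reference)), where the effective luminance
L_eff = mean intensity − 1.3 × (SD of 16-px-cell means). The structure
penalty stands in for retinal adaptation to spatial contrast: a uniform
slide of the same mean drives the retina harder than a structured scene.
This single mechanism makes the whole baseline-image ordering emerge:
white ≫ reference (strong constriction during baseline → large positive
MPDC), black ≪ reference (negative MPDC), whole scramble preserves the
mean but erases structure (moderate positive MPDC), grid scrambles
preserve both (MPDC near zero, shrinking as the grid refines). The
synthetic frame (288 × 192, bright panel + bright blocks on a gradient,
mean ≈ 166) and the constants above were calibrated once so the expected
MPDCs are ≈ +3.2 (white), −2.1 (black), +1.3 (scramble), ≤ 0.3 (grids).

*Task-evoked responses.* During play the diameter is d₀ (+ session drift)
+ a sustained effort shift (1.5 px easy, 2.0 px hard) + Poisson-placed
phasic events convolved with a unit-peak gamma kernel (onset 300 ms, peak
≈ 850 ms, < 5% of peak by 4 s — short-latency responses that subside
quickly). Phasic amplitudes are N(4.0, CV 0.45) px easy and N(15, CV
0.45) px hard, times the participant's TEPR gain; event counts are
Poisson(5.0) easy and Poisson(3.5) hard, with event times exponential
(scale 10 s) capped at a fixed 25 s initial-analysis horizon. The horizon
and the high amplitude CV make the *location* of the peak carry no
difficulty information, so latency to peak is a null feature even though
level durations differ — matching the observed dissociation where the
size-related subtractive features (MPDC, PD) carry the difficulty signal
and the time-related one does not.

*Divisive-feature null.* Before the hard world the session tonic drifts
up by 30% of d₀ (arousal carry-over). The drift enters the world-B
baseline and measurement equally, so subtractive features are untouched,
but it inflates the APCPS denominator by almost exactly the ratio of the
worlds' expected MPDCs — making the divisive feature uninformative, again
matching the observed pattern.

*Telemetry.* TE ~ Poisson(0.5 easy / 2.5 hard, scaled by e^(0.8·(0.5−skill)));
TC ~ logN with medians 43,486 ms (easy) and 83,970 ms (hard), σ = 0.25
plus a skill term; CP ~ Poisson(1) and attempts 1 + Poisson(0.5) carry no
difficulty effect by construction. Noise: 0.25 px per sample plus 0.10 px
per eye, a ±0.30 px tonic jitter per interval, blinks at 0.1 Hz (~150 ms,
both channels lost), and isolated ±5 px tracker spikes at 0.05 Hz for the
Hampel stage to remove.

One global seed fans out through `SeedSequence` spawn keys per participant
and trial, so enlarging a cohort never changes existing participants'
data.

*Calibration.* The constants above are the package's default study
conditions: cohorts of 14 (baseline-image comparison) and 20 (difficulty
study) participants reproduce the qualitative pattern — baseline-image
ordering with the three grid sizes forming one post hoc group; TE, TC,
MPDC, PD selected and CP, A, LP, APCPS not; classifier accuracy of game ∪
pupil features ≥ game features alone — with ≥ 90% probability per
replicate. They were fixed once against pilot seeds and are not adjusted
per run.

## What the generator does not emulate

Gaze-angle foreshortening, mm calibration, age/health/drug effects on
pupil size, nonlinearity of the light reflex, saccades and fixations,
realistic game frames, or correlations between telemetry and pupil
dynamics beyond the shared skill/difficulty structure. Passing tests
therefore demonstrate that the *pipeline* recovers the structure it
assumes at realistic sizes and noise levels, not that real cohorts would
show the same effect sizes. In particular the absolute classifier
accuracies and peak-dilation magnitudes of simulated cohorts exceed what
small human studies report, because the generator's effect sizes are set
for reliable qualitative recovery at n = 20.

## Degenerate inputs and numerical choices

Empty traces, all-missing intervals, zero baselines, incomplete levels
(no completion event), duplicate (participant, level) registers,
single-class training sets, and participants missing a world all raise
informative errors (or warn and exclude, where the design says so).
Constant vectors route to the nonparametric branch of the normality gate.
All-zero-difference pairings are degenerate for the signed-rank test and
raise. ε is clipped into its theoretical bounds; Mauchly's W is clipped
away from 0 before taking logs. Feature selection at α ≥ 1 selects
everything (p-values can be exactly 1).
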