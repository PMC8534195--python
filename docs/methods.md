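# Methods

## Synthetic call model

Calls are rendered as frequency-modulated sinusoids via phase integration
of a programmed instantaneous-frequency trajectory, with raised-cosine
onset/offset ramps (2 ms, capped at a quarter of the call) to avoid
spectral splatter. Trajectories per category:

| type  | trajectory | parameter priors (defaults) |
|-------|------------|------------------------------|
| LF    | constant   | base U(21, 27) kHz, duration U(30, 120) ms |
| Flat  | constant   | base U(35, 75) kHz, duration U(20, 80) ms |
| FM    | monotone curved sweep | base U(40, 70) kHz, extent U(6, 12) kHz, duration U(20, 80) ms |
| Trill | sinusoidal FM | base U(50, 75) kHz, depth U(5, 9) kHz, rate U(60, 90) Hz, duration U(50, 90) ms |

All trajectories stay within 20–100 kHz (validated at construction). The FM
sweep carries a half-cycle arc (curvature < extent/π, so the trajectory
remains monotone and its frequency extent equals the sweep extent). A
perfectly linear sweep would have sinuosity exactly 1.0 — indistinguishable
from a Flat call on that parameter — whereas real FM calls are wiggly; the
arc is the minimal shape that preserves the expected category ordering
(Trill most sinuous, then FM, then Flat) while never triggering the trill
cycle criterion (at most one extremum). Trill modulation depth exceeds the
FM half-extent so that trills are the most frequency-modulated category
(peak-to-trough 10–18 kHz vs 6–12 kHz), as expected from the literature.

These priors also keep every sampled call at least twice the classifier's
decision thresholds away from every category boundary (extent ≥ 2× the
3 kHz flat threshold; ≥ 3 oscillation cycles vs the 2-cycle minimum;
duration ≥ 2× the 8 ms trill minimum), so ground-truth labels are
unambiguous.

## Session and experiment model

Call onsets are drawn per type from an inhomogeneous Poisson process
(thinning algorithm) with piecewise-constant rates over 10-min bins:

* baseline (30 min): first-bin rates LF 0.3, Flat 2, FM 3, Trill 2
  events/min, decaying ×0.6 per bin. The paper-scale absolute rates are not
  published numerically, so these are fixed once as plausible for
  amphetamine-context rats; all downstream claims are about relative
  structure, not absolute counts.
* post-injection (60 min): rates jump to surge × first-bin baseline
  (surge ×8 for FM/Trill, ×3 for Flat, ×1 for LF), hold that peak for the
  first two bins (maximal in the first 20 min) and decay ×0.6 per bin
  thereafter — so the profile is non-increasing after the peak.
* condition multipliers: CNO ×0.5 on FM and Trill only; females ×1.5 on
  Trill.

A 50 ms refractory gap guarantees detector separability. Colliding onsets
are shifted forward to the first admissible time rather than dropped, which
conserves expected counts exactly (drop-based enforcement would bias the
Poisson mean by the dead-time fraction, ~2 % at the tested rates); events
pushed past the epoch end are dropped, and an error is raised when the
offered load exceeds the epoch capacity.

Event-level experiments (`simulate_experiment`) add per-rat log-normal rate
heterogeneity (σ = 0.4, shared across both test days) and per-day jitter
(σ = 0.15), giving counts realistic overdispersion relative to pure
Poisson. Audio is only rendered when the detector is under test; the
statistical battery operates on the event stream, which is what makes
100-repetition power analyses tractable.

Noise is white Gaussian; SNR is defined as mean call power (amplitude²/2)
over noise power within the 20–100 kHz band. The generator does not emulate
colored cage noise, echoes, overlapping callers, amplitude variation within
a call, or the learned-denoiser artifacts of real recording rigs — a
detector that is perfect here (it is, at ≥ 0 dB band SNR, because an FFT
concentrates a tonal call into a few bins) will not be perfect on real
audio. What the tests establish is the internal consistency of the chain:
every stage recovers what the generator put in, at the stated operating
points.

## Detection

Power spectrogram: 512-sample Hann window, 75 % overlap (0.49 kHz × 0.51 ms
resolution at 250 kHz). Per frame, pixels above median + 5·(1.4826·MAD) of
the band-limited (18–105 kHz) power are active; 8-connected components are
candidate calls. Components below 3 pixels are discarded as specks before
merging; fragments of ≥ 10 pixels separated by ≤ 5 ms merge when the facing
frame-edge frequency ranges come within 6 kHz (frequency continuity —
plain bounding-box overlap lets noise specks chain onto call onsets and
biases onset estimates early). Per frame, the magnitude-weighted mean
frequency of the component forms the contour; merged-gap frames are filled
by linear interpolation.

Contours are kept when they have ≥ 12 pixels, last more than 2 ms after
subtracting the window smear (window − hop ≈ 1.5 ms; without this
correction a 1.5 ms burst measures ~3 ms purely from windowing), and have a
principal frequency inside 20–100 kHz. Rejection rules: instantaneous
bandwidth > 25 kHz in any frame (click), median fraction of band power
within ±3 kHz of the ridge < 0.35 (weakly tonal; a genuine call at 0 dB
band SNR still scores ≈ 0.5), duration > 1 s.

Onset is reported as the first frame center minus half a hop; matching to
ground truth uses greedy one-to-one assignment with 5 ms onset tolerance.

## Features

* Principal frequency: unweighted mean of contour frequencies.
* Change in frequency: max − min over the contour. The absolute (max−min)
  convention is used rather than signed last−first because a trill returns
  near its start frequency and would otherwise score ~0, contradicting its
  status as the most modulated category.
* Sinuosity: path length ÷ endpoint chord, computed in grid units (time in
  frame steps, frequency in bin steps) so the axes are commensurate;
  mixing seconds with kilohertz would make the value depend on an arbitrary
  unit choice. A z-scored variant is available for sensitivity analysis.
* Duration: contour span + one frame step, so a k-frame contour has
  duration k·hop and a single-frame contour cannot be zero-length.

## Classification

Decision cascade: principal < 30 kHz → LF (30.0 kHz exactly is
high-frequency, giving exclusive half-open bands); extent < 3 kHz → Flat;
duration ≥ 8 ms and ≥ 2 rapid cycles → Trill; else FM. The 3 kHz flat
threshold and the cycle gates (excursions ≥ 1.5 kHz peak-to-trough, mean
cycle period ≤ 25 ms) operationalize the visual criteria "visible
modulation" and "rapid oscillation", which have no published numeric
values; all are config-exposed.

Cycle counting detrends the frequency track with a centered 25 ms moving
average, counts sign changes of the residual between excursions that clear
the amplitude gate, and reports ceil(changes / 2). The ceiling (not floor)
is deliberate: a sine of n whole cycles starting at phase 0 has 2n−1
interior crossings, and the count should be n regardless of starting phase.

## Statistics

The mixed ANOVA uses the multivariate contrast formulation: for each
within-subject effect, the subject × cell matrix is projected onto
orthonormal (Helmert) contrasts, the scores are regressed on the
effect-coded between-subject design, and the univariate F pools contrast
columns — hypothesis SS from the type-III linear hypothesis, error SS from
the residual SSCP trace, with df (q, q(N−g)). Greenhouse–Geisser ε is
tr(Σ)²/(q·tr(Σ²)) of the pooled contrast covariance, clamped to [1/q, 1]
(exactly 1 for two-level factors). Both uncorrected and corrected results
are always computed; the headline p uses the correction when a
Mauchly-style sphericity test rejects at 0.05 — a fixed, reproducible rule
rather than analyst discretion. Counts are analyzed untransformed; zeros
are data, and zero-call rats stay in count ANOVAs. The implementation is
verified in the test suite against an independent observation-level
projection oracle (type-III RSS differences) to 1e-8, and reproduces
R `car::Anova(..., type=3)` with sum-to-zero contrasts.

Wilcoxon rank-sum: midranks for ties; exact two-sided p
(2·min(P(W≤w), P(W≥w)), capped at 1) by full enumeration of all C(n, nₐ)
splits when n ≤ 20, normal approximation with tie and continuity
corrections above. One-way ANOVA across call types is between-subjects
(not all rats emit all types), with Tukey–Kramer HSD for unequal group
sizes via `scipy.stats.tukey_hsd`. All tests are two-sided at α = 0.05.

Degenerate inputs: all-equal data yield F = 0 (sums of squares below a
relative 1e-12 floor count as zero); zero-variance nonzero differences in a
paired t raise rather than report an infinite statistic.

## Embedding

Features are z-scored (constant columns dropped with a warning) and
projected with UMAP (default neighbors 15, min_dist 0.1, fixed
random_state, single-threaded for determinism). Duplicate feature rows are
collapsed onto the coordinates of their first occurrence after fitting,
making the map a function of the input. Cluster structure is summarized
with k-means on the 2-D coordinates (k = 3 by default, matching the
visually determined cluster count such maps typically show; silhouette
scores for k = 2..6 are reported so the choice is inspectable). Composition
tables conserve global type proportions exactly by construction.

## Problem sizes

Defaults were chosen so the whole suite runs comfortably on a laptop-class
single core: detector evaluation uses three 5-min sessions at 20 dB SNR
plus 1-min sessions for the SNR sweep; the classifier battery is 400 calls;
the power analysis is 100 simulated 16-rat experiments at the event level.
All sizes are arguments, so larger replications are one call away.

## Known limitations

* The detector's perfect score on synthetic tonal calls over white noise
  says nothing about colored noise, overlapping calls, or faint calls
  recorded off-axis; the rule thresholds would need re-tuning per rig.
* Overlapping-call separation is out of scope; the generator's refractory
  gap makes overlap impossible by construction.
* The four-category scheme is coarse (finer taxonomies with ≥ 14 subtypes
  exist); the embedding stage is the tool for looking past it.
* The mixed ANOVA requires complete within-subject cells; missing sessions
  must be handled upstream (it raises, listing the missing cells).
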