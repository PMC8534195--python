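# usvkit

Analysis pipeline for rat **ultrasonic vocalizations (USVs)** — the 20–100 kHz
calls rats emit during aversive (20–30 kHz "22-kHz" calls) and appetitive
(30–100 kHz "50-kHz" calls) states — built for within-subject pharmacology and
chemogenetics experiments in behavioral neuroscience.

The package covers the full chain a USV study needs, with a synthetic-data
generator that provides ground truth at every stage:

1. **Synthesis** (`usvkit.synth`) — parametric call rendering (constant tones,
   frequency sweeps, sinusoidally modulated trills) and whole experimental
   sessions: inhomogeneous-Poisson call onsets with a decaying 30-min
   baseline, a post-amphetamine surge maximal in the first 20 min,
   multiplicative suppression of FM/Trill rates under a CNO condition, and a
   female > male trill-rate effect. Output is 16-bit PCM WAV (250 kHz) plus a
   ground-truth CSV.
2. **Detection** (`usvkit.detect`) — power spectrogram (512-sample Hann
   window, 75 % overlap), per-frame adaptive thresholding
   (median + k·MAD), 8-connected component grouping with
   frequency-continuity gap merging, ridge extraction, and rule-based noise
   rejection (broadband clicks, weakly tonal components, over-long sounds).
   Calls must exceed 2 ms and lie in the 20–100 kHz acceptance band.
3. **Features** (`usvkit.features`) — the four standard call parameters:

   * principal frequency — mean frequency along the contour (kHz);
   * change in frequency — max − min frequency over the call (kHz);
   * sinuosity — contour path length ÷ endpoint chord length (≥ 1),
     computed in spectrogram grid units;
   * duration (ms).
4. **Classification** (`usvkit.classify`) — the four-category scheme:
   **LF** (principal frequency in [20, 30) kHz), **Flat** (modulation
   < 3 kHz), **Trill** (≥ 8 ms with ≥ 2 rapid oscillation cycles), **FM**
   (modulated, non-trill).
5. **Statistics** (`usvkit.stats`, `usvkit.analysis`) — counts in 10-min bins
   analyzed by mixed ANOVA (within-subject Drug × Time, between-subject Sex)
   with Greenhouse–Geisser correction; paired/independent *t* tests; exact
   Wilcoxon rank-sum on call-type proportions; one-way ANOVA with Tukey HSD
   across call types.
6. **Embedding** (`usvkit.embed`) — z-scored features projected to 2-D with
   UMAP, k-means cluster composition summaries and silhouette profiles.

## Worked example

`examples/04_drug_effect_statistics.py` simulates a 16-rat experiment (8
female, 8 male, each tested on a vehicle and a CNO day) and runs the
repeated-measures analysis:

```
simulated 52931 calls across 16 rats x 2 test days

drug main effect on post-amphetamine counts (10-min bins):
  Flat   F(1,14) =    2.41,  p = 0.1426
  FM     F(1,14) =   93.72,  p = 0.0000 *
  Trill  F(1,14) =   50.27,  p = 0.0000 *

Trill time course: F(1.06,14.91) = 67.27, p = 5e-07
(Greenhouse-Geisser eps = 0.213, correction applied)
```

The generator suppresses FM and Trill rates by 50 % under CNO while leaving
Flat untouched, and the analysis recovers exactly that pattern: large drug
main effects for FM and Trill, none for Flat (a type-I-error control). The
Time effect's fractional degrees of freedom show the Greenhouse–Geisser
correction at work — binned counts strongly violate sphericity because the
amphetamine surge makes early bins far more variable than late ones.

The other examples each exercise one capability (single-call synthesis,
detection against ground truth, classification confusion matrix, 2-D
embedding); each prints its numbers with a line on what they mean.

## Command line

The same stages are available as a CLI for batch runs over WAV files:

```bash
usvkit all --config config.yaml --outdir runs/demo
```

with subcommands `generate`, `detect`, `features`, `classify`, `stats`,
`embed`. The YAML config must define a `seed`; every output CSV carries a
provenance header (package version, config hash, seed).

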