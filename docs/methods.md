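# Methods

This document records the generative model, the algorithmic conventions
and the numerical choices behind the package, in enough detail to audit
any number the pipeline produces.

## 1. Stimulus design

**Words.** Four trisyllabic consonant–vowel words are synthesized from a
12-consonant × 5-vowel inventory. Two words carry a phonological cue —
vowel harmony (same vowel in all three syllables) or consonant harmony
(same consonant) — and two are uncued. All 12 syllables across the four
words are distinct, so syllable identity alone distinguishes words.
Synthesis is rejection sampling over random syllable draws until the
harmony and distinctness constraints hold.

**Stream.** The familiarization stream presents each word 24 times (96
word events) in strict alternation between object words (accompanied by
a face picture) and action words (accompanied by a head-gesture video).
Audio timing is 170 ms per syllable plus a 286 ms inter-syllable gap:
3 × (170 + 286) = 1368 ms per word and 131,328 ms of stream.

**Exact transitional probabilities.** The design targets are: syllable TP
1 within words, 0.5 between words; word-to-word TP 0.5; image-to-image TP
0.5. A linear 96-event sequence cannot balance all 8 permitted word
transitions in 95 slots, so TPs are computed *circularly* (the final event
is treated as preceding the first) and the sequence is built as a random
Eulerian circuit:

- when the repetition count is a multiple of 8 (default 24), the circuit
  is drawn on the *pair-type* multigraph whose nodes are
  (object word, action word) pairs, with equal parallel edges between
  every ordered node pair — this balances second-order structure and
  makes the image TP exactly 0.5 as well;
- for other even counts a word-level Eulerian circuit is used (word and
  syllable TPs exact; image TP only approximate), and odd counts are
  rejected.

Circuits are sampled by Hierholzer's algorithm over randomly shuffled
adjacency lists, so every run yields a fresh admissible ordering.

**Test schedule.** 16 trials, 8 per tested word, each word's trials
side-balanced (4 correct-left, 4 correct-right), with no more than two
consecutive trials sharing a word or a side (rejection shuffling). The
trial timeline puts lateral-image onset at t = 0 synchronized with the
second word presentation; the third presentation starts at 2368 ms and
the trial ends at 4700 ms. Three counterbalancing versions permute the
word–image pairings deterministically.

## 2. Gaze simulator

Gaze is generated at 50 Hz (20 ms samples) from an episode-level model
per trial:

1. an initial central fixation (the QC requirement is that gaze be
   centered just before image onset);
2. after a lognormal latency (mean 700 ms, sd 250 ms by default), a
   sequence of fixation episodes with lognormal durations (mean 700 ms,
   sd 450 ms). Each episode targets the correct image with probability
   `theta` — the single ground-truth learning parameter — otherwise the
   incorrect image, with occasional refixations through center;
3. episodes are separated by 40 ms saccade gaps, rasterized to samples
   with linear interpolation across gaps;
4. measurement noise: per-episode centroid jitter (sd 15 px), per-sample
   noise (sd 3 px), and missing samples (probability 0.05) written as
   invalid rows;
5. trial-level failure: with probability `p_invalid_trial` the infant is
   looking at a lateral image at onset, so the trial fails QC — this is
   what produces realistic valid-trial counts (≈ 8–9 of 16).

Cohorts draw per-infant parameters (theta, latency, invalid-trial rate
from a Beta distribution, engagement, age ≈ 8 ± 0.4 months) from a
`CohortSpec`, optionally with fussy drop-outs that truncate recordings.
Familiarization viewing is simulated at the sample level with a Bernoulli
engagement parameter and an eyes-vs-mouth split on the face.

The simulator is deliberately *episode-level*, not an oculomotor model:
it produces gaze with the statistical structure the analysis consumes
(fixation-like plateaus, saccadic gaps, tracker dropout), not realistic
velocity profiles. Pupillometry, smooth pursuit, head movement and
calibration drift are out of scope.

## 3. Fixation detection and AOIs

I-DT with dispersion D = (max x − min x) + (max y − min y) ≤ 30 px and
minimum duration 100 ms (5 samples; a fixation's duration is
n_samples × 20 ms). Windows are greedy-maximal: a window grows while D
stays under threshold, is emitted if long enough, and the scan resumes
after it. A single invalid sample inside a run is bridged by linear
interpolation; gaps of two or more samples split runs. The implementation
is incremental (running min/max) and is tested for exact equivalence
against an exhaustive brute-force oracle that recomputes dispersion from
scratch for every candidate window.

AOIs on the 1024 × 768 screen are half-open rectangles: left image
[0, 380) × [209, 559), center strip [380, 644) × [0, 768), right image
[644, 1024) × [209, 559). The familiarization stimulus is a 550 × 580
region centered on screen with eyes and mouth bands.

## 4. Quality control

A test trial is valid when at least 50% of the valid samples in
[−100, 0) ms lie in the center AOI (no data at all ⇒ invalid, reason
`no_data`). An infant is analyzed when at least 5 of 16 trials are valid.
Familiarization engagement (TLT-pct) is time on stimulus divided by the
full stream duration.

## 5. Analysis window

For each valid trial, lateralization is coded 1/0 per 20 ms grid point
(−500 to 4700 ms, 261 points) for gaze on either lateral image, then
averaged per infant. At each time point a right-tailed one-sample t-test
compares the infant means to 0.98 at alpha 0.01; a zero-variance column
counts as significant iff its mean exceeds 0.98. The window runs from the
earliest time ≥ 0 at which significance is sustained through 4700 ms.
Metrics require a window, so when no sustained run exists — the usual case
for realistic noisy cohorts, since near-ceiling lateralization is rarely
sustained — the pipeline falls back to a fixed onset (default 1060 ms).
The data-driven rule itself is validated on fully lateralized simulated
cohorts, where it recovers the true latency within one grid step.

## 6. Metrics

Within the analysis window, per trial:

- **TLT** — total looking time per image: summed fixation durations
  clipped to the window;
- **LF** — longest single (clipped) fixation per image;
- **TLT-p / LF-p** — correct-image proportions (null when both sides are
  zero);
- **TLT-acc / LF-acc** — binarized proportions; exact ties are null
  rather than forced to either side;
- **FG** — 1/0 for whether the first lateral fixation *with onset inside
  the window* targets the correct image; pre-window fixations never
  define FG.

Infant summaries average each metric over the trials where it is
defined; the valid-trial count is unaffected by metric nullity.

## 7. Group statistics

- One-sample two-sided t-tests of each infant-mean metric against 0.5,
  with Cohen's d = t/√n (equivalently (mean − 0.5)/sd). This convention
  reproduces printed pairs such as t = 2.389, n = 23 → d = 0.50 and
  t = 3.607, n = 21 → d = 0.79.
- Paired t-test of correct vs incorrect TLT; both d conventions
  (difference-sd and averaged-sd denominators) are implemented.
- 2×2 between-subjects ANOVA (phonemic cue × word type) with Type-II sums
  of squares (Type III available) and partial eta squared
  SS/(SS + SS_error); with group sizes 23/21/20/23 the error df is 83.
  Numerically null sums of squares (≤ 1e−12 of the total) are reported as
  exactly zero effects. ANCOVA adds age as a covariate and falls back to
  the ANOVA with a warning when the covariate is constant.
- Pearson correlations of the metrics with age, engagement and
  valid-trial counts; Holm step-down adjustment across metric families;
  Shapiro–Wilk as a diagnostic; Pearson chi-square without continuity
  correction for count comparisons.

## 8. Calibration

`rejection_rate` replicates the full pipeline (simulation → fixations →
QC → metrics → t-test) over fresh cohorts. At theta = 0.5 with n = 23 and
200 replicates the TLT-p test rejects at the nominal 5% level (observed
0.05 with seed 1); at theta = 0.65 power is effectively 1.0, and the
grand-mean TLT-p estimate tracks theta to within ~0.005 — the metric is
an approximately unbiased estimator of the episode-targeting probability
because episode durations are i.i.d. across targets.

## 9. Problem sizes and runtime

Defaults are chosen so the whole suite runs on one CPU in minutes: one
experiment (23 infants × 16 trials, ~0.2 s), 200-replicate calibrations
(~45 s each), the 100-trace I-DT oracle comparison (~1 s). All
randomness flows through `numpy.random.default_rng` seeds below 2³¹, and
every reported quantity is reproducible from a single `--seed`.
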