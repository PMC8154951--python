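# lexigaze

An end-to-end pipeline for infant preferential-looking experiments on
audiovisual word learning: statistically constrained stimulus design, a
synthetic 50 Hz gaze simulator, fixation detection, trial quality control,
a data-driven analysis window, and the looking-time metrics and group
statistics used to test learning.

In the paradigm this package models, infants hear a continuous stream of
four trisyllabic nonsense words. Each word reliably co-occurs with a visual
stimulus — a woman's face picture ("object words") or a head-gesture video
("action words") — while transitional probabilities (TPs) are the only cue
to word boundaries: syllable TP is 1 within words and 0.5 between words,
and each word predicts its image perfectly while images predict each other
at 0.5. Learning is then assessed with a two-image preferential-looking
test: the infant hears one word while the two candidate images appear left
and right, and longer looking at the matching image indicates learning.

## What is in the box

| Module | Purpose |
| --- | --- |
| `lexigaze.design` | Word synthesis with vowel/consonant harmony, Eulerian-balanced familiarization streams with exact TPs, and counterbalanced 16-trial test schedules |
| `lexigaze.simulate` | Episode-level synthetic gaze: latency, fixation episodes, refixations, saccade gaps, tracker noise, missing samples, fussiness and drop-out |
| `lexigaze.fixation` | I-DT dispersion-threshold fixation detection (30 px / 100 ms) and AOI assignment on a 1024×768 screen |
| `lexigaze.qc` | Trial validity (gaze centered just before image onset), infant inclusion (≥ 5 of 16 valid trials), familiarization engagement |
| `lexigaze.windowing` | Per-infant lateralization time courses and the pointwise-t sustained-significance rule that finds the analysis window |
| `lexigaze.metrics` | Per-trial TLT, LF and FG metrics, proportions and accuracies, per-infant means |
| `lexigaze.stats` | Chance-level t-tests with d = t/√n, paired tests, 2×2 between-subjects ANOVA/ANCOVA with partial eta squared, correlations, Holm adjustment |
| `lexigaze.pipeline` | `run_experiment` (one full experiment) and `rejection_rate` (replicate calibration) |

## Worked example

```python
import lexigaze as lg

design = lg.default_design("vowel", "action", rng_seed=0)
res = lg.run_experiment(design, lg.CohortSpec(theta_mean=0.65), 23, seed=42)

t = res.chance_tests["mean_tlt_p"]
print(res.n_analyzed, res.window.start_ms, res.window.end_ms)
print(f"TLT-p: mean {t.mean:.3f}, t({t.df}) = {t.t:.3f}, "
      f"p = {t.p:.2e}, d = {t.cohens_d:.3f}")
```

prints

```
18 1060.0 4700.0
TLT-p: mean 0.650, t(17) = 5.588, p = 3.26e-05, d = 1.317
```

— of 23 enrolled simulated infants, 18 pass quality control (the rest have
fewer than 5 valid trials), and the proportion of total looking time on the
correct image is above chance, close to the simulated ground-truth
preference of 0.65.

There is also a CLI:

```bash
lexigaze stimgen --seed 1 --out-dir out/          # stream + test trials
lexigaze simulate --seed 1 --n-infants 23 --out-dir out/gaze
lexigaze fixations --gaze out/gaze/inf000.csv --out out/fix000.csv
lexigaze run-all --n-infants 23 --theta 0.65 --seed 1 --out out/report.json
```

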