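"""Compute the looking-time metrics inside the analysis window and run the
group-level statistics.

Reads the gaze CSVs and the window report from the earlier scripts.  For
the cross-experiment ANOVA the script simulates a companion cohort with the
complementary cue/word-type cell so the 2x2 factorial has data in more
than one cell; with real data this table would be assembled from the four
experiments directly.

Writes results/stats/{infant_summaries.csv,chance_tests.csv,anova.csv,
ancova.csv,correlations.csv}.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from _common import RESULTS, design_and_schedule, load_recordings

import lexigaze as lg
from lexigaze.stats import (
    CHANCE_METRICS,
    ancova,
    correlations,
    multiple_comparison_adjust,
    one_sample_test,
    paired_test,
    two_way_anova,
)
from lexigaze.windowing import AnalysisWindow


def summaries_for(recordings, schedule, aois, window, design, ages) -> pd.DataFrame:
    cued = design.word(design.cued_words[0])
    out = []
    for rec in recordings:
        validities, valid = [], []
        for trial in schedule.trials:
            samples = rec.trials.get(trial.index)
            if samples is None:
                continue
            tv = lg.validate_trial(samples, aois, trial_id=trial.index)
            validities.append(tv)
            if tv.valid:
                valid.append((trial, samples))
        included, _ = lg.include_infant(validities)
        if not included:
            continue
        tms = [
            lg.trial_metrics(lg.idt_fixations(s, aois=aois), trial, window)
            for trial, s in valid
        ]
        out.append(
            lg.infant_summary(
                tms, infant_id=rec.infant_id,
                age_months=float(ages.get(rec.infant_id, float("nan"))),
                phonemic_cue=cued.harmony, word_type=cued.word_role,
            )
        )
    return lg.summaries_frame(out)


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--gaze-dir", type=Path, default=RESULTS / "gaze")
    ap.add_argument("--window-json", type=Path,
                    default=RESULTS / "window" / "window.json")
    ap.add_argument("--out-dir", type=Path, default=RESULTS / "stats")
    args = ap.parse_args()

    design, schedule = design_and_schedule(args.seed)
    aois = lg.default_test_aois()

    w = json.loads(args.window_json.read_text())
    start = w["start_ms"] if w["found"] else w["fallback_start_ms"]
    window = AnalysisWindow(float(start), float(w["end_ms"]))

    truth = pd.read_csv(args.gaze_dir / "ground_truth.csv")
    ages = dict(zip(truth["infant_id"], truth["age_months"]))
    recordings = load_recordings(args.gaze_dir)
    sdf = summaries_for(recordings, schedule, aois, window, design, ages)

    # chance tests with Holm adjustment across the five metrics
    rows = []
    for m in CHANCE_METRICS:
        r = one_sample_test(sdf[m].dropna(), mu0=0.5)
        rows.append({"metric": m, "mean": r.mean, "t": r.t, "df": r.df,
                     "p": r.p, "cohens_d": r.cohens_d, "n": r.n})
    cdf = pd.DataFrame(rows)
    cdf["p_holm"] = multiple_comparison_adjust(cdf["p"])
    pt = paired_test(sdf["mean_tlt_correct_ms"], sdf["mean_tlt_incorrect_ms"])

    # companion cohorts in the three remaining 2x2 cells so the factorial
    # table is complete (with real data these would be the other experiments)
    import numpy as np

    rng = np.random.default_rng(args.seed + 1)
    frames = [sdf]
    done = {(design.word(design.cued_words[0]).harmony,
             design.word(design.cued_words[0]).word_role)}
    for harmony in ("vowel", "consonant"):
        for role in ("action", "object"):
            if (harmony, role) in done:
                continue
            comp_design = lg.default_design(harmony, role,
                                            rng_seed=int(rng.integers(2**31)))
            comp = lg.run_experiment(
                comp_design, lg.CohortSpec(theta_mean=0.60), len(recordings),
                seed=int(rng.integers(2**31)), window_strategy="fixed",
                fallback_window_start_ms=window.start_ms,
            )
            comp_sdf = comp.summaries.copy()
            comp_sdf["infant_id"] = (
                f"{harmony[0]}{role[0]}_" + comp_sdf["infant_id"].astype(str)
            )
            frames.append(comp_sdf)
    both = pd.concat(frames, ignore_index=True)

    an = two_way_anova(both, "mean_tlt_p")
    anc = ancova(both, "mean_tlt_p")
    corr = correlations(sdf, "age_months")

    args.out_dir.mkdir(parents=True, exist_ok=True)
    sdf.to_csv(args.out_dir / "infant_summaries.csv", index=False)
    cdf.to_csv(args.out_dir / "chance_tests.csv", index=False)
    an.to_csv(args.out_dir / "anova.csv")
    anc.to_csv(args.out_dir / "ancova.csv")
    corr.to_csv(args.out_dir / "correlations.csv")

    print(f"{len(sdf)} infants analyzed; window "
          f"{window.start_ms:.0f}-{window.end_ms:.0f} ms")
    for _, r in cdf.iterrows():
        print(f"  {r['metric']}: mean {r['mean']:.3f}, "
              f"t({int(r['df'])}) = {r['t']:.3f}, p = {r['p']:.4f}, "
              f"d = {r['cohens_d']:.3f}, p_holm = {r['p_holm']:.4f}")
    print(f"  paired TLT correct vs incorrect: t({pt.df}) = {pt.t:.3f}, "
          f"p = {pt.p:.4f}")
    print(f"wrote tables to {args.out_dir}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
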