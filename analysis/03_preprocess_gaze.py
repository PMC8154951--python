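"""Detect fixations and apply trial / infant quality control to the raw
gaze CSVs produced by 02_simulate_cohort.py.

Writes results/preprocessed/{fixations.csv,trial_qc.csv,infant_qc.csv}.
"""

import argparse
from pathlib import Path

import pandas as pd

from _common import RESULTS, design_and_schedule, load_recordings

import lexigaze as lg
from lexigaze.io import fixations_frame, qc_frame


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1,
                    help="seed used for 02_simulate_cohort.py (reconstructs the schedule)")
    ap.add_argument("--gaze-dir", type=Path, default=RESULTS / "gaze")
    ap.add_argument("--min-valid-trials", type=int, default=5)
    ap.add_argument("--out-dir", type=Path, default=RESULTS / "preprocessed")
    args = ap.parse_args()

    _, schedule = design_and_schedule(args.seed)
    aois = lg.default_test_aois()
    recordings = load_recordings(args.gaze_dir)

    fix_by_infant: dict[str, dict[int, list]] = {}
    val_by_infant: dict[str, list] = {}
    infant_rows = []
    for rec in recordings:
        validities = []
        fixs: dict[int, list] = {}
        for trial in schedule.trials:
            samples = rec.trials.get(trial.index)
            if samples is None:
                continue
            tv = lg.validate_trial(samples, aois, trial_id=trial.index)
            validities.append(tv)
            if tv.valid:
                fixs[trial.index] = lg.idt_fixations(samples, aois=aois)
        included, n_valid = lg.include_infant(validities, args.min_valid_trials)
        fix_by_infant[rec.infant_id] = fixs
        val_by_infant[rec.infant_id] = validities
        infant_rows.append(
            {"infant_id": rec.infant_id, "n_valid_trials": n_valid,
             "included": included}
        )

    args.out_dir.mkdir(parents=True, exist_ok=True)
    fix_frames = [
        fixations_frame(fixs, iid, tid)
        for iid, by_trial in fix_by_infant.items()
        for tid, fixs in sorted(by_trial.items())
        if fixs
    ]
    fdf = (pd.concat(fix_frames, ignore_index=True) if fix_frames
           else pd.DataFrame())
    fdf.to_csv(args.out_dir / "fixations.csv", index=False)
    qc_frame(val_by_infant).to_csv(args.out_dir / "trial_qc.csv", index=False)
    idf = pd.DataFrame(infant_rows)
    idf.to_csv(args.out_dir / "infant_qc.csv", index=False)

    print(f"{len(recordings)} infants; "
          f"{int(idf['included'].sum())} pass QC "
          f"(mean valid trials {idf['n_valid_trials'].mean():.1f})")
    print(f"wrote fixations.csv, trial_qc.csv, infant_qc.csv to {args.out_dir}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
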