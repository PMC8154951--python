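"""Simulate a cohort of infants viewing the test trials (and optionally the
familiarization stream) and write the raw 50 Hz gaze samples to CSV.

Reads results/design/test_trials.json (run 01_design_stimuli.py first) if
present; otherwise regenerates the design from the seed.  Writes one gaze
CSV per infant plus ground_truth.csv under results/gaze/.
"""

import argparse
from pathlib import Path

import numpy as np

from _common import RESULTS, design_and_schedule  # noqa: F401

import lexigaze as lg
from lexigaze.io import write_gaze_csv
from lexigaze.simulate import CohortSpec


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-infants", type=int, default=23)
    ap.add_argument("--theta", type=float, default=0.65,
                    help="cohort-mean probability that a look targets the correct image")
    ap.add_argument("--familiarization", action="store_true")
    ap.add_argument("--out-dir", type=Path, default=RESULTS / "gaze")
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    design, schedule = design_and_schedule(args.seed)
    rng.integers(2**31)  # keep the draw chain aligned with design_and_schedule
    rng.integers(2**31)
    aois = lg.default_test_aois()
    stream = None
    fam_aois = None
    if args.familiarization:
        seq = lg.build_familiarization_sequence(design, rng_seed=int(rng.integers(2**31)))
        stream = lg.schedule_stream(seq, design)
        fam_aois = lg.default_familiarization_aois()

    cohort = CohortSpec(theta_mean=args.theta)
    recordings, truth = lg.simulate_cohort(
        args.n_infants, cohort, schedule, aois,
        seed=int(rng.integers(2**31)), stream=stream,
        familiarization_aois=fam_aois,
    )

    args.out_dir.mkdir(parents=True, exist_ok=True)
    n_written = 0
    for rec in recordings:
        if rec.dropped:
            continue
        write_gaze_csv(rec, args.out_dir / f"{rec.infant_id}.csv")
        n_written += 1
    truth.to_csv(args.out_dir / "ground_truth.csv", index=False)
    (args.out_dir / "test_trials.json").write_text(schedule.to_json())

    print(f"simulated {args.n_infants} infants "
          f"({sum(r.dropped for r in recordings)} fussy drop-outs)")
    print(f"wrote {n_written} gaze CSVs + ground_truth.csv to {args.out_dir}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
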