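"""Find the data-driven analysis window from the lateralization time
courses of QC-passing trials.

Per valid trial, gaze is coded 1/0 at each 20 ms point for being on a
lateral image; per-infant averages are tested pointwise (right-tailed t
against 0.98, alpha 0.01) and the window runs from the earliest sustained
onset to trial end (4700 ms).  If no sustained run exists, the report says
so and downstream metrics fall back to the fixed onset given here.

Writes results/window/{window.json,timecourse.csv}.
"""

import argparse
from pathlib import Path

import pandas as pd

from _common import RESULTS, design_and_schedule, load_recordings

import lexigaze as lg
from lexigaze.io import write_json
from lexigaze.windowing import timecourse_grid


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--gaze-dir", type=Path, default=RESULTS / "gaze")
    ap.add_argument("--mu0", type=float, default=0.98)
    ap.add_argument("--alpha", type=float, default=0.01)
    ap.add_argument("--fallback-start-ms", type=float, default=1060.0)
    ap.add_argument("--out-dir", type=Path, default=RESULTS / "window")
    args = ap.parse_args()

    _, schedule = design_and_schedule(args.seed)
    aois = lg.default_test_aois()
    grid = timecourse_grid()

    tcs = {}
    for rec in load_recordings(args.gaze_dir):
        rows = []
        for trial in schedule.trials:
            samples = rec.trials.get(trial.index)
            if samples is None:
                continue
            if lg.validate_trial(samples, aois).valid:
                rows.append(lg.lateralization_timecourse(samples, aois))
        if rows:
            tcs[rec.infant_id] = rows

    matrix = lg.build_lateralization_matrix(tcs, grid)
    pvals, mask = lg.pointwise_test(matrix, mu0=args.mu0, alpha=args.alpha)
    window = lg.find_window(mask, grid, pointwise_p=pvals)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "found": window.found,
        "start_ms": window.start_ms,
        "end_ms": window.end_ms,
        "mu0": args.mu0,
        "alpha": args.alpha,
        "n_infants": len(matrix.infant_ids),
        "diagnostics": window.diagnostics,
    }
    if not window.found:
        payload["fallback_start_ms"] = args.fallback_start_ms
    write_json(payload, args.out_dir / "window.json")
    pd.DataFrame(
        {"time_ms": grid, "mean_lateralization": matrix.values.mean(axis=0),
         "p": pvals, "significant": mask.astype(int)}
    ).to_csv(args.out_dir / "timecourse.csv", index=False)

    if window.found:
        print(f"window: {window.start_ms:.0f}-{window.end_ms:.0f} ms")
    else:
        print(f"no sustained window; fall back to "
              f"{args.fallback_start_ms:.0f}-{grid[-1]:.0f} ms")
    print(f"wrote window.json, timecourse.csv to {args.out_dir}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
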