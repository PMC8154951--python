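"""Shared helpers for the numbered analysis scripts.

The scripts form a pipeline over results/: 01 designs stimuli, 02 simulates
gaze, 03 detects fixations and applies QC, 04 finds the analysis window,
05 computes metrics and group statistics.  All of them derive the design
and test schedule deterministically from the same --seed so that later
stages can reconstruct them without re-reading earlier outputs.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

import numpy as np  # noqa: E402

import lexigaze as lg  # noqa: E402

RESULTS = ROOT / "results"


def design_and_schedule(seed: int):
    """Design + test schedule derived from the run seed (same chain as 02)."""
    rng = np.random.default_rng(seed)
    design = lg.default_design(rng_seed=int(rng.integers(2**31)))
    schedule = lg.build_test_trials(design, rng_seed=int(rng.integers(2**31)))
    return design, schedule


def load_recordings(gaze_dir: Path):
    """Read every per-infant gaze CSV under ``gaze_dir``."""
    from lexigaze.io import read_gaze_table, recording_from_frame

    recs = []
    for path in sorted(gaze_dir.glob("inf*.csv")):
        recs.append(recording_from_frame(read_gaze_table(path)))
    if not recs:
        raise SystemExit(
            f"no gaze CSVs in {gaze_dir}; run analysis/02_simulate_cohort.py first"
        )
    return recs
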