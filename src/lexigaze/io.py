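"""Readers and writers for the package's plain-text interchange formats.

Gaze exports use the canonical dialect
``infant_id, phase, trial_id, time_ms, x_px, y_px, valid`` — comma- or
tab-separated; invalid samples keep their row with ``valid = 0`` and empty
coordinates, matching real tracker exports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fixation import Fixation
from .qc import TrialValidity
from .simulate import GazeRecording

GAZE_COLUMNS = ["infant_id", "phase", "trial_id", "time_ms", "x_px", "y_px", "valid"]


def write_gaze_csv(recording: GazeRecording, path: str | Path, sep: str = ",") -> Path:
    path = Path(path)
    df = recording.to_frame()[GAZE_COLUMNS]
    df.to_csv(path, sep=sep, index=False, float_format="%.2f")
    return path


def read_gaze_table(path: str | Path) -> pd.DataFrame:
    """Read a gaze export, sniffing comma vs tab separation."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze table missing columns: {missing}")
    df["valid"] = df["valid"].astype(int)
    return df


def recording_from_frame(df: pd.DataFrame) -> GazeRecording:
    """Rebuild a per-trial recording from a long-format gaze table."""
    iid = str(df["infant_id"].iloc[0])
    trials = {}
    test = df[df["phase"] == "test"]
    for tid, g in test.groupby("trial_id"):
        trials[int(tid)] = {
            "time_ms": g["time_ms"].to_numpy(float),
            "x_px": g["x_px"].to_numpy(float),
            "y_px": g["y_px"].to_numpy(float),
            "valid": g["valid"].to_numpy(int),
        }
    fam = df[df["phase"] == "familiarization"]
    familiarization = None
    if len(fam):
        familiarization = {
            "time_ms": fam["time_ms"].to_numpy(float),
            "x_px": fam["x_px"].to_numpy(float),
            "y_px": fam["y_px"].to_numpy(float),
            "valid": fam["valid"].to_numpy(int),
        }
    return GazeRecording(infant_id=iid, trials=trials, familiarization=familiarization)


def fixations_frame(
    fixations: list[Fixation], infant_id: str, trial_id: int
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "infant_id": infant_id,
                "trial_id": trial_id,
                "onset_ms": f.onset_ms,
                "offset_ms": f.offset_ms,
                "x": f.x,
                "y": f.y,
                "n_samples": f.n_samples,
                "aoi": f.aoi,
            }
            for f in fixations
        ]
    )


def qc_frame(validities_by_infant: dict[str, list[TrialValidity]]) -> pd.DataFrame:
    rows = []
    for iid, vs in validities_by_infant.items():
        for v in vs:
            rows.append(
                {"infant_id": iid, "trial_id": v.trial_id, "valid": int(v.valid),
                 "reason": v.reason}
            )
    return pd.DataFrame(rows)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, default=default))
    return path
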