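"""Per-trial and per-infant looking-time metrics inside the analysis window.

For each valid trial the fixations falling (after clipping) into the
analysis window yield:

* **TLT** — total looking time per lateral image (sum of clipped fixation
  durations), with proportion ``tlt_p = TLT_correct / (TLT_correct +
  TLT_incorrect)`` and the per-trial binarization ``tlt_acc`` (1 when the
  correct image got more looking, 0 when less, undefined on ties);
* **LF** — the longest single clipped fixation per image, with ``lf_p``
  and ``lf_acc`` defined the same way;
* **FG** — whether the first lateral fixation beginning at or after the
  window onset targeted the correct image.

Infant summaries are arithmetic means over the non-null trial values, and
all group-level inference runs on those infant means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TestTrial
from .fixation import Fixation, LATERAL_AOIS
from .windowing import AnalysisWindow

__all__ = ["TrialMetrics", "InfantSummary", "trial_metrics", "infant_summary"]

METRIC_FIELDS = ("fg", "tlt_p", "tlt_acc", "lf_p", "lf_acc",
                 "tlt_correct_ms", "tlt_incorrect_ms", "lf_correct_ms", "lf_incorrect_ms")


@dataclass
class TrialMetrics:
    trial_id: int
    fg: float | None
    tlt_correct_ms: float
    tlt_incorrect_ms: float
    lf_correct_ms: float
    lf_incorrect_ms: float
    tlt_p: float | None
    lf_p: float | None
    tlt_acc: float | None
    lf_acc: float | None


def _proportion(c: float, i: float) -> float | None:
    tot = c + i
    return c / tot if tot > 0 else None


def _acc(p: float | None) -> float | None:
    if p is None or p == 0.5:  # ties are undefined, not zero
        return None
    return 1.0 if p > 0.5 else 0.0


def trial_metrics(
    fixations: list[Fixation],
    trial: TestTrial,
    window: AnalysisWindow,
    first_gaze_from: str = "fixation",
) -> TrialMetrics:
    """Looking-time metrics for one valid trial.

    Fixations must be AOI-labelled trial-relative (t = 0 at image onset);
    they are clipped to [window.start_ms, window.end_ms] before summing.
    """
    if not window.found:
        raise ValueError("analysis window was not found; cannot compute metrics")
    w0, w1 = window.start_ms, window.end_ms
    correct_aoi = "left_image" if trial.correct_side == "left" else "right_image"

    tlt = {a: 0.0 for a in LATERAL_AOIS}
    lf = {a: 0.0 for a in LATERAL_AOIS}
    fg: float | None = None
    for f in sorted(fixations, key=lambda f: f.onset_ms):
        if f.aoi not in LATERAL_AOIS:
            continue
        clipped = max(0.0, min(f.offset_ms, w1) - max(f.onset_ms, w0))
        if clipped > 0:
            tlt[f.aoi] += clipped
            lf[f.aoi] = max(lf[f.aoi], clipped)
        if fg is None and f.onset_ms >= w0 and f.onset_ms < w1:
            fg = 1.0 if f.aoi == correct_aoi else 0.0

    incorrect_aoi = "right_image" if correct_aoi == "left_image" else "left_image"
    tlt_p = _proportion(tlt[correct_aoi], tlt[incorrect_aoi])
    lf_p = _proportion(lf[correct_aoi], lf[incorrect_aoi])
    return TrialMetrics(
        trial_id=trial.index,
        fg=fg,
        tlt_correct_ms=tlt[correct_aoi],
        tlt_incorrect_ms=tlt[incorrect_aoi],
        lf_correct_ms=lf[correct_aoi],
        lf_incorrect_ms=lf[incorrect_aoi],
        tlt_p=tlt_p,
        lf_p=lf_p,
        tlt_acc=_acc(tlt_p),
        lf_acc=_acc(lf_p),
    )


@dataclass
class InfantSummary:
    infant_id: str
    age_months: float
    n_valid_trials: int
    mean_fg: float
    mean_tlt_correct_ms: float
    mean_tlt_incorrect_ms: float
    mean_tlt_p: float
    mean_tlt_acc: float
    mean_lf_p: float
    mean_lf_acc: float
    phonemic_cue: str = ""
    word_type: str = ""
    tlt_pct: float = float("nan")

    def as_row(self) -> dict:
        return dict(self.__dict__)


def infant_summary(
    metrics: list[TrialMetrics],
    infant_id: str,
    age_months: float = float("nan"),
    phonemic_cue: str = "",
    word_type: str = "",
    tlt_pct: float = float("nan"),
) -> InfantSummary:
    """Per-infant arithmetic means of each metric over non-null trials."""
    if not metrics:
        raise ValueError("infant has no valid trials")

    def mean_of(attr: str) -> float:
        vals = [getattr(m, attr) for m in metrics if getattr(m, attr) is not None]
        return float(np.mean(vals)) if vals else float("nan")

    return InfantSummary(
        infant_id=infant_id,
        age_months=age_months,
        n_valid_trials=len(metrics),
        mean_fg=mean_of("fg"),
        mean_tlt_correct_ms=mean_of("tlt_correct_ms"),
        mean_tlt_incorrect_ms=mean_of("tlt_incorrect_ms"),
        mean_tlt_p=mean_of("tlt_p"),
        mean_tlt_acc=mean_of("tlt_acc"),
        mean_lf_p=mean_of("lf_p"),
        mean_lf_acc=mean_of("lf_acc"),
        phonemic_cue=phonemic_cue,
        word_type=word_type,
        tlt_pct=tlt_pct,
    )


def summaries_frame(summaries: list[InfantSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in summaries])
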