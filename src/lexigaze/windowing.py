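"""Data-driven identification of the analysis time window.

Each valid trial yields a binary lateralization time course on the 20 ms
grid (1 = gaze on a lateral image).  Trials are averaged within infant;
at every time point the infant means are submitted to a right-tailed
one-sample t-test against 0.98 at alpha = 0.01.  The analysis window
starts at the earliest post-onset time from which significance is
sustained through the trial end (4700 ms).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .fixation import SAMPLE_PERIOD_MS, TIMECOURSE_END_MS, TIMECOURSE_START_MS

__all__ = [
    "LateralizationMatrix",
    "AnalysisWindow",
    "build_lateralization_matrix",
    "pointwise_test",
    "find_window",
    "timecourse_grid",
]


def timecourse_grid(
    t_start: float = TIMECOURSE_START_MS,
    t_end: float = TIMECOURSE_END_MS,
    period: float = SAMPLE_PERIOD_MS,
) -> np.ndarray:
    return np.arange(t_start, t_end + period / 2, period)


@dataclass
class LateralizationMatrix:
    """Per-infant mean lateralization proportion at each time point."""

    values: np.ndarray  # shape (n_infants, n_times), entries in [0, 1]
    times_ms: np.ndarray
    infant_ids: list[str]
    n_valid_trials: dict[str, int]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.infant_ids), self.times_ms.size):
            raise ValueError("matrix shape does not match infants x times")
        if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1:
            raise ValueError("lateralization proportions must lie in [0, 1]")


def build_lateralization_matrix(
    timecourses_by_infant: dict[str, list[np.ndarray]],
    times_ms: np.ndarray | None = None,
) -> LateralizationMatrix:
    """Average each infant's valid-trial binary time courses.

    Infants contributing zero valid trials are dropped with a warning.
    """
    times = timecourse_grid() if times_ms is None else np.asarray(times_ms, float)
    rows, ids, counts = [], [], {}
    for iid, tcs in timecourses_by_infant.items():
        if not tcs:
            warnings.warn(f"infant {iid} has no valid trials; excluded")
            continue
        arr = np.vstack(tcs)
        if arr.shape[1] != times.size:
            raise ValueError(f"infant {iid}: time course length mismatch")
        rows.append(arr.mean(axis=0))
        ids.append(iid)
        counts[iid] = arr.shape[0]
    if not rows:
        raise ValueError("no infants with valid trials")
    return LateralizationMatrix(
        values=np.vstack(rows), times_ms=times, infant_ids=ids, n_valid_trials=counts
    )


def pointwise_test(
    matrix: LateralizationMatrix, mu0: float = 0.98, alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Right-tailed one-sample t-test of the infant means against ``mu0``.

    Returns (p_values, significance_mask) over the time grid.  At
    zero-variance time points the t statistic is undefined; the point is
    declared significant iff the common value exceeds ``mu0`` (the ceiling
    behaviour the procedure is designed to detect), with p set to 0 or 1
    accordingly.
    """
    v = matrix.values
    if v.shape[0] < 2:
        raise ValueError("pointwise test needs at least 2 infants")
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    zero_var = sd == 0.0
    p = np.ones(v.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - mu0) / (sd / np.sqrt(v.shape[0]))
    ok = ~zero_var
    p[ok] = sps.t.sf(t[ok], df=v.shape[0] - 1)
    p[zero_var] = np.where(mean[zero_var] > mu0, 0.0, 1.0)
    return p, p < alpha


@dataclass
class AnalysisWindow:
    """[start_ms, end_ms] interval for the looking-time metrics."""

    start_ms: float | None
    end_ms: float
    pointwise_p: np.ndarray | None = None
    times_ms: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def found(self) -> bool:
        return self.start_ms is not None

    def to_json(self) -> str:
        payload = {
            "start_ms": self.start_ms,
            "end_ms": self.end_ms,
            "diagnostics": self.diagnostics,
        }
        if self.pointwise_p is not None:
            payload["pointwise_p"] = list(map(float, self.pointwise_p))
            payload["times_ms"] = list(map(float, self.times_ms))
        return json.dumps(payload, indent=1)


def find_window(
    mask: np.ndarray,
    times_ms: np.ndarray,
    end_ms: float = TIMECOURSE_END_MS,
    transient_tolerance: int = 0,
    pointwise_p: np.ndarray | None = None,
) -> AnalysisWindow:
    """Earliest post-onset time from which significance is sustained.

    ``start_ms`` is the smallest grid time t >= 0 such that every point of
    [t, end_ms] is significant, allowing at most ``transient_tolerance``
    consecutive non-significant points (default 0: strictly sustained).
    A never-satisfied mask yields a no-window result with diagnostics.
    """
    times = np.asarray(times_ms, float)
    mask = np.asarray(mask, bool)
    in_range = (times >= 0) & (times <= end_ms)
    idx = np.nonzero(in_range)[0]
    start = None
    # scan from the end: find the longest suffix whose gaps never exceed tol
    gap = 0
    for k in reversed(idx):
        if mask[k]:
            gap = 0
            start = float(times[k])
        else:
            gap += 1
            if gap > transient_tolerance:
                break
    diagnostics = {
        "n_significant": int(mask[idx].sum()),
        "n_points": int(idx.size),
        "last_significant_ms": float(times[idx][mask[idx]][-1]) if mask[idx].any() else None,
    }
    if start is None or not mask[idx][-1]:
        # significance must reach the trial end to count as sustained
        return AnalysisWindow(None, end_ms, pointwise_p, times, diagnostics)
    return AnalysisWindow(float(start), end_ms, pointwise_p, times, diagnostics)
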