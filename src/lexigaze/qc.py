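"""Trial-level and infant-level quality control, plus familiarization
engagement metrics.

A test trial is *valid* when the infant's gaze is at the center of the
screen just before lateral-image onset; infants contribute to the analysis
only if they reach a minimum number of valid trials (5 of 16 here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import StreamSpec
from .fixation import AOIConfig, SAMPLE_PERIOD_MS, assign_aoi

__all__ = [
    "TrialValidity",
    "FamiliarizationSummary",
    "validate_trial",
    "include_infant",
    "familiarization_summary",
]


@dataclass(frozen=True)
class TrialValidity:
    trial_id: int
    valid: bool
    reason: str  # "ok" | "not_centered_at_onset" | "no_data"

    def __post_init__(self) -> None:
        if self.valid and self.reason != "ok":
            raise ValueError("a valid trial must have reason 'ok'")


def validate_trial(
    samples,
    aois: AOIConfig,
    trial_id: int = 0,
    pre_onset_window_ms: float = 100.0,
    min_center_fraction: float = 0.5,
) -> TrialValidity:
    """Center-at-onset check over the pre-onset window [-w, 0).

    Valid iff at least ``min_center_fraction`` of the *valid* samples in
    the window lie in the center AOI; a window with no valid samples gives
    ``no_data``.
    """
    t = np.asarray(samples["time_ms"], dtype=float)
    x = np.asarray(samples["x_px"], dtype=float)
    y = np.asarray(samples["y_px"], dtype=float)
    valid = np.asarray(samples["valid"]).astype(bool)
    sel = (t >= -pre_onset_window_ms) & (t < 0) & valid
    if not sel.any():
        return TrialValidity(trial_id, False, "no_data")
    x0, y0, x1, y1 = aois["center"]
    with np.errstate(invalid="ignore"):
        centered = (x[sel] >= x0) & (x[sel] < x1) & (y[sel] >= y0) & (y[sel] < y1)
    if centered.mean() >= min_center_fraction:
        return TrialValidity(trial_id, True, "ok")
    return TrialValidity(trial_id, False, "not_centered_at_onset")


def include_infant(
    validities: list[TrialValidity], min_valid_trials: int = 5
) -> tuple[bool, int]:
    """Inclusion flag and valid-trial count for one infant."""
    n_valid = sum(v.valid for v in validities)
    return n_valid >= min_valid_trials, n_valid


@dataclass(frozen=True)
class FamiliarizationSummary:
    tlt_pct: float  # % of the stream duration with gaze on the stimulus
    eyes_pct: float  # % of on-face time in the eyes AOI
    mouth_pct: float  # % of on-face time in the mouth AOI


def familiarization_summary(
    samples, stream: StreamSpec, aois: AOIConfig
) -> FamiliarizationSummary:
    """Engagement with the stimulus over the whole familiarization stream.

    The denominator of ``tlt_pct`` is the full stream duration (total
    expected samples at 50 Hz), so looking away and tracker loss both count
    against engagement.  Eyes/mouth percentages are taken over on-face
    samples only.
    """
    if stream.total_duration_ms <= 0:
        raise ValueError("zero-duration stream")
    n_expected = int(stream.total_duration_ms // SAMPLE_PERIOD_MS)
    t = np.asarray(samples["time_ms"], dtype=float)
    x = np.asarray(samples["x_px"], dtype=float)
    y = np.asarray(samples["y_px"], dtype=float)
    valid = np.asarray(samples["valid"]).astype(bool)
    sel = valid & (t >= 0) & (t < stream.total_duration_ms)

    def inside(name: str) -> np.ndarray:
        x0, y0, x1, y1 = aois[name]
        with np.errstate(invalid="ignore"):
            return sel & (x >= x0) & (x < x1) & (y >= y0) & (y < y1)

    stim_name = "stimulus" if "stimulus" in aois else "screen"
    on_face = inside(stim_name)
    n_face = int(on_face.sum())
    tlt_pct = 100.0 * n_face / n_expected
    if n_face == 0:
        return FamiliarizationSummary(tlt_pct, float("nan"), float("nan"))
    eyes = inside("eyes") & on_face if "eyes" in aois else np.zeros_like(on_face)
    mouth = inside("mouth") & on_face if "mouth" in aois else np.zeros_like(on_face)
    return FamiliarizationSummary(
        tlt_pct=tlt_pct,
        eyes_pct=100.0 * float(eyes.sum()) / n_face,
        mouth_pct=100.0 * float(mouth.sum()) / n_face,
    )
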