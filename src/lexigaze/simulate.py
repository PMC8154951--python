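"""Synthetic infant gaze generator.

Emulates a 50 Hz remote eye-tracker recording of an infant on a 1024x768
screen across a familiarization stream and 16 preferential-looking test
trials.  Gaze is generated at the level of *look episodes* (fixation bouts
with lognormal durations), not independent samples, which preserves the
autocorrelated structure of real infant gaze: per-sample preference noise
would understate trial-to-trial variance and inflate apparent power.

Ground-truth parameters (the per-infant preference ``theta`` above all) are
recorded so that downstream estimates can be checked against what was
actually simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DesignConfig, StreamSpec, TestTrial, TestTrialSchedule
from .fixation import (
    AOIConfig,
    SAMPLE_PERIOD_MS,
    TIMECOURSE_END_MS,
    TIMECOURSE_START_MS,
)

__all__ = [
    "InfantProfile",
    "CohortSpec",
    "GazeRecording",
    "simulate_trial",
    "simulate_familiarization",
    "simulate_cohort",
    "expected_tlt_p",
]


def _lognorm_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and sd."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    var = sd * sd
    sigma2 = math.log(1.0 + var / (mean * mean))
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass
class InfantProfile:
    """Generative parameters for one simulated infant.

    ``preference_theta`` is the probability that any lateral look episode
    targets the correct image (0.5 = no learning).  Latency and episode
    durations are lognormal, parameterized by their arithmetic mean/sd in
    ms.  ``p_invalid_trial`` is the probability that the infant is not
    centered at lateral-image onset, which fails the trial downstream.
    """

    infant_id: str = "inf00"
    age_months: float = 8.0
    preference_theta: float = 0.55
    center_latency_mean_ms: float = 700.0
    center_latency_sd_ms: float = 250.0
    fixation_dur_mean_ms: float = 700.0
    fixation_dur_sd_ms: float = 450.0
    refixation_rate: float = 0.15
    p_missing_sample: float = 0.05
    p_invalid_trial: float = 0.45
    engagement_familiarization: float = 0.68
    p_eyes_region: float = 0.88
    fussiness_dropout: float = 0.0
    centroid_jitter_sd_px: float = 15.0
    sample_noise_sd_px: float = 3.0
    saccade_gap_ms: float = 40.0

    def __post_init__(self) -> None:
        for name in (
            "preference_theta",
            "refixation_rate",
            "p_missing_sample",
            "p_invalid_trial",
            "engagement_familiarization",
            "p_eyes_region",
            "fussiness_dropout",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("center_latency_mean_ms", "fixation_dur_mean_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _aoi_anchor(aois: AOIConfig, name: str, rng: np.random.Generator, jitter_sd: float):
    """Episode anchor: AOI center plus Gaussian jitter, clipped inside."""
    x0, y0, x1, y1 = aois[name]
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    m = 25.0  # keep anchors away from edges so sample noise stays inside
    ax = np.clip(cx + rng.normal(0, jitter_sd), x0 + m, x1 - m)
    ay = np.clip(cy + rng.normal(0, jitter_sd), y0 + m, y1 - m)
    return float(ax), float(ay)


def simulate_trial(
    profile: InfantProfile,
    trial: TestTrial,
    aois: AOIConfig,
    rng: np.random.Generator,
    t_start: float = TIMECOURSE_START_MS,
    t_end: float = TIMECOURSE_END_MS,
) -> dict[str, np.ndarray]:
    """Simulate one test trial; returns arrays keyed time_ms/x_px/y_px/valid.

    Timeline: gaze rests in the center AOI (or, for a drawn-invalid trial,
    on a random lateral image) until a lognormal latency after image onset,
    then alternates lateral look episodes, each targeting the correct side
    with probability ``preference_theta``, with occasional returns to
    center at rate ``refixation_rate`` and 40 ms saccade gaps.
    """
    grid = np.arange(t_start, t_end + SAMPLE_PERIOD_MS / 2, SAMPLE_PERIOD_MS)
    n = grid.size
    x = np.empty(n)
    y = np.empty(n)

    correct_aoi = "left_image" if trial.correct_side == "left" else "right_image"
    incorrect_aoi = "right_image" if trial.correct_side == "left" else "left_image"

    invalid_trial = rng.random() < profile.p_invalid_trial
    start_aoi = (
        (correct_aoi if rng.random() < 0.5 else incorrect_aoi)
        if invalid_trial
        else "center"
    )

    lat_mu, lat_sig = _lognorm_params(
        profile.center_latency_mean_ms, profile.center_latency_sd_ms
    )
    fix_mu, fix_sig = _lognorm_params(
        profile.fixation_dur_mean_ms, profile.fixation_dur_sd_ms
    )

    # episode schedule: (t0, t1, anchor_x, anchor_y)
    episodes: list[tuple[float, float, float, float]] = []
    latency = float(rng.lognormal(lat_mu, lat_sig))
    ax, ay = _aoi_anchor(aois, start_aoi, rng, profile.centroid_jitter_sd_px)
    episodes.append((t_start, latency, ax, ay))
    t = latency + profile.saccade_gap_ms
    while t < t_end:
        side = correct_aoi if rng.random() < profile.preference_theta else incorrect_aoi
        dur = float(rng.lognormal(fix_mu, fix_sig))
        ax, ay = _aoi_anchor(aois, side, rng, profile.centroid_jitter_sd_px)
        episodes.append((t, min(t + dur, t_end), ax, ay))
        t += dur + profile.saccade_gap_ms
        if t < t_end and rng.random() < profile.refixation_rate:
            cdur = float(rng.lognormal(fix_mu, fix_sig)) * 0.5
            ax, ay = _aoi_anchor(aois, "center", rng, profile.centroid_jitter_sd_px)
            episodes.append((t, min(t + cdur, t_end), ax, ay))
            t += cdur + profile.saccade_gap_ms

    # rasterize: episode anchor during episodes, linear travel in the gaps
    x[:] = np.nan
    y[:] = np.nan
    for t0, t1, ax, ay in episodes:
        sel = (grid >= t0) & (grid < t1)
        x[sel] = ax
        y[sel] = ay
    # fill saccade-gap samples by interpolation between neighbours
    gap = np.isnan(x)
    if gap.any() and (~gap).any():
        x[gap] = np.interp(grid[gap], grid[~gap], x[~gap])
        y[gap] = np.interp(grid[gap], grid[~gap], y[~gap])

    x += rng.normal(0, profile.sample_noise_sd_px, n)
    y += rng.normal(0, profile.sample_noise_sd_px, n)

    valid = rng.random(n) >= profile.p_missing_sample
    x[~valid] = np.nan
    y[~valid] = np.nan
    return {
        "time_ms": grid,
        "x_px": x,
        "y_px": y,
        "valid": valid.astype(np.int8),
        "ground_truth_invalid": invalid_trial,
    }


def simulate_familiarization(
    profile: InfantProfile,
    stream: StreamSpec,
    aois: AOIConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Simulate familiarization gaze over the full stream duration.

    Each sample is on the stimulus with probability
    ``engagement_familiarization``; on-stimulus samples land in the eyes
    AOI with probability ``p_eyes_region`` and in the mouth AOI otherwise.
    Off-stimulus samples are emitted invalid (gaze away from the screen),
    and tracker dropouts add ``p_missing_sample`` on top.
    """
    n = int(stream.total_duration_ms // SAMPLE_PERIOD_MS)
    grid = np.arange(n) * SAMPLE_PERIOD_MS
    on = rng.random(n) < profile.engagement_familiarization
    eyes = rng.random(n) < profile.p_eyes_region
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    for region, sel in (("eyes", on & eyes), ("mouth", on & ~eyes)):
        x0, y0, x1, y1 = aois[region]
        k = int(sel.sum())
        x[sel] = rng.uniform(x0, x1, k)
        y[sel] = rng.uniform(y0, y1, k)
    valid = on & (rng.random(n) >= profile.p_missing_sample)
    x[~valid] = np.nan
    y[~valid] = np.nan
    return {
        "time_ms": grid,
        "x_px": x,
        "y_px": y,
        "valid": valid.astype(np.int8),
    }


@dataclass
class GazeRecording:
    """One infant's simulated session on the 20 ms grid."""

    infant_id: str
    trials: dict[int, dict[str, np.ndarray]]
    familiarization: dict[str, np.ndarray] | None = None
    dropped: bool = False
    screen: tuple[int, int] = (1024, 768)

    def to_frame(self) -> pd.DataFrame:
        """Canonical long-format export (one row per sample)."""
        frames = []
        if self.familiarization is not None:
            f = pd.DataFrame(
                {k: v for k, v in self.familiarization.items() if k != "ground_truth_invalid"}
            )
            f.insert(0, "trial_id", np.nan)
            f.insert(0, "phase", "familiarization")
            frames.append(f)
        for tid in sorted(self.trials):
            d = self.trials[tid]
            f = pd.DataFrame(
                {k: v for k, v in d.items() if k != "ground_truth_invalid"}
            )
            f.insert(0, "trial_id", tid)
            f.insert(0, "phase", "test")
            frames.append(f)
        out = pd.concat(frames, ignore_index=True)
        out.insert(0, "infant_id", self.infant_id)
        return out


@dataclass
class CohortSpec:
    """Population distribution the per-infant profiles are drawn from."""

    base: InfantProfile = field(default_factory=InfantProfile)
    theta_mean: float = 0.55
    theta_sd: float = 0.0
    latency_mean_sd_ms: float = 150.0  # between-infant sd of the mean latency
    p_invalid_mean: float = 0.45
    p_invalid_concentration: float = 10.0  # Beta a+b; 0 disables heterogeneity
    engagement_sd: float = 0.15
    age_mean_months: float = 7.96
    age_sd_months: float = 0.4
    dropout: float = 0.0

    def draw_profile(self, infant_id: str, rng: np.random.Generator) -> InfantProfile:
        theta = float(np.clip(rng.normal(self.theta_mean, self.theta_sd), 0.0, 1.0)) \
            if self.theta_sd > 0 else self.theta_mean
        lat = max(150.0, rng.normal(self.base.center_latency_mean_ms, self.latency_mean_sd_ms))
        if self.p_invalid_concentration > 0:
            a = self.p_invalid_mean * self.p_invalid_concentration
            b = (1 - self.p_invalid_mean) * self.p_invalid_concentration
            p_inv = float(rng.beta(a, b))
        else:
            p_inv = self.p_invalid_mean
        eng = float(np.clip(
            rng.normal(self.base.engagement_familiarization, self.engagement_sd), 0.05, 1.0
        ))
        return replace(
            self.base,
            infant_id=infant_id,
            age_months=float(rng.normal(self.age_mean_months, self.age_sd_months)),
            preference_theta=theta,
            center_latency_mean_ms=float(lat),
            p_invalid_trial=p_inv,
            engagement_familiarization=eng,
            fussiness_dropout=self.dropout,
        )


def simulate_cohort(
    n_infants: int,
    cohort: CohortSpec,
    schedule: TestTrialSchedule,
    aois: AOIConfig,
    seed: int,
    stream: StreamSpec | None = None,
    familiarization_aois: AOIConfig | None = None,
) -> tuple[list[GazeRecording], pd.DataFrame]:
    """Simulate a cohort; returns recordings plus the ground-truth table.

    Deterministic in ``seed``.  Infants drawn fussy (probability
    ``cohort.dropout``) abort after a random prefix of trials and are
    flagged ``dropped`` — the analysis pipeline excludes them up front, as
    fussiness exclusions are made from the session video, not from gaze.
    """
    if n_infants < 1:
        raise ValueError("n_infants must be >= 1")
    rng = np.random.default_rng(seed)
    recordings = []
    rows = []
    for i in range(n_infants):
        iid = f"inf{i:03d}"
        prof = cohort.draw_profile(iid, rng)
        dropped = rng.random() < prof.fussiness_dropout
        n_trials = int(rng.integers(0, len(schedule.trials))) if dropped \
            else len(schedule.trials)
        trials = {
            t.index: simulate_trial(prof, t, aois, rng)
            for t in schedule.trials[:n_trials]
        }
        fam = None
        if stream is not None and not dropped:
            fam = simulate_familiarization(
                prof, stream, familiarization_aois or aois, rng
            )
        recordings.append(
            GazeRecording(infant_id=iid, trials=trials, familiarization=fam, dropped=dropped)
        )
        rows.append(
            {
                "infant_id": iid,
                "age_months": prof.age_months,
                "preference_theta": prof.preference_theta,
                "center_latency_mean_ms": prof.center_latency_mean_ms,
                "p_invalid_trial": prof.p_invalid_trial,
                "engagement_familiarization": prof.engagement_familiarization,
                "dropped": dropped,
                "n_trials_recorded": n_trials,
            }
        )
    return recordings, pd.DataFrame(rows)


def expected_tlt_p(
    profile: InfantProfile,
    window_ms: tuple[float, float] = (1060.0, 4700.0),
    n_sims: int = 20_000,
    seed: int = 0,
) -> float:
    """Episode-level expectation of the per-trial TLT proportion.

    Monte-Carlo over the episode process alone (durations and side choices,
    clipped to the analysis window), independent of the sample/fixation
    pipeline; used as the analytic reference in recovery checks.
    """
    rng = np.random.default_rng(seed)
    fix_mu, fix_sig = _lognorm_params(
        profile.fixation_dur_mean_ms, profile.fixation_dur_sd_ms
    )
    lat_mu, lat_sig = _lognorm_params(
        profile.center_latency_mean_ms, profile.center_latency_sd_ms
    )
    w0, w1 = window_ms
    props = []
    for _ in range(n_sims):
        t = float(rng.lognormal(lat_mu, lat_sig)) + profile.saccade_gap_ms
        tc = ti = 0.0
        while t < w1:
            dur = float(rng.lognormal(fix_mu, fix_sig))
            t0, t1 = t, min(t + dur, w1)
            ov = max(0.0, min(t1, w1) - max(t0, w0))
            if rng.random() < profile.preference_theta:
                tc += ov
            else:
                ti += ov
            t += dur + profile.saccade_gap_ms
            if t < w1 and rng.random() < profile.refixation_rate:
                t += float(rng.lognormal(fix_mu, fix_sig)) * 0.5 + profile.saccade_gap_ms
        if tc + ti > 0:
            props.append(tc / (tc + ti))
    return float(np.mean(props))
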