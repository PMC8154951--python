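"""Dispersion-based fixation parsing and area-of-interest assignment.

Raw 50 Hz gaze samples are parsed into fixations with the classic I-DT
(dispersion-threshold) algorithm: a maximal run of consecutive valid
samples is a fixation when its duration reaches ``min_duration_ms`` while
its dispersion D = (max x - min x) + (max y - min y) stays at or below the
threshold (30 px here, about 0.9 degrees at a 60 cm viewing distance).

Areas of interest are half-open pixel rectangles [x0, x1) x [y0, y1) with
the origin at the top-left of the 1024 x 768 screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AOIConfig",
    "Fixation",
    "default_test_aois",
    "default_familiarization_aois",
    "idt_fixations",
    "assign_aoi",
    "lateralization_timecourse",
    "TIMECOURSE_START_MS",
    "TIMECOURSE_END_MS",
    "SAMPLE_PERIOD_MS",
]

SCREEN_W, SCREEN_H = 1024, 768
SAMPLE_PERIOD_MS = 20.0
TIMECOURSE_START_MS = -500.0
TIMECOURSE_END_MS = 4700.0

PRIMARY_AOIS = ("left_image", "right_image", "center")
LATERAL_AOIS = ("left_image", "right_image")

Rect = tuple[float, float, float, float]  # x0, y0, x1, y1


@dataclass
class AOIConfig:
    """Named half-open rectangles; the primary AOIs must be pairwise disjoint."""

    rects: dict[str, Rect]

    def __post_init__(self) -> None:
        sw, sh = self.rects.get("screen", (0, 0, SCREEN_W, SCREEN_H))[2:]
        for name, (x0, y0, x1, y1) in self.rects.items():
            if not (x0 < x1 and y0 < y1):
                raise ValueError(f"AOI {name!r} is degenerate")
            if name != "screen" and not (0 <= x0 and x1 <= sw and 0 <= y0 and y1 <= sh):
                raise ValueError(f"AOI {name!r} exceeds the screen")
        prim = [n for n in PRIMARY_AOIS if n in self.rects]
        for i, a in enumerate(prim):
            for b in prim[i + 1 :]:
                if _overlap(self.rects[a], self.rects[b]):
                    raise ValueError(f"primary AOIs {a!r} and {b!r} overlap")

    def __getitem__(self, name: str) -> Rect:
        return self.rects[name]

    def __contains__(self, name: str) -> bool:
        return name in self.rects

    def center_of(self, name: str) -> tuple[float, float]:
        x0, y0, x1, y1 = self.rects[name]
        return (x0 + x1) / 2.0, (y0 + y1) / 2.0


def _overlap(a: Rect, b: Rect) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def default_test_aois(
    image_w: int = 380,
    image_h: int = 350,
    center_width: int = 264,
) -> AOIConfig:
    """Test-phase geometry: two 380x350 image squares flanking a center strip.

    The center strip of width ``center_width`` is centered on x = 512 and
    spans the full screen height; each image square is horizontally centered
    in the remaining lateral band and vertically centered on the screen.
    """
    cx0 = SCREEN_W / 2 - center_width / 2
    cx1 = SCREEN_W / 2 + center_width / 2
    y0 = (SCREEN_H - image_h) / 2
    lx0 = (cx0 - image_w) / 2
    rx0 = cx1 + (SCREEN_W - cx1 - image_w) / 2
    return AOIConfig(
        rects={
            "screen": (0, 0, SCREEN_W, SCREEN_H),
            "left_image": (lx0, y0, lx0 + image_w, y0 + image_h),
            "right_image": (rx0, y0, rx0 + image_w, y0 + image_h),
            "center": (cx0, 0, cx1, SCREEN_H),
        }
    )


def default_familiarization_aois(stim_w: int = 550, stim_h: int = 580) -> AOIConfig:
    """Familiarization geometry: centered 550x580 stimulus with eyes/mouth bands."""
    x0 = (SCREEN_W - stim_w) / 2
    y0 = (SCREEN_H - stim_h) / 2
    # face sub-regions: eyes in the upper-middle band, mouth below
    eyes = (x0 + 90, y0 + 140, x0 + stim_w - 90, y0 + 280)
    mouth = (x0 + 150, y0 + 330, x0 + stim_w - 150, y0 + 440)
    return AOIConfig(
        rects={
            "screen": (0, 0, SCREEN_W, SCREEN_H),
            "stimulus": (x0, y0, x0 + stim_w, y0 + stim_h),
            "eyes": eyes,
            "mouth": mouth,
        }
    )


def assign_aoi(
    x: float, y: float, aois: AOIConfig, labels: tuple[str, ...] = PRIMARY_AOIS
) -> str:
    """Label of the rectangle containing (x, y), else ``"outside"``.

    Rectangles are half-open, so boundary coordinates belong to at most one
    AOI and assignment is unambiguous for disjoint rectangles.
    """
    if not (np.isfinite(x) and np.isfinite(y)):
        return "outside"
    for name in labels:
        if name not in aois:
            continue
        x0, y0, x1, y1 = aois[name]
        if x0 <= x < x1 and y0 <= y < y1:
            return name
    return "outside"


@dataclass
class Fixation:
    onset_ms: float
    offset_ms: float
    x: float
    y: float
    n_samples: int
    aoi: str = ""

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def _bridge_single_invalid(x: np.ndarray, y: np.ndarray, valid: np.ndarray):
    """Linearly interpolate isolated invalid samples flanked by valid ones."""
    x = x.copy()
    y = y.copy()
    valid = valid.copy()
    bad = ~valid
    idx = np.nonzero(bad[1:-1])[0] + 1
    for i in idx:
        if valid[i - 1] and valid[i + 1]:
            x[i] = 0.5 * (x[i - 1] + x[i + 1])
            y[i] = 0.5 * (y[i - 1] + y[i + 1])
            valid[i] = True
    return x, y, valid


def idt_fixations(
    samples,
    dispersion_px: float = 30.0,
    min_duration_ms: float = 100.0,
    sample_period_ms: float = SAMPLE_PERIOD_MS,
    bridge_invalid: bool = True,
    aois: AOIConfig | None = None,
    aoi_labels: tuple[str, ...] = PRIMARY_AOIS,
) -> list[Fixation]:
    """I-DT fixation detection on a time-ordered sample table.

    ``samples`` is anything with ``time_ms``, ``x_px``, ``y_px`` and
    ``valid`` columns/keys (a pandas DataFrame or a dict of arrays).  Each
    sample represents one 20 ms tick, so a fixation's duration is
    ``n_samples * sample_period_ms``.  Runs of valid samples are broken by
    gaps of more than one sample; a single invalid sample is bridged by
    linear interpolation unless ``bridge_invalid`` is off.  If ``aois`` is
    given, each fixation is labelled by the AOI containing its centroid.
    """
    t = np.asarray(samples["time_ms"], dtype=float)
    x = np.asarray(samples["x_px"], dtype=float)
    y = np.asarray(samples["y_px"], dtype=float)
    valid = np.asarray(samples["valid"]).astype(bool)
    valid = valid & np.isfinite(x) & np.isfinite(y)
    if t.size == 0 or not valid.any():
        return []
    if np.any(np.diff(t) <= 0):
        raise ValueError("samples must be strictly time-ordered")

    if bridge_invalid:
        x, y, valid = _bridge_single_invalid(x, y, valid)

    min_n = max(1, math.ceil(min_duration_ms / sample_period_ms))
    fixations: list[Fixation] = []

    # split into runs of consecutive (on the 20 ms grid) valid samples
    run_start = None
    breaks = []
    for i in range(t.size):
        contiguous = i > 0 and abs(t[i] - t[i - 1] - sample_period_ms) < 1e-6
        if valid[i] and (run_start is None):
            run_start = i
        elif run_start is not None and (not valid[i] or not contiguous):
            breaks.append((run_start, i))
            run_start = i if valid[i] else None
    if run_start is not None:
        breaks.append((run_start, t.size))

    for a, b in breaks:
        fixations.extend(
            _idt_run(t[a:b], x[a:b], y[a:b], dispersion_px, min_n, sample_period_ms)
        )
    if aois is not None:
        for f in fixations:
            f.aoi = assign_aoi(f.x, f.y, aois, aoi_labels)
    return fixations


def _idt_run(t, x, y, thr, min_n, period) -> list[Fixation]:
    out = []
    n = t.size
    i = 0
    while i + min_n <= n:
        j = i + min_n
        xmin, xmax = x[i:j].min(), x[i:j].max()
        ymin, ymax = y[i:j].min(), y[i:j].max()
        if (xmax - xmin) + (ymax - ymin) <= thr:
            while j < n:
                nx0 = min(xmin, x[j])
                nx1 = max(xmax, x[j])
                ny0 = min(ymin, y[j])
                ny1 = max(ymax, y[j])
                if (nx1 - nx0) + (ny1 - ny0) > thr:
                    break
                xmin, xmax, ymin, ymax = nx0, nx1, ny0, ny1
                j += 1
            out.append(
                Fixation(
                    onset_ms=float(t[i]),
                    offset_ms=float(t[j - 1] + period),
                    x=float(x[i:j].mean()),
                    y=float(y[i:j].mean()),
                    n_samples=j - i,
                )
            )
            i = j
        else:
            i += 1
    return out


def lateralization_timecourse(
    samples,
    aois: AOIConfig,
    t_start: float = TIMECOURSE_START_MS,
    t_end: float = TIMECOURSE_END_MS,
    period: float = SAMPLE_PERIOD_MS,
) -> np.ndarray:
    """Binary gaze-lateralization vector on the 20 ms grid of one trial.

    Times are trial-relative with t = 0 at lateral-image onset.  Entry k
    (time t_start + k*period) is 1 iff the sample at that time is valid and
    falls in the left or right image AOI; missing, invalid or non-lateral
    samples give 0.
    """
    grid = np.arange(t_start, t_end + period / 2, period)
    t = np.asarray(samples["time_ms"], dtype=float)
    x = np.asarray(samples["x_px"], dtype=float)
    y = np.asarray(samples["y_px"], dtype=float)
    valid = np.asarray(samples["valid"]).astype(bool)
    out = np.zeros(grid.size, dtype=float)
    idx = np.round((t - t_start) / period).astype(int)
    ok = (idx >= 0) & (idx < grid.size) & np.isclose(t, t_start + idx * period)
    lateral = np.zeros(t.size, dtype=bool)
    finite = np.isfinite(x) & np.isfinite(y)
    for name in LATERAL_AOIS:
        x0, y0, x1, y1 = aois[name]
        with np.errstate(invalid="ignore"):
            lateral |= finite & (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
    sel = ok & valid & lateral
    out[idx[sel]] = 1.0
    return out
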