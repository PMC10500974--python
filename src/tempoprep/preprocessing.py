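"""Saccade detection, trial validity filtering and preprocessing accounting.

The detector mirrors the study's criteria: a saccade is a contiguous episode
whose smoothed velocity exceeds 22 deg/s, with peak acceleration above
3800 deg/s^2 and cumulative displacement above 1 deg.  Velocity and
acceleration come from central differences of the 500 Hz trace with a 3-sample
moving-average smoother.  Episodes touching blink gaps (NaN samples) are
discarded.

Trial filters:

* artifact rejection — any blink gap overlapping the foreperiod/response
  window, or a sample-to-sample discontinuity outside detected saccades,
  drops the trial;
* visually-guided selection — the first saccade with latency in [100, 1000] ms
  after the imperative stimulus (endpoints inclusive) landing inside the
  3 x 3 deg target box.

``summarize_preprocessing`` emits the trial accounting (total / after
artifact rejection / visually guided, with percentages of total rounded
half-up to two decimals).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .simulate import EyeTrace

VELOCITY_THRESHOLD = 22.0     # deg/s
ACCEL_THRESHOLD = 3800.0      # deg/s^2
AMPLITUDE_THRESHOLD = 1.0     # deg
LATENCY_WINDOW = (100.0, 1000.0)  # ms after IS onset, inclusive


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    peak_velocity_deg_s: float
    peak_accel_deg_s2: float
    landing_xy_deg: tuple[float, float]
    latency_ms: float | None = None  # onset - IS onset, when IS is known


def _smooth3(v: np.ndarray) -> np.ndarray:
    out = v.copy()
    out[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    return out


def detect_saccades(
    trace: EyeTrace,
    velocity_threshold: float = VELOCITY_THRESHOLD,
    accel_threshold: float = ACCEL_THRESHOLD,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
) -> list[SaccadeEvent]:
    """Detect saccades by velocity/acceleration/amplitude thresholds.

    Onset is the first supra-threshold velocity sample of an episode.  Episodes
    containing or adjacent to NaN (blink) samples are skipped.
    """
    if len(trace.t) < 5:
        raise ValueError("trace shorter than the smoothing window")
    dt = np.median(np.diff(trace.t)) / 1000.0  # s
    x, y = trace.x, trace.y
    vx = np.gradient(x, trace.t / 1000.0)
    vy = np.gradient(y, trace.t / 1000.0)
    speed = _smooth3(np.hypot(vx, vy))
    accel = np.abs(np.gradient(speed, trace.t / 1000.0))
    bad = np.isnan(x) | np.isnan(y)
    # NaNs propagate through the derivative stencils; widen by one sample
    bad = bad | np.roll(bad, 1) | np.roll(bad, -1)
    above = (speed > velocity_threshold) & ~bad & ~np.isnan(speed)
    events: list[SaccadeEvent] = []
    i, n = 0, len(above)
    is_onset = trace.events.get("is_onset")
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        seg = slice(i, j)
        if np.any(bad[max(0, i - 1) : min(n, j + 1)]):
            i = j
            continue
        amp = float(np.hypot(x[j - 1] - x[max(i - 1, 0)], y[j - 1] - y[max(i - 1, 0)]))
        peak_v = float(np.nanmax(speed[seg]))
        peak_a = float(np.nanmax(accel[seg]))
        if amp > amplitude_threshold and peak_a > accel_threshold:
            onset = float(trace.t[i])
            events.append(
                SaccadeEvent(
                    onset_ms=onset,
                    offset_ms=float(trace.t[j - 1]),
                    amplitude_deg=amp,
                    peak_velocity_deg_s=peak_v,
                    peak_accel_deg_s2=peak_a,
                    landing_xy_deg=(float(x[j - 1]), float(y[j - 1])),
                    latency_ms=None if is_onset is None else onset - is_onset,
                )
            )
        i = j
    return events


def reject_artifacts(
    trace: EyeTrace,
    jump_threshold_deg: float = 2.0,
    events: list[SaccadeEvent] | None = None,
    max_peak_velocity: float = 800.0,
    min_duration_ms: float = 10.0,
) -> tuple[bool, str | None]:
    """Keep/drop decision for one trial's trace.

    Drops when a blink gap (NaN run) overlaps the foreperiod or response
    window, or when recording continuity is broken: a sample-to-sample jump
    above ``jump_threshold_deg`` outside detected saccade episodes, or a
    detected episode that is not a plausible eye movement — peak velocity
    beyond ``max_peak_velocity`` (the saccadic main sequence saturates well
    below that) or duration under ``min_duration_ms`` (a signal jump, not a
    movement).  Returns ``(keep, reason)`` with reason in
    {None, "blink", "discontinuity"}.
    """
    ws = trace.events.get("ws_onset", trace.t[0])
    gap = np.isnan(trace.x) | np.isnan(trace.y)
    if np.any(gap & (trace.t >= ws)):
        return False, "blink"
    if events is None:
        events = detect_saccades(trace)
    for ev in events:
        if (
            ev.peak_velocity_deg_s > max_peak_velocity
            or (ev.offset_ms - ev.onset_ms) < min_duration_ms
        ):
            return False, "discontinuity"
    jump = np.hypot(np.diff(trace.x), np.diff(trace.y))
    in_saccade = np.zeros(len(trace.t) - 1, dtype=bool)
    for ev in events:
        in_saccade |= (trace.t[:-1] >= ev.onset_ms - 4.0) & (
            trace.t[:-1] <= ev.offset_ms + 4.0
        )
    if np.any((jump > jump_threshold_deg) & ~in_saccade & ~np.isnan(jump)):
        return False, "discontinuity"
    return True, None


def select_visually_guided(
    events: list[SaccadeEvent],
    is_onset: float,
    box_center: tuple[float, float],
    box_size_deg: float = 3.0,
    latency_window: tuple[float, float] = LATENCY_WINDOW,
) -> SaccadeEvent | None:
    """First saccade initiated 100-1000 ms after IS (inclusive) landing in the box."""
    lo, hi = latency_window
    half = box_size_deg / 2.0
    for ev in sorted(events, key=lambda e: e.onset_ms):
        lat = ev.onset_ms - is_onset
        if lat < lo or lat > hi:
            continue
        dx = abs(ev.landing_xy_deg[0] - box_center[0])
        dy = abs(ev.landing_xy_deg[1] - box_center[1])
        if dx <= half and dy <= half:
            return SaccadeEvent(**{**ev.__dict__, "latency_ms": lat})
    return None


def preprocess_trials(
    trials: pd.DataFrame,
    anticipatory_ms: float = LATENCY_WINDOW[0],
    late_ms: float = LATENCY_WINDOW[1],
) -> pd.DataFrame:
    """Apply the validity filters to a flagged trial table.

    Ensures anticipatory/late flags reflect the latency window (inclusive
    endpoints are *valid*) and adds a ``valid`` column: not artifact, not
    anticipatory/late/off-target, latency present.  Idempotent.
    """
    out = trials.copy()
    lat = out["latency"]
    out["anticipatory"] = lat.notna() & (lat < anticipatory_ms)
    out["late"] = lat.notna() & (lat > late_ms)
    out["valid"] = (
        lat.notna()
        & ~out["artifact"]
        & ~out["anticipatory"]
        & ~out["late"]
        & ~out["off_target"]
    )
    return out


@dataclass(frozen=True)
class PreprocessSummary:
    """Trial accounting: totals, survivors of each filter, and % of total."""

    n_total: int
    n_after_artifact: int
    n_visually_guided: int
    pct_after_artifact: float
    pct_visually_guided: float
    pct_lost_to_blinks: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["total", "after_artifact_rejection", "visually_guided"],
                "n": [self.n_total, self.n_after_artifact, self.n_visually_guided],
                "pct_of_total": [100.0, self.pct_after_artifact, self.pct_visually_guided],
            }
        )


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_counts(n_total: int, n_after_artifact: int, n_visually_guided: int) -> PreprocessSummary:
    """Accounting from raw stage counts (percentages of total, 2 decimals)."""
    if not (n_total >= n_after_artifact >= n_visually_guided >= 0):
        raise ValueError("counts must be non-increasing across stages")
    pct_art = _round2(100.0 * n_after_artifact / n_total) if n_total else 100.0
    pct_vg = _round2(100.0 * n_visually_guided / n_total) if n_total else 100.0
    return PreprocessSummary(
        n_total, n_after_artifact, n_visually_guided,
        pct_art, pct_vg, _round2(100.0 - pct_art),
    )


def summarize_preprocessing(trials: pd.DataFrame) -> PreprocessSummary:
    """Table-1-style accounting from a flagged trial table."""
    flagged = preprocess_trials(trials)
    return summarize_counts(
        len(flagged),
        int((~flagged["artifact"]).sum()),
        int(flagged["valid"].sum()),
    )
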