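"""Synthetic experiment generator.

Emulates the oculomotor variable-foreperiod study end to end so every
downstream stage (hazard regressors, preprocessing, mixed models, equivalence
tests) can be exercised without real recordings:

* design — 42 subjects x 4 blocks x 100 trials; per anchor (1600 / 2400 ms) a
  baseline block (constant foreperiod, ~5 ms technical jitter) always precedes
  the uncertain block (Gaussian kernel, sigma 120 ms, truncated to
  1250-2750 ms); anchor-pair order counterbalanced across subjects; target side
  left/right with p = 0.5;
* latencies — a generative :class:`~tempoprep.prep_models.PreparationModel`
  plus a Gaussian subject random intercept (default SD 33.571 ms) and Gaussian
  residual noise (default SD 51.905 ms, the random-term scales of the fitted
  short-anchor mixed model);
* gaze traces — 500 Hz cyclopean x/y in degrees with event timestamps, a
  minimum-jerk saccade of ~9.5 deg at the generated latency, optional blink
  gaps (fixture surface for the saccade detector);
* dropout — Bernoulli artifact flags (default rate 5.07%, the study's
  blink/lost-signal loss) and anticipatory/late/off-target flags.

All randomness flows from one seed via ``numpy`` SeedSequence spawning, so the
whole experiment is reproducible and stages can be re-run in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design as _design
from .design import (
    DEFAULT_BOUNDS,
    FPDistribution,
    LONG_ANCHOR,
    SHORT_ANCHOR,
    make_baseline,
    make_uncertain,
    sample_foreperiods,
)
from .prep_models import PreparationModel

#: Random-term SDs of the fitted short-anchor mixed model (ms).
DEFAULT_SUBJECT_SD: float = 33.571
DEFAULT_RESID_SD: float = 51.905
#: Trial fraction lost to blinks / lost eye signal.
DEFAULT_ARTIFACT_RATE: float = 0.0507

TRIAL_COLUMNS = [
    "subject_id", "block_label", "block_order_index", "trial_index",
    "fp_n", "fp_prev", "sequence", "latency", "target_side",
    "artifact", "anticipatory", "late", "off_target",
]


def block_distributions(
    anchors=(SHORT_ANCHOR, LONG_ANCHOR),
    jitter_sd: float = _design.BASELINE_JITTER_SD,
    sigma: float = _design.UNCERTAIN_SIGMA,
    bounds=DEFAULT_BOUNDS,
) -> dict[str, FPDistribution]:
    """The four block distributions keyed by label (B_short, U_short, ...)."""
    short, long_ = sorted(anchors)

    def b_bounds(anchor):
        # baseline foreperiods stay within anchor +- 3 technical-jitter SDs
        if jitter_sd == 0:
            return bounds
        return (max(bounds[0], anchor - 3 * jitter_sd), min(bounds[1], anchor + 3 * jitter_sd))

    return {
        "B_short": make_baseline(short, jitter_sd, bounds=b_bounds(short)),
        "U_short": make_uncertain(short, sigma, bounds=bounds),
        "B_long": make_baseline(long_, jitter_sd, bounds=b_bounds(long_)),
        "U_long": make_uncertain(long_, sigma, bounds=bounds),
    }


def build_design(
    n_subjects: int = 42,
    n_trials_per_block: int = 100,
    anchors=(SHORT_ANCHOR, LONG_ANCHOR),
    seed: int | np.random.Generator = 0,
    jitter_sd: float = _design.BASELINE_JITTER_SD,
    sigma: float = _design.UNCERTAIN_SIGMA,
    bounds=DEFAULT_BOUNDS,
) -> pd.DataFrame:
    """Build the per-subject block plan and sample all foreperiods.

    Half the subjects start with the short-anchor pair, half with the long
    one (odd ``n_subjects`` is counterbalanced as evenly as possible, with a
    warning).  Within an anchor pair the baseline block always precedes the
    uncertain block.  Returns a trial table (one row per trial) with
    foreperiods sampled, history columns (``fp_prev``, ``sequence``) filled,
    and latency/flag columns initialised to missing/False.
    """
    if n_subjects % 2:
        import warnings

        warnings.warn(
            "odd n_subjects: start-anchor counterbalancing is off by one subject"
        )
    rng = np.random.default_rng(seed)
    dists = block_distributions(anchors, jitter_sd, sigma, bounds)
    # counterbalanced start anchor, randomly assigned to subjects
    starts = np.array(["short", "long"]).repeat(
        [(n_subjects + 1) // 2, n_subjects // 2]
    )
    rng.shuffle(starts)
    rows = []
    for subj in range(1, n_subjects + 1):
        order = ["short", "long"] if starts[subj - 1] == "short" else ["long", "short"]
        labels = [f"B_{order[0]}", f"U_{order[0]}", f"B_{order[1]}", f"U_{order[1]}"]
        for b_idx, label in enumerate(labels):
            fps = sample_foreperiods(dists[label], n_trials_per_block, rng)
            sides = rng.choice(["left", "right"], size=n_trials_per_block)
            for t_idx in range(n_trials_per_block):
                rows.append(
                    (subj, label, b_idx, t_idx + 1, float(fps[t_idx]), sides[t_idx])
                )
    table = pd.DataFrame(
        rows,
        columns=["subject_id", "block_label", "block_order_index", "trial_index",
                 "fp_n", "target_side"],
    )
    # history within each block; first trial of a block has no predecessor
    table["fp_prev"] = table.groupby(["subject_id", "block_order_index"])["fp_n"].shift(1)
    table["sequence"] = table["fp_prev"] - table["fp_n"]
    table["latency"] = np.nan
    for flag in ("artifact", "anticipatory", "late", "off_target"):
        table[flag] = False
    return table[TRIAL_COLUMNS]


def simulate_latencies(
    plan: pd.DataFrame,
    model: PreparationModel,
    subject_sd: float = DEFAULT_SUBJECT_SD,
    resid_sd: float | None = DEFAULT_RESID_SD,
    seed: int | np.random.Generator = 0,
    anticipatory_ms: float = 100.0,
    late_ms: float = 1000.0,
    dists: dict[str, FPDistribution] | None = None,
) -> pd.DataFrame:
    """Generate trial latencies under a preparation model.

    latency = model mean at fp_n (with trace history for the fMTP model)
    + subject intercept ~ N(0, subject_sd^2) + eps ~ N(0, sd(fp)^2), where the
    residual SD is ``resid_sd`` unless the model is ``scalar_noise`` (or
    ``resid_sd`` is None), in which case the model's own noise law applies.
    Latencies outside [anticipatory_ms, late_ms] are flagged.
    """
    rng = np.random.default_rng(seed)
    table = plan.copy()
    if dists is None:
        dists = block_distributions()
    subj_ids = table["subject_id"].unique()
    intercepts = dict(zip(subj_ids, rng.normal(0.0, subject_sd, len(subj_ids))))
    latency = pd.Series(np.nan, index=table.index)
    for (_, _), block in table.groupby(["subject_id", "block_order_index"], sort=False):
        label = block["block_label"].iloc[0]
        fn = model.latency_fn(dists[label])
        fps = block["fp_n"].to_numpy()
        if model.name == "fmtp_trace":
            mean = np.array(
                [fn(fp, history=list(fps[:i][::-1])) for i, fp in enumerate(fps)]
            )
        else:
            mean = np.asarray(fn(fps), dtype=float)
        if model.name == "scalar_noise" or resid_sd is None:
            sd = model.noise_sd(fps)
        else:
            sd = np.full(len(fps), float(resid_sd))
        latency.loc[block.index] = (
            mean + intercepts[block["subject_id"].iloc[0]] + rng.normal(0.0, 1.0, len(fps)) * sd
        )
    table["latency"] = latency.to_numpy()
    table["anticipatory"] = table["latency"] < anticipatory_ms
    table["late"] = table["latency"] > late_ms
    return table


def apply_dropout(
    trials: pd.DataFrame,
    artifact_rate: float = DEFAULT_ARTIFACT_RATE,
    seed: int | np.random.Generator = 0,
    off_target_rate: float = 0.0,
) -> pd.DataFrame:
    """Flag a Bernoulli subset of trials as artifacts (blink / lost signal).

    Optionally also flags an independent ``off_target_rate`` subset as landing
    outside the target box.
    """
    if not (0 <= artifact_rate < 1):
        raise ValueError("artifact_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = trials.copy()
    out["artifact"] = rng.random(len(out)) < artifact_rate
    if off_target_rate > 0:
        out["off_target"] = out["off_target"] | (rng.random(len(out)) < off_target_rate)
    return out


# ---------------------------------------------------------------------------
# Gaze traces


@dataclass
class EyeTrace:
    """Synthetic cyclopean gaze trace sampled at 500 Hz.

    ``t`` in ms from trial start; ``x``/``y`` in degrees (NaN inside blink
    gaps); ``events`` holds the display timestamps (fixation, pre-FP, warning
    and imperative stimulus onsets) plus target geometry.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    events: dict
    sample_rate: float = 500.0

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_ms": self.t, "x_deg": self.x, "y_deg": self.y}).to_csv(
            path, index=False
        )

    def events_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.events, fh, indent=1)

    @classmethod
    def from_csv(cls, path, events_path) -> "EyeTrace":
        frame = pd.read_csv(path)
        with open(events_path) as fh:
            events = json.load(fh)
        return cls(
            frame["t_ms"].to_numpy(), frame["x_deg"].to_numpy(),
            frame["y_deg"].to_numpy(), events,
        )


def _minimum_jerk(frac: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]."""
    return 10 * frac**3 - 15 * frac**4 + 6 * frac**5


@dataclass
class SaccadeParams:
    """Kinematic knobs of the synthetic saccade generator."""

    amplitude_deg: float = 9.5
    duration_ms: float = 48.0
    fixation_noise_deg: float = 0.04
    pre_fp_ms: float = 2000.0
    fixation_ms: float = 1100.0
    ws_flash_ms: float = 50.0
    post_landing_ms: float = 300.0
    blink_gap_ms: float = 150.0


def simulate_eye_trace(
    fp_n: float,
    latency: float | None,
    target_side: str = "right",
    params: SaccadeParams | None = None,
    seed: int | np.random.Generator = 0,
    blink: bool = False,
    fixation_only: bool = False,
) -> EyeTrace:
    """One trial's gaze trace: fixation, a saccade at IS onset + latency, flags.

    ``blink`` inserts a >= 100 ms NaN gap during the foreperiod;
    ``fixation_only`` suppresses the saccade (no response trial).
    """
    params = params or SaccadeParams()
    rng = np.random.default_rng(seed)
    dt = 1000.0 / 500.0
    ws_onset = params.fixation_ms + params.pre_fp_ms
    is_onset = ws_onset + fp_n
    resp = 0.0 if (latency is None or fixation_only) else latency
    total = is_onset + resp + params.post_landing_ms
    t = np.arange(0.0, total, dt)
    x = rng.normal(0.0, params.fixation_noise_deg, len(t))
    y = rng.normal(0.0, params.fixation_noise_deg, len(t))
    side = 1.0 if target_side == "right" else -1.0
    events = {
        "fixation_onset": 0.0,
        "pre_fp_onset": params.fixation_ms,
        "ws_onset": ws_onset,
        "is_onset": is_onset,
        "fp_n": fp_n,
        "target_side": target_side,
        "target_x": side * 9.5,
        "target_y": 0.0,
        "box_size_deg": 3.0,
    }
    if latency is not None and not fixation_only:
        onset = is_onset + latency
        in_sacc = (t >= onset) & (t < onset + params.duration_ms)
        frac = (t[in_sacc] - onset) / params.duration_ms
        x[in_sacc] += side * params.amplitude_deg * _minimum_jerk(frac)
        x[t >= onset + params.duration_ms] += side * params.amplitude_deg
    if blink:
        gap_start = ws_onset + 0.3 * fp_n
        gap = (t >= gap_start) & (t < gap_start + params.blink_gap_ms)
        x[gap] = np.nan
        y[gap] = np.nan
    return EyeTrace(t, x, y, events)


def simulate_eye_traces(
    trials: pd.DataFrame,
    params: SaccadeParams | None = None,
    seed: int | np.random.Generator = 0,
) -> list[EyeTrace]:
    """Traces for every trial in the table (artifact rows become blink trials)."""
    rng = np.random.default_rng(seed)
    traces = []
    for _, row in trials.iterrows():
        lat = None if np.isnan(row["latency"]) else float(row["latency"])
        traces.append(
            simulate_eye_trace(
                row["fp_n"], lat, row["target_side"], params,
                seed=rng, blink=bool(row["artifact"]),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# Trial-table I/O


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Delimited text, one row per trial; missing values as empty fields."""
    table.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table {path} lacks columns: {missing}")
    for flag in ("artifact", "anticipatory", "late", "off_target"):
        table[flag] = table[flag].astype(bool)
    return table
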