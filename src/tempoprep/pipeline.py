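"""Orchestrated runs: simulate -> hazard -> preprocess -> analyze -> report.

A run is a pure function of its :class:`RunConfig`: one master seed spawns
per-stage child seeds (design, latencies, dropout), so re-running any stage
with the same config reproduces its outputs byte for byte.  Every intermediate
is plain delimited text or JSON in the run directory:

``trials.csv``            simulated trial table with hazard regressors attached
``hazard_<block>.csv``    classic/mirror/reciprocal hazard per block
``table_preprocessing.csv`` trial accounting (total / after artifacts / guided)
``lmm_<dataset>.csv``     mixed-model fixed/random effects per predictor
``lm_binned.csv``         binned linear models + slope analysis battery
``tost.json``             paired-SD and coefficient equivalence tests
``manifest.json``         config, config hash, seed, package version
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import DEFAULT_BOUNDS
from .hazard import hazard_at, hazard_classic, hazard_mirror, hazard_reciprocal
from .prep_models import PreparationModel
from .preprocessing import preprocess_trials, summarize_preprocessing
from .simulate import (
    DEFAULT_ARTIFACT_RATE,
    DEFAULT_RESID_SD,
    DEFAULT_SUBJECT_SD,
    apply_dropout,
    block_distributions,
    build_design,
    read_trial_table,
    simulate_latencies,
    write_trial_table,
)
from . import stats as tp_stats


@dataclass
class RunConfig:
    """Complete description of a pipeline run (fully serialisable)."""

    seed: int = 0
    out_dir: str = "run"
    # design
    n_subjects: int = 42
    n_trials_per_block: int = 100
    anchors: tuple[float, float] = (1600.0, 2400.0)
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    jitter_sd: float = 5.0
    sigma: float = 120.0
    # generative model
    model: dict = field(default_factory=lambda: {"name": "hr_classic"})
    subject_sd: float = DEFAULT_SUBJECT_SD
    resid_sd: float = DEFAULT_RESID_SD
    # dropout
    artifact_rate: float = DEFAULT_ARTIFACT_RATE
    off_target_rate: float = 0.05
    # preprocessing
    anticipatory_ms: float = 100.0
    late_ms: float = 1000.0
    # analysis
    predictors: tuple[str, ...] = ("fp_n", "hr_rec", "fp_prev", "sequence")
    bin_width: float = 50.0
    alpha: float = 0.01
    sesoi_dz: float = tp_stats.SESOI_DZ
    sesoi_f2: dict = field(default_factory=lambda: dict(tp_stats.SESOI_F2))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["anchors"] = list(self.anchors)
        d["bounds"] = list(self.bounds)
        d["predictors"] = list(self.predictors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("anchors", "bounds", "predictors"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def child_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds spawned from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("design", "latency", "dropout")
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, ss.spawn(len(names)))
        }


def _block_dists(cfg: RunConfig):
    return block_distributions(cfg.anchors, cfg.jitter_sd, cfg.sigma, cfg.bounds)


def attach_hazard(trials: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Add per-trial ``hr_classic`` and ``hr_rec`` columns (bin-center lookup)."""
    out = trials.copy()
    out["hr_classic"] = np.nan
    out["hr_rec"] = np.nan
    for label, dist in _block_dists(cfg).items():
        mask = out["block_label"] == label
        if not mask.any():
            continue
        h = hazard_classic(dist, cfg.bin_width)
        hrec = hazard_reciprocal(h)
        fps = out.loc[mask, "fp_n"].to_numpy()
        out.loc[mask, "hr_classic"] = hazard_at(h, fps)
        out.loc[mask, "hr_rec"] = hazard_at(hrec, fps)
    return out


def stage_simulate(cfg: RunConfig) -> pd.DataFrame:
    seeds = cfg.child_seeds()
    dists = _block_dists(cfg)
    plan = build_design(
        cfg.n_subjects, cfg.n_trials_per_block, cfg.anchors, seeds["design"],
        cfg.jitter_sd, cfg.sigma, cfg.bounds,
    )
    model = PreparationModel(**cfg.model)
    trials = simulate_latencies(
        plan, model, cfg.subject_sd, cfg.resid_sd, seeds["latency"],
        cfg.anticipatory_ms, cfg.late_ms, dists,
    )
    trials = apply_dropout(trials, cfg.artifact_rate, seeds["dropout"], cfg.off_target_rate)
    return attach_hazard(trials, cfg)


def stage_hazard_tables(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    tables = {}
    for label, dist in _block_dists(cfg).items():
        h = hazard_classic(dist, cfg.bin_width)
        frames = [h.to_frame(), hazard_mirror(h).to_frame(), hazard_reciprocal(h).to_frame()]
        tables[label] = pd.concat(frames, ignore_index=True)
    return tables


def stage_analyze(cfg: RunConfig, clean: pd.DataFrame) -> dict:
    """The statistical battery on preprocessed (valid) trials."""
    valid = clean[clean["valid"]]
    results: dict = {"lmm": {}, "lm": [], "paired": {}, "tost": {}}
    lmm_rows = []
    for label in ("U_short", "U_long"):
        sub = valid[valid["block_label"] == label]
        anchor = label.split("_")[1]
        results["lmm"][label] = {}
        for predictor in cfg.predictors:
            res = tp_stats.fit_latency_mixed(sub, predictor, "rs1", "REML")
            results["lmm"][label][predictor] = res
            lmm_rows.append(res.to_table_row(dataset=label))
        # binned linear-model battery
        for reg in ("FPn", "HRrec"):
            r = tp_stats.fit_latency_lm_binned(sub, reg, bin_width=cfg.bin_width, bounds=cfg.bounds)
            results["lm"].append((label, r.formula, r))
        binned = tp_stats.bin_latency_stats(sub, cfg.bin_width, cfg.bounds)
        slope = tp_stats.weber_slope_analysis(binned["fp_bin"], binned["var"])
        results["lm"].append((label, "var ~ k^2*FP^2 + c", slope))
        sdreg = tp_stats.sd_vs_hazard_regression(binned["sd"], binned["hr_classic"])
        results["lm"].append((label, sdreg.formula, sdreg))
        # coefficient equivalence for the previous-foreperiod effect
        results["tost"][f"fp_prev_{anchor}"] = tp_stats.tost_coefficient(
            results["lmm"][label]["fp_prev"], cfg.sesoi_f2[anchor], cfg.alpha
        )
    # paired SD tests between anchors, within condition kind
    for kind in ("B", "U"):
        a = valid[valid["block_label"] == f"{kind}_short"].groupby("subject_id")["latency"].std()
        b = valid[valid["block_label"] == f"{kind}_long"].groupby("subject_id")["latency"].std()
        common = a.index.intersection(b.index)
        t, df, p = tp_stats.paired_sd_test(a.loc[common], b.loc[common])
        results["paired"][kind] = {"t": t, "df": df, "p": p}
        results["tost"][f"sd_{kind}"] = tp_stats.tost_paired(
            (a.loc[common] - b.loc[common]).to_numpy(), cfg.sesoi_dz, cfg.alpha
        )
    results["lmm_table"] = pd.concat(lmm_rows, ignore_index=True)
    return results


def _lm_table(results: dict) -> pd.DataFrame:
    rows = []
    for label, formula, r in results["lm"]:
        if isinstance(r, tp_stats.SlopeAnalysisResult):
            rows.append(
                {"Dataset": label, "Formula": formula, "beta": r.k_squared,
                 "SE": r.k_squared_se, "ci_low": r.ci_low, "ci_high": r.ci_high,
                 "p": r.p, "adj_R2": r.adj_r2}
            )
        else:
            rows.append(
                {"Dataset": label, "Formula": formula, "beta": r.slope,
                 "SE": r.slope_se, "ci_low": r.ci_low, "ci_high": r.ci_high,
                 "p": r.p, "adj_R2": r.adj_r2}
            )
    return pd.DataFrame(rows)


def _tost_json(results: dict) -> dict:
    out = {}
    for name, r in results["tost"].items():
        out[name] = {
            "bounds": list(r.bounds), "effect_size_type": r.effect_size_type,
            "effect": r.effect, "ci": list(r.ci), "p_lower": r.p_lower,
            "p_upper": r.p_upper, "alpha": r.alpha, "equivalent": r.equivalent,
        }
    for kind, d in results["paired"].items():
        out[f"paired_sd_{kind}"] = d
    return out


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute all stages and write every artifact to the run directory."""
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        trials = stage_simulate(cfg)
        write_trial_table(trials, out / "trials.csv")

        stage = "hazard"
        for label, frame in stage_hazard_tables(cfg).items():
            frame.to_csv(out / f"hazard_{label}.csv", index=False)

        stage = "preprocess"
        clean = preprocess_trials(trials, cfg.anticipatory_ms, cfg.late_ms)
        write_trial_table(clean, out / "trials_clean.csv")
        summary = summarize_preprocessing(trials)
        summary.to_frame().to_csv(out / "table_preprocessing.csv", index=False)

        stage = "analyze"
        results = stage_analyze(cfg, clean)

        stage = "report"
        results["lmm_table"].to_csv(out / "lmm_results.csv", index=False)
        _lm_table(results).to_csv(out / "lm_binned.csv", index=False)
        with open(out / "tost.json", "w") as fh:
            json.dump(_tost_json(results), fh, indent=1)
        manifest = {
            "package": "tempoprep",
            "version": __version__,
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "config_sha256": cfg.digest(),
            "child_seeds": cfg.child_seeds(),
            "stages": ["simulate", "hazard", "preprocess", "analyze", "report"],
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except Exception as exc:  # partial outputs stay on disk for inspection
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
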