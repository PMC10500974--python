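"""Predicted latency and latency-SD curves for temporal-preparation hypotheses.

Each hypothesis maps a property of the foreperiod distribution onto mean
saccadic latency through an affine mapping (the comparison between hypotheses
is about curve *shape*; absolute scale is free):

* ``hr_classic`` / ``hr_subjective`` — latency = a + b * (1 / HR(t)); the
  reciprocal hazard falls steeply over the foreperiod, so latency decreases as
  the "go" signal becomes imminent.  The subjective variant blurs the pmf
  first (kernel SD = phi * elapsed time).
* ``pdf`` — latency = a - b * f(t)/max f: latency is minimal where "go"
  signals are most frequent, producing a valley at the anchor and longer
  latencies on both flanks.
* ``fmtp_trace`` — trace-conditioning account: previously experienced
  foreperiods leave Gaussian-smeared memory traces (SD = smear_k * trace
  time); preparation at time t is the decay-weighted sum of trace densities,
  and latency = a - b * preparation.  Produces sequence effects (a short
  previous foreperiod shortens the current latency at short times).
* ``scalar_noise`` — flat mean latency with scalar (Weber) variability:
  sd(FP) = sqrt(k^2 * FP^2 + c).

SD-curve predictions distinguish the hypotheses on variability: blurring-based
accounts (subjective hazard, fMTP) predict SD growing with elapsed time; the
PDF account predicts a variability valley at the mode; an affine decreasing
map of the classic hazard reproduces the empirically observed SD decline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import FPDistribution
from .hazard import DEFAULT_PHI, hazard_at, hazard_classic, hazard_reciprocal, subjective_hazard

MODEL_NAMES = ("hr_classic", "hr_subjective", "pdf", "fmtp_trace", "scalar_noise", "linear_fp")

#: Default affine mapping, taken from the fitted latency ~ reciprocal-hazard
#: relation of the short-anchor uncertain block (intercept ms, slope ms per
#: unit of 1/HR).
DEFAULT_A: float = 217.924
DEFAULT_B: float = 0.371


@dataclass
class PreparationModel:
    """A named temporal-preparation hypothesis with its generative parameters.

    Parameters
    ----------
    name : str
        One of ``hr_classic``, ``hr_subjective``, ``pdf``, ``fmtp_trace``,
        ``scalar_noise``, ``linear_fp``.
    a, b : float
        Affine latency mapping (ms; b in ms per regressor unit, >= 0 for the
        hazard models).
    k : float
        Weber fraction for scalar/blurring variability (unitless).
    c : float
        Time-independent variance floor (ms^2) of the scalar-noise law.
    baseline_sd : float
        Constant latency SD (ms) used where the model does not itself
        prescribe one.
    phi : float
        Blur coefficient of the subjective hazard.
    smear_k, decay : float
        fMTP-like trace smearing fraction and per-trial forgetting weight.
    """

    name: str
    a: float = DEFAULT_A
    b: float = DEFAULT_B
    k: float = 0.1
    c: float = 0.0
    baseline_sd: float = 51.905
    phi: float = DEFAULT_PHI
    smear_k: float = 0.2
    decay: float = 1.0
    bin_width: float = 50.0

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        if self.name.startswith("hr") and self.b < 0:
            raise ValueError("hazard models require b >= 0")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be > 0")
        if not (0 < self.decay <= 1):
            raise ValueError("decay must be in (0, 1]")

    # -- mean-latency machinery -------------------------------------------------

    def latency_fn(self, dist: FPDistribution):
        """Return latency(fp_ms, history) for this model on ``dist``.

        ``history`` (list of previous foreperiods, most recent first) only
        matters for ``fmtp_trace``.
        """
        if self.name in ("hr_classic", "hr_subjective"):
            if self.name == "hr_classic":
                h = hazard_classic(dist, self.bin_width)
            else:
                h = subjective_hazard(dist, self.phi, self.bin_width)
            hrec = hazard_reciprocal(h)

            def fn(fp, history=None):
                return self.a + self.b * hazard_at(hrec, fp)

        elif self.name == "pdf":
            peak = dist.pmf.max()

            def fn(fp, history=None):
                fp_arr = np.atleast_1d(np.asarray(fp, dtype=float))
                idx = np.clip(
                    np.round((fp_arr - dist.support[0]) / dist.grid_ms).astype(int),
                    0, len(dist.support) - 1,
                )
                out = self.a - self.b * dist.pmf[idx] / peak
                return out if np.ndim(fp) else float(out[0])

        elif self.name == "fmtp_trace":

            def fn(fp, history=None):
                prep = fmtp_trace_prepare(history or [], self.smear_k, self.decay, fp)
                return self.a - self.b * prep

        elif self.name == "linear_fp":

            def fn(fp, history=None):
                return self.a + self.b * np.asarray(fp, dtype=float)

        else:  # scalar_noise: flat mean, the action is in the noise law

            def fn(fp, history=None):
                fp_arr = np.asarray(fp, dtype=float)
                return self.a + 0.0 * fp_arr

        return fn

    def noise_sd(self, fp) -> np.ndarray:
        """Trial-level residual SD at foreperiod ``fp`` (ms)."""
        fp = np.asarray(fp, dtype=float)
        if self.name == "scalar_noise":
            return np.sqrt(self.k**2 * fp**2 + self.c)
        return np.full_like(fp, self.baseline_sd, dtype=float)


def predict_latency_hr(
    dist: FPDistribution,
    phi: float | None = None,
    a: float = DEFAULT_A,
    b: float = DEFAULT_B,
    bin_width: float = 50.0,
) -> pd.DataFrame:
    """Mean-latency curve latency = a + b / HR over the binned support.

    ``phi=None`` uses the objective (classic) hazard; a positive ``phi`` the
    subjective (blurred) one.
    """
    if phi is None:
        h = hazard_classic(dist, bin_width)
    else:
        h = subjective_hazard(dist, phi, bin_width)
    hrec = hazard_reciprocal(h)
    return pd.DataFrame(
        {
            "fp_bin_center_ms": hrec.support,
            "predicted_latency_ms": a + b * hrec.values,
            "model_name": "hr_subjective" if phi is not None else "hr_classic",
        }
    )


def predict_latency_pdf(
    dist: FPDistribution,
    a: float = DEFAULT_A,
    b: float = 50.0,
    bin_width: float = 50.0,
) -> pd.DataFrame:
    """Mean-latency curve latency = a - b * f/max(f): a valley at the mode."""
    h = hazard_classic(dist, bin_width)  # reuse binned mass for the curve support
    from .hazard import _binned_pmf

    edges, mass = _binned_pmf(dist, bin_width)
    occupied = mass > 0
    rel = mass[occupied] / mass.max()
    centers = ((edges[:-1] + edges[1:]) / 2.0)[occupied]
    return pd.DataFrame(
        {
            "fp_bin_center_ms": centers,
            "predicted_latency_ms": a - b * rel,
            "model_name": "pdf",
        }
    )


def predict_sd_curves(
    model: PreparationModel, dist: FPDistribution, bin_width: float = 50.0
) -> pd.DataFrame:
    """Predicted latency-SD over the binned support for each hypothesis.

    Blurring accounts (``hr_subjective``, ``fmtp_trace``) and ``scalar_noise``
    give SD growing with elapsed time, the ``pdf`` account an SD valley at the
    mode, and ``hr_classic`` an affine *decreasing* map of the classic hazard
    (the empirically observed pattern).
    """
    h = hazard_classic(dist, bin_width)
    t = h.support
    if model.name == "scalar_noise":
        sd = np.sqrt(model.k**2 * t**2 + model.c)
    elif model.name in ("hr_subjective", "fmtp_trace"):
        sd = np.sqrt((model.k * t) ** 2 + model.baseline_sd**2)
    elif model.name == "pdf":
        from .hazard import _binned_pmf

        edges, mass = _binned_pmf(dist, bin_width)
        rel = mass[mass > 0] / mass.max()
        sd = model.baseline_sd + model.k * model.baseline_sd * (1.0 - rel)
    elif model.name in ("hr_classic", "linear_fp"):
        # affine decreasing map of HR_classic; default scale from the fitted
        # SD ~ classic-hazard relation (slope ~ -23 ms per hazard unit)
        sd = model.baseline_sd + 23.317 * (h.mean() - h.values)
        sd = np.maximum(sd, 1.0)
    else:  # pragma: no cover - names checked at construction
        raise ValueError(f"unknown model {model.name}")
    return pd.DataFrame(
        {"fp_bin_center_ms": t, "predicted_sd_ms": sd, "model_name": model.name}
    )


def fmtp_trace_prepare(fp_history, smear_k: float, decay: float, t) -> np.ndarray | float:
    """Preparation at time ``t`` from Gaussian-smeared memory traces.

    Each past foreperiod FP_{n-1-j} (``fp_history`` most recent first)
    contributes a normal density N(t; mean=FP, sd=smear_k*FP) weighted by
    decay^j.  Empty history gives 0.
    """
    if not (0 < decay <= 1):
        raise ValueError("decay must be in (0, 1]")
    if smear_k <= 0:
        raise ValueError("smear_k must be > 0")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    prep = np.zeros_like(t_arr)
    for j, fp_prev in enumerate(fp_history):
        prep += decay**j * sps.norm.pdf(t_arr, loc=fp_prev, scale=smear_k * fp_prev)
    return prep if np.ndim(t) else float(prep[0])
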