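"""Foreperiod (FP) distributions for variable-foreperiod experiments.

A trial presents a warning stimulus (WS) followed, after a foreperiod, by an
imperative "go" stimulus (IS).  Blocks use either a baseline (B) distribution —
a single anchor duration with only technical jitter (sigma ~ 5 ms) — or an
uncertain (U) distribution obtained by convolving the anchor with a Gaussian
kernel (sigma = 120 ms).  Foreperiods are restricted to a fixed range
(1250-2750 ms by default); Gaussian mass falling outside the range is cut and
the distribution renormalised.

Distributions are represented on a discrete millisecond grid: ``FPDistribution``
carries the support (grid points) and the probability mass per point.  The fine
grid is internal; 50-ms binning (:func:`bin_foreperiods`) is used for reporting
and for hazard-rate regressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_BOUNDS: tuple[float, float] = (1250.0, 2750.0)
#: Anchor durations used in the short/long blocks, ms.
SHORT_ANCHOR: float = 1600.0
LONG_ANCHOR: float = 2400.0
#: Technical jitter SD of the baseline condition, ms.
BASELINE_JITTER_SD: float = 5.0
#: Gaussian kernel SD of the uncertain condition, ms.
UNCERTAIN_SIGMA: float = 120.0


@dataclass(frozen=True)
class FPDistribution:
    """Discretised foreperiod distribution on a regular millisecond grid.

    Attributes
    ----------
    support : ndarray
        Ordered grid of durations (ms), spacing ``grid_ms``.
    pmf : ndarray
        Probability mass per grid point; non-negative, sums to 1.
    anchor : float
        Mean FP duration of the block (ms) before truncation.
    sigma : float
        SD of the generating Gaussian (ms); ~5 for B, 120 for U.
    kind : str
        ``"B"`` (baseline) or ``"U"`` (uncertain).
    bounds : tuple of float
        Admissible FP range (ms); mass outside is truncated away.
    grid_ms : float
        Grid spacing in ms.
    """

    support: np.ndarray
    pmf: np.ndarray
    anchor: float
    sigma: float
    kind: str
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    grid_ms: float = 1.0

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        pmf = np.asarray(self.pmf, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "pmf", pmf)
        if support.shape != pmf.shape or support.ndim != 1:
            raise ValueError("support and pmf must be 1-d arrays of equal length")
        if np.any(pmf < 0):
            raise ValueError("pmf entries must be non-negative")
        if abs(pmf.sum() - 1.0) > 1e-9:
            raise ValueError(f"pmf must sum to 1 (got {pmf.sum():.12f})")
        lo, hi = self.bounds
        if support.min() < lo - 1e-9 or support.max() > hi + 1e-9:
            raise ValueError("support points must lie within bounds")

    def mean(self) -> float:
        return float(np.sum(self.support * self.pmf))

    def var(self) -> float:
        m = self.mean()
        return float(np.sum((self.support - m) ** 2 * self.pmf))

    def sd(self) -> float:
        return float(np.sqrt(self.var()))

    def mode(self) -> float:
        return float(self.support[np.argmax(self.pmf)])

    def with_pmf(self, pmf: np.ndarray) -> "FPDistribution":
        return replace(self, pmf=pmf)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"duration_ms": self.support, "pmf": self.pmf})

    def to_csv(self, path) -> None:
        """Write as two-column delimited text with a metadata header comment."""
        with open(path, "w") as fh:
            fh.write(
                f"# anchor={self.anchor} sigma={self.sigma} kind={self.kind} "
                f"bounds={self.bounds[0]},{self.bounds[1]} grid_ms={self.grid_ms}\n"
            )
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "FPDistribution":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("missing metadata header comment")
            meta = dict(item.split("=") for item in header[1:].split())
            frame = pd.read_csv(fh)
        lo, hi = (float(v) for v in meta["bounds"].split(","))
        return cls(
            support=frame["duration_ms"].to_numpy(),
            pmf=frame["pmf"].to_numpy(),
            anchor=float(meta["anchor"]),
            sigma=float(meta["sigma"]),
            kind=meta["kind"],
            bounds=(lo, hi),
            grid_ms=float(meta["grid_ms"]),
        )


def _gaussian_cell_masses(
    grid: np.ndarray, mean: float, sd: float, grid_ms: float
) -> np.ndarray:
    """Gaussian mass integrated over each grid cell [t - g/2, t + g/2)."""
    edges = np.concatenate([grid - grid_ms / 2.0, [grid[-1] + grid_ms / 2.0]])
    cdf = sps.norm.cdf(edges, loc=mean, scale=sd)
    return np.diff(cdf)


def _grid(bounds: tuple[float, float], grid_ms: float) -> np.ndarray:
    lo, hi = bounds
    n = int(np.floor((hi - lo) / grid_ms + 1e-9)) + 1
    return lo + grid_ms * np.arange(n)


def make_baseline(
    anchor: float,
    jitter_sd: float = BASELINE_JITTER_SD,
    grid_ms: float = 1.0,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> FPDistribution:
    """Baseline (B) distribution: a near point mass at ``anchor``.

    ``jitter_sd`` models the technical jitter of the display; 0 gives an exact
    point mass on the grid point nearest the anchor.
    """
    lo, hi = bounds
    if not (lo <= anchor <= hi):
        raise ValueError(f"anchor {anchor} outside bounds {bounds}")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    grid = _grid(bounds, grid_ms)
    if jitter_sd == 0:
        pmf = np.zeros_like(grid)
        pmf[np.argmin(np.abs(grid - anchor))] = 1.0
    else:
        pmf = _gaussian_cell_masses(grid, anchor, jitter_sd, grid_ms)
        pmf = pmf / pmf.sum()
    return FPDistribution(grid, pmf, anchor, jitter_sd, "B", bounds, grid_ms)


def make_uncertain(
    anchor: float,
    sigma: float = UNCERTAIN_SIGMA,
    grid_ms: float = 1.0,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> FPDistribution:
    """Uncertain (U) distribution: anchor convolved with a Gaussian kernel.

    The Gaussian (mean ``anchor``, SD ``sigma``) is discretised on the grid,
    truncated to ``bounds`` and renormalised.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    lo, hi = bounds
    if not (lo <= anchor <= hi):
        raise ValueError(f"anchor {anchor} outside bounds {bounds}")
    grid = _grid(bounds, grid_ms)
    pmf = _gaussian_cell_masses(grid, anchor, sigma, grid_ms)
    pmf = pmf / pmf.sum()
    return FPDistribution(grid, pmf, anchor, sigma, "U", bounds, grid_ms)


def sample_foreperiods(
    dist: FPDistribution, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. foreperiods (ms) from the distribution's pmf."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.choice(dist.support, size=n, p=dist.pmf)


def bin_edges(bounds: tuple[float, float] = DEFAULT_BOUNDS, bin_width: float = 50.0) -> np.ndarray:
    """Half-open bin edges tiling [lo, hi], anchored at the lower bound."""
    lo, hi = bounds
    n = int(np.ceil((hi - lo) / bin_width - 1e-9))
    return lo + bin_width * np.arange(n + 1)


def bin_foreperiods(
    fps,
    bin_width: float = 50.0,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> pd.DataFrame:
    """Histogram foreperiods into half-open [lo, hi) bins anchored at the range start.

    Returns a frame with ``bin_center`` and ``count`` (all bins, including empty
    ones).  The upper range bound falls into the last bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    fps = np.asarray(fps, dtype=float)
    edges = bin_edges(bounds, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    if fps.size == 0:
        return pd.DataFrame({"bin_center": centers, "count": np.zeros(len(centers), int)})
    if fps.min() < bounds[0] or fps.max() > bounds[1]:
        raise ValueError("foreperiods outside the binning range")
    # np.histogram closes the final bin on the right, matching "hi in last bin"
    counts, _ = np.histogram(fps, bins=edges)
    return pd.DataFrame({"bin_center": centers, "count": counts})
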