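"""Hazard-rate variants of a foreperiod distribution.

The hazard rate (HR) at elapsed time t is the conditional probability that the
"go" signal occurs in the current bin given it has not occurred yet:

    HR(t_i) = p_i / S(t_i),   S(t_i) = sum_{j >= i} p_j

with the survival S evaluated *before* bin i, so the hazard at the final
occupied bin is exactly 1.  Three variants are used as trial-level regressors:

* ``classic``   — the conditional probability above; grows over the foreperiod
  and peaks (HR = 1) at the longest possible "go" time.
* ``mirror``    — classic reflected about its arithmetic mean (2*mean - HR);
  decreasing trend with a local minimum near the anchor.
* ``reciprocal``— 1 / classic; steeply decreasing, used as the latency
  regressor (latency rises linearly in 1/HR).

A *subjective* hazard models temporal blurring (scalar expectancy): before the
hazard is computed, the objective pmf is convolved with a Gaussian kernel whose
SD grows linearly with elapsed time (sd = phi * t).  With blurring, probability
mass leaks toward neighbouring times, the hazard rises earlier and more
smoothly, and — under the blurring hypothesis — latency variability should
grow with elapsed time.

Hazards are computed on a binned support (50-ms bins by default, matching the
reporting convention) restricted to bins that carry probability mass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import FPDistribution, bin_edges

#: Default blur coefficient: kernel SD as a fraction of elapsed time.
DEFAULT_PHI: float = 0.26


@dataclass(frozen=True)
class HazardFunction:
    """Hazard values on a binned foreperiod support.

    ``support`` holds bin centers (ms) for bins with nonzero mass; ``edges``
    the corresponding half-open bin edges (len = len(support) + 1 is *not*
    guaranteed because occupied bins need not be contiguous; ``bin_lo`` gives
    each bin's left edge).  ``phi`` is set only for the subjective variant.
    """

    support: np.ndarray
    values: np.ndarray
    variant: str
    bin_lo: np.ndarray
    bin_width: float
    source: FPDistribution | None = None
    phi: float | None = None

    def __post_init__(self):
        if len(self.support) != len(self.values):
            raise ValueError("support/values length mismatch")

    def mean(self) -> float:
        return float(np.mean(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"duration_ms": self.support, "hazard": self.values, "variant": self.variant}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _binned_pmf(dist: FPDistribution, bin_width: float):
    """Aggregate the fine-grid pmf onto half-open bins on the absolute bin lattice.

    Edges sit at multiples of ``bin_width`` (the lattice passes through the
    1250-ms range start for 50-ms bins), so binned supports of a distribution
    and of its blurred extension stay aligned.
    """
    lo, hi = dist.bounds
    start = np.floor(lo / bin_width) * bin_width
    n = int(np.ceil((hi - start) / bin_width - 1e-9))
    edges = start + bin_width * np.arange(n + 1)
    idx = np.clip(((dist.support - start) // bin_width).astype(int), 0, n - 1)
    mass = np.bincount(idx, weights=dist.pmf, minlength=n)
    return edges, mass


def hazard_classic(dist: FPDistribution, bin_width: float = 50.0) -> HazardFunction:
    """Classic hazard on the binned support: bin mass over survival-before-bin.

    The support is restricted to bins with pmf > 0 so that all three variants
    (including the reciprocal) are well defined.  The final occupied bin has
    hazard exactly 1.
    """
    if dist.pmf.sum() <= 0:
        raise ValueError("distribution carries no mass")
    edges, mass = _binned_pmf(dist, bin_width)
    # survival before each bin, computed by reverse accumulation so the last
    # occupied bin gives S == p exactly (no cancellation)
    survival = np.cumsum(mass[::-1])[::-1]
    occupied = mass > 0
    values = mass[occupied] / survival[occupied]
    centers = ((edges[:-1] + edges[1:]) / 2.0)[occupied]
    lo_edges = edges[:-1][occupied]
    return HazardFunction(centers, values, "classic", lo_edges, bin_width, source=dist)


def hazard_mirror(h: HazardFunction) -> HazardFunction:
    """Classic hazard reflected about its arithmetic mean: 2*mean(HR) - HR."""
    if not h.variant.endswith("classic"):
        raise ValueError("mirror is defined on a classic hazard")
    return replace(h, values=2.0 * h.mean() - h.values, variant="mirror")


def hazard_reciprocal(h: HazardFunction) -> HazardFunction:
    """Pointwise reciprocal 1/HR of the classic hazard."""
    if not h.variant.endswith("classic"):
        raise ValueError("reciprocal is defined on a classic hazard")
    if np.any(h.values <= 0):
        raise ValueError("classic hazard must be > 0 on its support")
    return replace(h, values=1.0 / h.values, variant="reciprocal")


def blur_pdf(dist: FPDistribution, phi: float) -> FPDistribution:
    """Convolve the pmf with a Gaussian kernel whose SD grows with elapsed time.

    Each source mass point at time tau is spread as N(mean=tau, sd=phi*tau);
    the result is re-discretised on a 1-grid_ms extension of the support and
    renormalised.  phi -> 0 recovers the input.
    """
    if phi <= 0:
        raise ValueError("phi must be > 0")
    g = dist.grid_ms
    src_t = dist.support[dist.pmf > 0]
    src_p = dist.pmf[dist.pmf > 0]
    max_sd = phi * src_t.max()
    lo = max(g, np.floor(src_t.min() - 6 * max_sd))
    hi = np.ceil(src_t.max() + 6 * max_sd)
    out_grid = np.arange(lo, hi + g / 2, g)
    out_edges = np.concatenate([out_grid - g / 2, [out_grid[-1] + g / 2]])
    out = np.zeros(len(out_grid))
    # integrate each source kernel over the destination cells (exact at any sd,
    # including sd << grid); chunked to bound the intermediate matrix size
    for start in range(0, len(src_t), 256):
        t = src_t[start : start + 256, None]
        p = src_p[start : start + 256, None]
        cdf = sps.norm.cdf(out_edges[None, :], loc=t, scale=phi * t)
        out += (p * np.diff(cdf, axis=1)).sum(axis=0)
    out = out / out.sum()
    return FPDistribution(
        out_grid, out, dist.anchor, dist.sigma, dist.kind,
        bounds=(float(out_grid[0]), float(out_grid[-1])), grid_ms=g,
    )


def subjective_hazard(
    dist: FPDistribution, phi: float = DEFAULT_PHI, bin_width: float = 50.0
) -> HazardFunction:
    """Classic hazard of the blurred (subjective) distribution."""
    blurred = blur_pdf(dist, phi)
    h = hazard_classic(blurred, bin_width)
    return replace(h, variant="subjective_classic", phi=phi)


def hazard_at(h: HazardFunction, fp) -> np.ndarray | float:
    """Hazard value of the bin containing ``fp`` (half-open [lo, lo + width) bins).

    Raises if any fp falls outside the occupied support.
    """
    fp_arr = np.atleast_1d(np.asarray(fp, dtype=float))
    lo = h.bin_lo
    # the overall upper edge belongs to the last bin (same convention as the
    # foreperiod histogram, where the range maximum closes the final bin)
    top = lo[-1] + h.bin_width
    fp_eff = np.where(fp_arr == top, np.nextafter(top, -np.inf), fp_arr)
    idx = np.searchsorted(lo, fp_eff, side="right") - 1
    clipped = np.clip(idx, 0, len(lo) - 1)
    bad = (idx < 0) | (fp_eff >= lo[clipped] + h.bin_width)
    if np.any(bad):
        raise ValueError(
            f"foreperiod(s) {fp_arr[bad]} outside hazard support "
            f"[{lo[0]}, {lo[-1] + h.bin_width})"
        )
    out = h.values[idx]
    return out if np.ndim(fp) else float(out[0])
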