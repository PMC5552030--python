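"""The community-elevation proportion matrix.

For each community the within-community elevation distribution is smoothed
with a Gaussian kernel density estimate; at each discretized elevation step
``e`` (default 0.001 m) the matrix row holds the abundance-weighted
posterior

    proportion(c | e) = n_c * f_c(e) / sum_j n_j * f_j(e),

where ``f_c`` is community ``c``'s KDE and ``n_c`` its pixel count.  Rows
with any support sum to one; rows where every density underflows are filled
from the nearest step with support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

_SQRT2PI = math.sqrt(2.0 * math.pi)


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule bandwidth ``(3n/4)^(-1/5) * sd`` (sd with ddof=1)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise InputError("need at least 2 points for a bandwidth")
    return float((3.0 * n / 4.0) ** (-0.2) * np.std(x, ddof=1))


def gaussian_kde_grid(x: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    """Exact sum-over-kernels Gaussian KDE of sample ``x`` on ``grid``.

    Evaluated in chunks so memory stays bounded for large samples.
    """
    x = np.asarray(x, dtype=float)
    grid = np.asarray(grid, dtype=float)
    n = x.size
    out = np.empty(grid.size)
    chunk = max(1, int(4_000_000 / max(n, 1)))
    for s in range(0, grid.size, chunk):
        g = grid[s:s + chunk]
        z = (g[:, None] - x[None, :]) / h
        out[s:s + chunk] = np.exp(-0.5 * z * z).sum(axis=1)
    return out / (n * h * _SQRT2PI)


@dataclass
class CommunityElevationMatrix:
    """Discretized elevation steps x community proportions."""

    steps: np.ndarray          # strictly increasing, constant spacing
    proportions: np.ndarray    # (n_steps, k), rows sum to 1
    communities: tuple[str, ...]
    counts: np.ndarray         # per-community pixel counts (priors)
    bandwidths: np.ndarray     # per-community KDE bandwidths (m)
    step: float

    def row_index(self, elevation) -> np.ndarray:
        """Snap elevations to the nearest step (ties toward +inf), clamped."""
        e = np.asarray(elevation, dtype=float)
        if np.any(np.isnan(e)):
            raise ValueError("NaN elevation")
        idx = np.floor((e - self.steps[0]) / self.step + 0.5).astype(int)
        return np.clip(idx, 0, self.steps.size - 1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.proportions, columns=list(self.communities))
        df.insert(0, "elevation", self.steps)
        return df

    def to_csv(self, path, float_format: str = "%.10g") -> None:
        self.to_frame().to_csv(path, index=False, float_format=float_format)


def build_matrix(pixels: pd.DataFrame, step: float = 0.001,
                 bandwidth="silverman") -> CommunityElevationMatrix:
    """Build the community-elevation proportion matrix from a pixel table.

    Parameters
    ----------
    pixels
        Pixel table with ``elevation`` and categorical ``community`` columns.
    step
        Elevation discretization (m).  The grid spans the pixel elevation
        range padded by three times the widest bandwidth, snapped to the
        step lattice.
    bandwidth
        ``"silverman"`` or a fixed bandwidth in meters applied to every
        community.
    """
    if step <= 0:
        raise InputError("step must be positive")
    if pixels.empty:
        raise InputError("empty pixel table")
    communities = tuple(pixels["community"].cat.categories)
    groups = {
        c: pixels.loc[pixels["community"] == c, "elevation"].to_numpy()
        for c in communities
    }
    present = [c for c in communities if groups[c].size >= 2]
    if not present:
        raise InputError("no community has >= 2 pixels")

    bw = np.zeros(len(communities))
    for i, c in enumerate(communities):
        if groups[c].size >= 2:
            bw[i] = (silverman_bandwidth(groups[c])
                     if bandwidth == "silverman" else float(bandwidth))
    pad = 3.0 * bw.max()
    e = pixels["elevation"].to_numpy()
    lo = math.floor((e.min() - pad) / step) * step
    hi = math.ceil((e.max() + pad) / step) * step
    n_steps = int(round((hi - lo) / step)) + 1
    steps = lo + step * np.arange(n_steps)

    weighted = np.zeros((n_steps, len(communities)))
    counts = np.zeros(len(communities))
    for i, c in enumerate(communities):
        x = groups[c]
        counts[i] = x.size
        if x.size >= 2:
            weighted[:, i] = x.size * gaussian_kde_grid(x, steps, bw[i])

    totals = weighted.sum(axis=1)
    has_support = totals > 0.0
    props = np.zeros_like(weighted)
    props[has_support] = weighted[has_support] / totals[has_support, None]
    if not has_support.all():
        # fill underflow rows from the nearest step with support
        support_idx = np.nonzero(has_support)[0]
        missing = np.nonzero(~has_support)[0]
        pos = np.searchsorted(support_idx, missing)
        pos = np.clip(pos, 0, support_idx.size - 1)
        left = support_idx[np.maximum(pos - 1, 0)]
        right = support_idx[pos]
        nearest = np.where(
            np.abs(steps[missing] - steps[left])
            <= np.abs(steps[right] - steps[missing]),
            left, right,
        )
        props[missing] = props[nearest]

    return CommunityElevationMatrix(
        steps=steps, proportions=props, communities=communities,
        counts=counts, bandwidths=bw, step=step,
    )


def lookup_row(matrix: CommunityElevationMatrix, elevation) -> np.ndarray:
    """Return the proportion row(s) for an elevation (nearest-step snap).

    Elevations above/below the grid return the top/bottom row.  Scalar in,
    1-D row out; array in, 2-D rows out.
    """
    idx = matrix.row_index(elevation)
    return matrix.proportions[idx]
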