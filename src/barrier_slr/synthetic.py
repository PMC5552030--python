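"""Synthetic barrier-island landscapes with the structure the model assumes.

The generator emulates a gently sloping ridge/swale landscape in which
vegetation communities segregate along the elevation gradient:

1. an elevation surface with spatial autocorrelation is built by smoothing
   white noise with a moving-average kernel and rank-mapping the result onto
   the target marginal elevation distribution (a community-weighted mixture
   of per-community normals plus a sub-MLW sea-floor tail);
2. each cell at or above the open-water threshold is assigned a community by
   the exact elevation-conditioned posterior
   ``p(c | e) \\propto weight_c * density_c(e)``; cells below the threshold
   become open water.

Per-community elevation distributions default to the published stratum
means/SDs; salt marsh and freshwater wetland optionally carry a second mode
so their profiles are bimodal.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

from . import communities as comm
from .errors import ConfigError
from .grid_io import IDENTITY_TRANSFORM, LandscapeGrid

# Second-mode defaults for the bimodal communities.  The bimodality itself is
# an observed feature; these mode locations/weights are arbitrary plausible
# choices (no published values exist) and are meant only to produce two
# well-separated elevation peaks.
_DUAL_MODE = {
    "SMAR": ((0.00, 0.22), (0.75, 0.25), 0.35),  # (m1,s1), (m2,s2), w2
    "FWET": ((0.40, 0.30), (1.40, 0.32), 0.40),
}


@dataclass(frozen=True)
class CommunityMixture:
    """One- or two-component normal elevation distribution (m MLHW)."""

    mean: float
    sd: float
    second_mode: tuple[float, float, float] | None = None  # (mean, sd, weight)

    def __post_init__(self):
        if self.sd <= 0:
            raise ConfigError("sd must be positive")
        if self.second_mode is not None:
            m2, s2, w2 = self.second_mode
            if s2 <= 0 or not 0.0 <= w2 <= 1.0:
                raise ConfigError("invalid second mode")

    def pdf(self, e):
        e = np.asarray(e, dtype=float)
        if self.second_mode is None:
            return stats.norm.pdf(e, self.mean, self.sd)
        m2, s2, w2 = self.second_mode
        return (1.0 - w2) * stats.norm.pdf(e, self.mean, self.sd) + \
            w2 * stats.norm.pdf(e, m2, s2)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.second_mode is None:
            return rng.normal(self.mean, self.sd, size=n)
        m2, s2, w2 = self.second_mode
        pick2 = rng.random(n) < w2
        out = rng.normal(self.mean, self.sd, size=n)
        n2 = int(pick2.sum())
        out[pick2] = rng.normal(m2, s2, size=n2)
        return out

    def expected_mean(self) -> float:
        if self.second_mode is None:
            return self.mean
        m2, _, w2 = self.second_mode
        return (1.0 - w2) * self.mean + w2 * m2

    def truncated_mean(self, lower: float) -> float:
        """Mean conditional on elevation >= ``lower`` (closed form)."""
        comps = [(self.mean, self.sd, 1.0)]
        if self.second_mode is not None:
            m2, s2, w2 = self.second_mode
            comps = [(self.mean, self.sd, 1.0 - w2), (m2, s2, w2)]
        num = 0.0
        den = 0.0
        for m, s, w in comps:
            a = (lower - m) / s
            tail = stats.norm.sf(a)
            num += w * tail * (m + s * stats.norm.pdf(a) / tail)
            den += w * tail
        return num / den

    def mass_above(self, lower: float) -> float:
        comps = [(self.mean, self.sd, 1.0)]
        if self.second_mode is not None:
            m2, s2, w2 = self.second_mode
            comps = [(self.mean, self.sd, 1.0 - w2), (m2, s2, w2)]
        return sum(w * stats.norm.sf((lower - m) / s) for m, s, w in comps)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic landscape generator."""

    mixtures: dict[str, CommunityMixture]
    weights: dict[str, float]
    shape: tuple[int, int] = (200, 200)
    smoothing_length: int = 5
    seed: int = 0
    sea_floor_fraction: float = 0.15
    sea_floor_range: tuple[float, float] = (-1.5, -0.2)
    water_level: float = -comm.MLW_OFFSET
    cell_size: float = 3.0

    def __post_init__(self):
        if set(self.mixtures) != set(self.weights):
            raise ConfigError("mixtures and weights must cover the same communities")
        w = np.array(list(self.weights.values()), dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-8):
            raise ConfigError("weights must be non-negative and sum to 1")
        if w.sum() == 0 or np.all(w == 0):
            raise ConfigError("all community weights are zero")
        if not 0.0 <= self.sea_floor_fraction < 1.0:
            raise ConfigError("sea_floor_fraction must be in [0, 1)")
        if self.smoothing_length < 1:
            raise ConfigError("smoothing_length must be >= 1")

    @property
    def communities(self) -> tuple[str, ...]:
        return tuple(self.mixtures)

    @classmethod
    def default(cls, dual_peaks: bool = True, **overrides) -> "SyntheticConfig":
        """Default nine-community configuration.

        ``dual_peaks=True`` replaces the salt-marsh and freshwater-wetland
        single normals with two-mode mixtures; ``False`` keeps every
        community at its published single-mode mean/SD (the configuration
        used for regression fixtures).
        """
        mixtures = {}
        for c in comm.COMMUNITIES:
            if dual_peaks and c in _DUAL_MODE:
                (m1, s1), (m2, s2), w2 = _DUAL_MODE[c]
                mixtures[c] = CommunityMixture(m1, s1, (m2, s2, w2))
            else:
                mixtures[c] = CommunityMixture(comm.DEFAULT_MEAN[c],
                                               comm.DEFAULT_SD[c])
        return cls(mixtures=mixtures, weights=dict(comm.DEFAULT_WEIGHT),
                   **overrides)


def _posterior(config: SyntheticConfig, e: np.ndarray) -> np.ndarray:
    """Exact posterior p(community | elevation), shape (len(e), k)."""
    dens = np.column_stack([
        config.weights[c] * config.mixtures[c].pdf(e)
        for c in config.communities
    ])
    total = dens.sum(axis=1, keepdims=True)
    total[total == 0.0] = 1.0
    return dens / total


def land_weights(config: SyntheticConfig) -> dict[str, float]:
    """Expected community frequencies among land cells.

    Community assignment applies only at/above the open-water threshold, so
    land-cell frequencies are the configured weights scaled by each
    community's probability mass above that threshold.
    """
    raw = {
        c: config.weights[c] * config.mixtures[c].mass_above(config.water_level)
        for c in config.communities
    }
    tot = sum(raw.values())
    return {c: v / tot for c, v in raw.items()}


def generate_landscape(config: SyntheticConfig) -> LandscapeGrid:
    """Generate an aligned elevation + community grid (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    nrow, ncol = config.shape
    n = nrow * ncol

    # spatially autocorrelated field -> ranks
    noise = rng.standard_normal((nrow, ncol))
    if config.smoothing_length > 1:
        noise = ndimage.uniform_filter(noise, size=config.smoothing_length,
                                       mode="reflect")
    order = np.argsort(noise.ravel(), kind="stable")

    # target marginal: sea-floor tail + community-weighted normal mixture
    k = len(config.communities)
    probs = np.empty(k + 1)
    probs[0] = config.sea_floor_fraction
    probs[1:] = (1.0 - config.sea_floor_fraction) * comm.weight_array(
        config.weights, config.communities
    )
    comp = rng.choice(k + 1, size=n, p=probs)
    values = np.empty(n)
    sea = comp == 0
    lo, hi = config.sea_floor_range
    values[sea] = rng.uniform(lo, hi, size=int(sea.sum()))
    for i, c in enumerate(config.communities, start=1):
        m = comp == i
        values[m] = config.mixtures[c].rvs(int(m.sum()), rng)

    elev = np.empty(n)
    elev[order] = np.sort(values)
    elev = elev.reshape(nrow, ncol)

    # label: open water below threshold, else posterior draw
    community = np.full((nrow, ncol), comm.WATER, dtype="U16")
    land = elev >= config.water_level
    e_land = elev[land]
    post = _posterior(config, e_land)
    cum = np.cumsum(post, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(e_land.size)
    pick = (cum <= u[:, None]).sum(axis=1)
    pick = np.minimum(pick, k - 1)
    labels = np.array(config.communities, dtype="U16")[pick]
    community[land] = labels

    return LandscapeGrid(
        elevation=elev,
        community=community,
        cell_size=config.cell_size,
        datum_offset_mlhw=0.0,
        transform=(0.0, config.cell_size, 0.0, 0.0, 0.0, -config.cell_size),
        crs="synthetic",
        classes=config.communities,
    )


def sample_community_elevations(community: str, n: int,
                                config: SyntheticConfig | None = None,
                                seed: int = 0) -> np.ndarray:
    """Draw ``n`` iid elevations from one community's generating mixture."""
    if config is None:
        config = SyntheticConfig.default()
    if community not in config.mixtures:
        raise ConfigError(f"unknown community {community!r}")
    rng = np.random.default_rng(seed)
    return config.mixtures[community].rvs(int(n), rng)


def iid_pixel_sample(n: int, config: SyntheticConfig | None = None,
                     seed: int = 0, extent: float = 3000.0):
    """Simulate an iid pixel subsample: communities allocated by landscape
    weights, elevations drawn from each community's mixture, coordinates
    uniform in an ``extent`` x ``extent`` m box (no spatial correlation).

    Returns a pixel-table-style DataFrame usable by the regression module.
    """
    import pandas as pd

    if config is None:
        config = SyntheticConfig.default(dual_peaks=False)
    rng = np.random.default_rng(seed)
    cs = list(config.communities)
    w = comm.weight_array(config.weights, tuple(cs))
    idx = rng.choice(len(cs), size=n, p=w)
    elev = np.empty(n)
    for i, c in enumerate(cs):
        m = idx == i
        elev[m] = config.mixtures[c].rvs(int(m.sum()), rng)
    return pd.DataFrame(
        {
            "x": rng.uniform(0, extent, n),
            "y": rng.uniform(0, extent, n),
            "elevation": elev,
            "community": pd.Categorical(
                np.array(cs, dtype=object)[idx], categories=cs
            ),
        }
    )
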