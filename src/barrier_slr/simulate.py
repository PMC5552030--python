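"""Stochastic community-change simulation across sea-level-rise scenarios.

Each scenario shifts every pixel's relative elevation down by the rise,
sends pixels below mean lagoon water (MLW, ``mlw_offset`` m below MLHW) to
the absorbing open-water state, and redraws every remaining pixel's
community from the multinomial row of the community-elevation proportion
matrix at its new elevation.  Classification is independent per pixel: the
model is aspatial and describes the collective behavior of the landscape,
not the fate of individual locations.

Randomness: a replicate with seed ``s`` draws one uniform variate per
non-absorbed pixel, in pixel-table order, from ``numpy`` Generator ``s``;
the community with the first cumulative row proportion exceeding the
variate is selected.  Replicate ``r`` of a batch uses ``base_seed + r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .communities import ABSORBED, MLW_OFFSET
from .errors import InputError
from .matrix import CommunityElevationMatrix, lookup_row


@dataclass(frozen=True)
class SLRScenario:
    """One sea-level-rise scenario (meters of rise; MLW offset below MLHW)."""

    rise: float = 0.0
    mlw_offset: float = MLW_OFFSET

    def __post_init__(self):
        if self.rise < 0:
            raise InputError("rise must be >= 0")
        if not self.mlw_offset > 0:
            raise InputError("mlw_offset must be positive")

    @property
    def label(self) -> str:
        return f"rise_{self.rise:g}"


#: Default scenario ladder: no change plus the three projected rises (m).
DEFAULT_RISES = (0.0, 0.2, 0.4, 1.2)


def shift_elevation(elevation_mlhw, scenario: SLRScenario):
    """New relative elevation after the rise: ``elevation - rise``."""
    return np.asarray(elevation_mlhw, dtype=float) - scenario.rise


def _draw(rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Vectorized multinomial draw: first index whose cumulative proportion
    exceeds the uniform variate."""
    cum = np.cumsum(rows, axis=1)
    cum[:, -1] = 1.0
    pick = (cum <= u[:, None]).sum(axis=1)
    return np.minimum(pick, rows.shape[1] - 1)


def classify_pixel(elevation_mlhw: float, matrix: CommunityElevationMatrix,
                   scenario: SLRScenario, rng: np.random.Generator) -> str:
    """Classify one pixel at its post-rise elevation.

    Deterministically ``ABSORBED`` below MLW, otherwise one multinomial draw
    from the matrix row at the shifted elevation.
    """
    e = float(shift_elevation(elevation_mlhw, scenario))
    if e < -scenario.mlw_offset:
        return ABSORBED
    row = lookup_row(matrix, e)
    i = int(_draw(row[None, :], rng.random(1))[0])
    return matrix.communities[i]


@dataclass
class SimulationResult:
    """One replicate: transition contingency and final proportions."""

    contingency: pd.DataFrame      # from-community x (communities + ABSORBED)
    proportions_total: pd.Series   # final counts / all input pixels
    proportions_remaining: pd.Series  # final counts / non-absorbed pixels
    absorbed: int
    seed: int
    scenario: SLRScenario


def run_simulation(pixels: pd.DataFrame, matrix: CommunityElevationMatrix,
                   scenario: SLRScenario, seed: int) -> SimulationResult:
    """Run one replicate over every pixel (deterministic given seed).

    Pixels already below MLW at input are excluded rather than counted as
    transitions; the simulation models the landscape above the open-water
    boundary.
    """
    if pixels.empty:
        raise InputError("empty pixel table")
    communities = list(matrix.communities)
    k = len(communities)
    keep = pixels["elevation"].to_numpy() >= -scenario.mlw_offset
    pixels = pixels.loc[keep]
    if pixels.empty:
        raise InputError("no input pixels above MLW")
    n = len(pixels)

    e_new = shift_elevation(pixels["elevation"].to_numpy(), scenario)
    from_codes = pd.Categorical(pixels["community"],
                                categories=communities).codes.astype(int)
    absorbed_mask = e_new < -scenario.mlw_offset
    land_idx = np.nonzero(~absorbed_mask)[0]

    rng = np.random.default_rng(seed)
    to_codes = np.full(n, k, dtype=int)  # k == ABSORBED column
    if land_idx.size:
        rows = lookup_row(matrix, e_new[land_idx])
        u = rng.random(land_idx.size)
        to_codes[land_idx] = _draw(rows, u)

    cont = np.zeros((k, k + 1), dtype=np.int64)
    np.add.at(cont, (from_codes, to_codes), 1)
    cont_df = pd.DataFrame(cont, index=communities,
                           columns=communities + [ABSORBED])
    final = cont[:, :k].sum(axis=0)
    absorbed = int(absorbed_mask.sum())
    remaining = n - absorbed
    prop_total = pd.Series(final / n, index=communities)
    prop_remaining = pd.Series(
        final / remaining if remaining else np.zeros(k), index=communities
    )
    return SimulationResult(
        contingency=cont_df, proportions_total=prop_total,
        proportions_remaining=prop_remaining, absorbed=absorbed,
        seed=seed, scenario=scenario,
    )


@dataclass
class ReplicateResult:
    """Replicate batch for one scenario: raw proportions plus summaries."""

    scenario: SLRScenario
    communities: tuple[str, ...]
    replicates_total: np.ndarray       # (n_reps, k)
    replicates_remaining: np.ndarray   # (n_reps, k)
    contingency_mean: pd.DataFrame     # mean counts across replicates
    absorbed: int                      # identical across replicates
    n_pixels: int
    base_seed: int

    @property
    def n_reps(self) -> int:
        return self.replicates_total.shape[0]

    def summary(self, basis: str = "total") -> pd.DataFrame:
        """Median and central-95% endpoints of final proportions."""
        arr = {"total": self.replicates_total,
               "remaining": self.replicates_remaining}[basis]
        q = np.percentile(arr, [2.5, 50.0, 97.5], axis=0)
        return pd.DataFrame(
            {"lo2.5": q[0], "median": q[1], "hi97.5": q[2]},
            index=list(self.communities),
        )

    def interval_width(self, basis: str = "total") -> pd.Series:
        s = self.summary(basis)
        return s["hi97.5"] - s["lo2.5"]


def replicate_simulations(pixels: pd.DataFrame,
                          matrix: CommunityElevationMatrix,
                          scenario: SLRScenario, n_reps: int = 1000,
                          base_seed: int = 0) -> ReplicateResult:
    """Run ``n_reps`` replicates (seeds ``base_seed + r``) of one scenario."""
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    k = len(matrix.communities)
    tot = np.empty((n_reps, k))
    rem = np.empty((n_reps, k))
    cont_sum = None
    absorbed = 0
    n_pixels = 0
    for r in range(n_reps):
        res = run_simulation(pixels, matrix, scenario, seed=base_seed + r)
        tot[r] = res.proportions_total.to_numpy()
        rem[r] = res.proportions_remaining.to_numpy()
        cont_sum = res.contingency if cont_sum is None else cont_sum + res.contingency
        absorbed = res.absorbed
        n_pixels = int(res.contingency.to_numpy().sum())
    return ReplicateResult(
        scenario=scenario, communities=matrix.communities,
        replicates_total=tot, replicates_remaining=rem,
        contingency_mean=cont_sum / n_reps, absorbed=absorbed,
        n_pixels=n_pixels, base_seed=base_seed,
    )


#: Subsample sizes explored by the sensitivity analysis.
DEFAULT_SUBSAMPLE_SIZES = (10**6, 10**5, 10**4, 500, 250)


def subsample_sensitivity(pixels: pd.DataFrame,
                          matrix: CommunityElevationMatrix,
                          scenarios, sizes=DEFAULT_SUBSAMPLE_SIZES,
                          reps: int = 500, base_seed: int = 0
                          ) -> dict[int, dict[str, ReplicateResult]]:
    """Replicate batches on random pixel subsamples of decreasing size.

    For each size a subsample is drawn without replacement (fresh seed per
    size); the proportion matrix is *not* rebuilt.  Sizes exceeding the
    pixel count are skipped with a warning.  Returns
    ``{size: {scenario label: ReplicateResult}}``.
    """
    import warnings

    out: dict[int, dict[str, ReplicateResult]] = {}
    n = len(pixels)
    for j, size in enumerate(sizes):
        if size > n:
            warnings.warn(f"subsample size {size} exceeds pixel count {n}; "
                          "skipped", stacklevel=2)
            continue
        rng = np.random.default_rng(base_seed + 10_000 * (j + 1))
        idx = rng.choice(n, size=size, replace=False)
        sub = pixels.iloc[np.sort(idx)]
        out[size] = {
            sc.label: replicate_simulations(sub, matrix, sc, n_reps=reps,
                                            base_seed=base_seed)
            for sc in scenarios
        }
    return out
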