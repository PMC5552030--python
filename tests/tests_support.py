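"""Shared synthetic fixtures for the regression tests."""

import numpy as np
import pandas as pd


def spatial_two_community_sample(seed, n=150, r_true=40.0, extent=300.0,
                                 sigmas=(0.5, 1.3), means=(0.3, 1.5)):
    """Two-community elevations with exponential spatial correlation.

    Returns ``(frame, D, comm, y)`` where ``frame`` is a pixel-table-style
    DataFrame and ``D`` the dense distance matrix (for likelihood oracles).
    """
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, extent, (n, 2))
    comm = np.where(rng.random(n) < 0.5, "A", "B")
    sig = np.where(comm == "A", sigmas[0], sigmas[1])
    mu = np.where(comm == "A", means[0], means[1])
    D = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    L = np.linalg.cholesky(np.exp(-D / r_true) + 1e-10 * np.eye(n))
    y = mu + sig * (L @ rng.standard_normal(n))
    frame = pd.DataFrame({
        "x": xy[:, 0], "y": xy[:, 1], "elevation": y,
        "community": pd.Categorical(comm, categories=["A", "B"]),
    })
    return frame, D, comm, y
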