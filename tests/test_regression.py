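import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import barrier_slr as b
from barrier_slr.errors import InputError
from barrier_slr.matrix import silverman_bandwidth


def _frame(x, y, elev, comm, cats=None):
    return pd.DataFrame({
        "x": x, "y": y, "elevation": elev,
        "community": pd.Categorical(comm, categories=cats or
                                    sorted(set(comm))),
    })


from tests_support import spatial_two_community_sample as _spatial_sample


def test_constant_single_community_is_exact():
    df = _frame(np.arange(5.0), np.zeros(5), np.full(5, 1.0), ["A"] * 5)
    fit = b.fit_stratified_gls(df, correlation="none")
    assert fit.table.loc["A", "mean"] == 1.0
    assert fit.table.loc["A", "sd"] == 0.0


@pytest.mark.parametrize("ll_null,ll_fit,n,expected", [
    (-100.0, -100.0, 50, 0.0),
    (-150.0, -150.0, 100, 0.0),
    # frozen from a direct evaluation of the closed form
    (-150.0, -50.0, 100, 0.9099694268296196),
])
def test_nagelkerke_values(ll_null, ll_fit, n, expected):
    assert b.nagelkerke_r2(ll_fit, ll_null, n) == pytest.approx(expected,
                                                                abs=1e-12)


def test_nagelkerke_domain():
    with pytest.raises(ValueError):
        b.nagelkerke_r2(-1.0, -2.0, 0)
    with pytest.warns(UserWarning):
        b.nagelkerke_r2(-3.0, -2.0, 10)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(ll_null=st.floats(-500, -10), frac=st.floats(0, 0.999),
       n=st.integers(2, 5000))
def test_nagelkerke_in_unit_interval(ll_null, frac, n):
    """For fitted likelihoods below one the index stays in [0, 1)."""
    r2 = b.nagelkerke_r2(ll_null * (1.0 - frac), ll_null, n)
    assert 0.0 <= r2 < 1.0


def test_iid_recovery_single_dataset():
    """One iid draw at the default community parameters: most generating
    means fall inside their fitted 95% CIs and the stratified model beats
    the single-mean null."""
    df = b.iid_pixel_sample(2000, seed=42)
    fit = b.fit_stratified_gls(df, correlation="none")
    from barrier_slr.communities import DEFAULT_MEAN
    hits = sum(
        fit.table.loc[c, "ci_lo"] <= DEFAULT_MEAN[c] <= fit.table.loc[c, "ci_hi"]
        for c in fit.table.index
    )
    assert hits >= 7
    assert fit.loglik >= fit.loglik_null
    assert 0 <= fit.r2 < 1


def test_spatial_ml_matches_brute_force_grid():
    """At small n the exponential-correlation ML fit attains (or beats) the
    best point of a dense grid search over (range, sigma_A, sigma_B) with
    the exact multivariate-normal likelihood."""
    df, D, comm, y = _spatial_sample(seed=7)
    n = len(y)
    fit = b.fit_stratified_gls(df)
    X = np.column_stack([comm == "A", comm == "B"]).astype(float)

    def neg2ll(rr, s1, s2):
        s = np.where(comm == "A", s1, s2)
        Sig = np.outer(s, s) * np.exp(-D / rr)
        np.fill_diagonal(Sig, s ** 2)
        L = np.linalg.cholesky(Sig)
        Xi = np.linalg.solve(L, X)
        yi = np.linalg.solve(L, y)
        mu = np.linalg.lstsq(Xi, yi, rcond=None)[0]
        res = yi - Xi @ mu
        return n * np.log(2 * np.pi) + 2 * np.log(np.diag(L)).sum() + res @ res

    grid_best = min(
        neg2ll(rr, s1, s2)
        for rr in np.exp(np.linspace(np.log(5), np.log(200), 21))
        for s1 in np.linspace(0.3, 0.9, 13)
        for s2 in np.linspace(0.8, 2.0, 13)
    )
    assert -2 * fit.loglik <= grid_best + 0.5
    assert 5 < fit.range_m < 200


def test_spatial_range_recovery():
    df, *_ = _spatial_sample(seed=19, n=200)
    fit = b.fit_stratified_gls(df)
    assert 10 < fit.range_m < 160  # true range 40 m


def test_zero_correlation_estimates_negligible_range():
    """On iid data the estimated range implies correlation < 0.05 at the
    median inter-pixel distance."""
    df = b.iid_pixel_sample(400, seed=3)
    fit = b.fit_stratified_gls(df)
    from scipy.spatial.distance import pdist
    d_med = np.median(pdist(df[["x", "y"]].to_numpy()))
    assert np.exp(-d_med / fit.range_m) < 0.05


def test_likelihood_improves_over_null_across_seeds():
    for seed in range(5):
        df = b.iid_pixel_sample(800, seed=seed)
        fit = b.fit_stratified_gls(df, correlation="none")
        assert fit.loglik >= fit.loglik_null


def test_singleton_stratum_flagged_unidentifiable():
    df = _frame([0, 1, 2, 3, 4], [0, 0, 0, 0, 0],
                [1.0, 1.2, 0.8, 1.1, 5.0],
                ["A", "A", "A", "A", "B"], cats=["A", "B"])
    fit = b.fit_stratified_gls(df, correlation="none")
    assert not fit.table.loc["B", "identifiable"]
    assert np.isnan(fit.table.loc["B", "sd"])
    assert fit.table.loc["A", "identifiable"]


def test_input_guards():
    df = _frame([0.0], [0.0], [1.0], ["A"])
    with pytest.raises(InputError):
        b.fit_stratified_gls(df)
    big = b.iid_pixel_sample(50, seed=0)
    with pytest.raises(InputError):
        b.fit_stratified_gls(big, max_n=10)


def test_density_profile_peak_and_normalization():
    rng = np.random.default_rng(1)
    x = rng.normal(1.0, 0.1, 10**4)
    df = _frame(np.zeros_like(x), np.zeros_like(x), x, ["A"] * x.size)
    prof = b.elevation_density_profiles(df)
    grid = prof["elevation"].to_numpy()
    dens = prof["A"].to_numpy()
    assert abs(grid[np.argmax(dens)] - 1.0) < 0.05
    assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)


def test_density_profile_dual_peaks():
    """The bimodal salt-marsh generator yields a profile with two local
    maxima."""
    cfg = b.SyntheticConfig.default(dual_peaks=True)
    x = b.sample_community_elevations("SMAR", 20000, config=cfg, seed=2)
    df = _frame(np.zeros_like(x), np.zeros_like(x), x, ["SMAR"] * x.size)
    prof = b.elevation_density_profiles(df, n_grid=400)
    d = prof["SMAR"].to_numpy()
    peaks = [i for i in range(1, len(d) - 1)
             if d[i] > d[i - 1] and d[i] >= d[i + 1] and d[i] > 0.1 * d.max()]
    assert len(peaks) >= 2


def test_density_profile_matches_naive_kde_oracle():
    rng = np.random.default_rng(4)
    x = rng.normal(0.5, 0.3, 500)
    df = _frame(np.zeros_like(x), np.zeros_like(x), x, ["A"] * x.size)
    prof = b.elevation_density_profiles(df, n_grid=100)
    h = silverman_bandwidth(x)
    grid = prof["elevation"].to_numpy()
    naive = np.array([
        sum(np.exp(-0.5 * ((g - xi) / h) ** 2) for xi in x)
        / (x.size * h * np.sqrt(2 * np.pi))
        for g in grid
    ])
    np.testing.assert_allclose(prof["A"].to_numpy(), naive, rtol=1e-9)


def test_density_profile_skips_empty_community():
    x = np.array([0.1, 0.2, 0.3])
    df = _frame(np.zeros(3), np.zeros(3), x, ["A"] * 3, cats=["A", "B"])
    with pytest.warns(UserWarning):
        prof = b.elevation_density_profiles(df)
    assert "B" not in prof.columns
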