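import numpy as np
import pandas as pd
import pytest

import barrier_slr as b
from barrier_slr.communities import ABSORBED
from barrier_slr.errors import InputError


def _pixels(elev, comm, cats):
    e = np.asarray(elev, dtype=float)
    return pd.DataFrame({
        "elevation": e,
        "community": pd.Categorical(comm, categories=list(cats)),
    })


@pytest.mark.parametrize("elev,rise,expected", [
    (1.2, 0.2, 1.0),   # the documented worked example
    (0.7, 0.0, 0.7),
    (0.1, 1.2, -1.1),
])
def test_shift_elevation(elev, rise, expected):
    assert b.shift_elevation(elev, b.SLRScenario(rise)) == pytest.approx(
        expected, abs=1e-15)


def test_scenario_validation():
    with pytest.raises(InputError):
        b.SLRScenario(-0.1)
    with pytest.raises(InputError):
        b.SLRScenario(0.2, mlw_offset=0.0)


def test_below_mlw_is_absorbed(small_matrix):
    rng = np.random.default_rng(0)
    assert b.classify_pixel(-0.25, small_matrix, b.SLRScenario(0.0),
                            rng) == ABSORBED
    # exactly at MLW stays in play
    out = b.classify_pixel(-0.2, small_matrix, b.SLRScenario(0.0), rng)
    assert out in small_matrix.communities


def test_degenerate_matrix_is_deterministic():
    rng0 = np.random.default_rng(1)
    px = _pixels(rng0.normal(1.0, 0.2, 300), ["A"] * 300, ["A"])
    m = b.build_matrix(px, step=0.01)
    rng = np.random.default_rng(2)
    for _ in range(10):
        assert b.classify_pixel(1.0, m, b.SLRScenario(0.0), rng) == "A"


def test_classification_frequencies_match_row(small_matrix):
    """Repeated draws at one elevation reproduce the matrix row within
    binomial error."""
    n = 20000
    px = _pixels(np.full(n, 0.6), ["SMAR"] * n, small_matrix.communities)
    res = b.run_simulation(px, small_matrix, b.SLRScenario(0.0), seed=11)
    row = b.lookup_row(small_matrix, 0.6)
    for i, c in enumerate(small_matrix.communities):
        p = row[i]
        se = np.sqrt(p * (1 - p) / n)
        assert abs(res.proportions_total[c] - p) <= 4 * se + 1e-9, c


def test_total_inundation(small_pixels, small_matrix):
    res = b.run_simulation(small_pixels, small_matrix, b.SLRScenario(20.0),
                           seed=0)
    assert res.absorbed == len(
        small_pixels[small_pixels["elevation"] >= -0.2])
    assert (res.proportions_total == 0).all()


def test_empty_input_rejected(small_matrix):
    with pytest.raises(InputError):
        b.run_simulation(_pixels([], [], small_matrix.communities),
                         small_matrix, b.SLRScenario(0.0), seed=0)


def test_trace_oracle(small_matrix):
    """A 20-pixel run equals a step-by-step hand trace that replays the
    documented variate order: one uniform per non-absorbed pixel in table
    order, community = first index whose cumulative proportion exceeds it."""
    rng0 = np.random.default_rng(33)
    elev = rng0.uniform(-0.5, 2.5, 20)
    comm = rng0.choice(small_matrix.communities, 20)
    px = _pixels(elev, comm, small_matrix.communities)
    sc = b.SLRScenario(0.2)
    seed = 42
    res = b.run_simulation(px, small_matrix, sc, seed=seed)

    keep = elev >= -sc.mlw_offset
    e_new = elev[keep] - sc.rise
    land = e_new >= -sc.mlw_offset
    u = np.random.default_rng(seed).random(int(land.sum()))
    k = len(small_matrix.communities)
    expected = np.zeros((k, k + 1), dtype=int)
    ui = 0
    for e0, c0, is_land in zip(e_new, comm[keep], land):
        i_from = small_matrix.communities.index(c0)
        if not is_land:
            expected[i_from, k] += 1
            continue
        row = b.lookup_row(small_matrix, e0)
        cum = 0.0
        pick = k - 1
        for j in range(k):
            cum += row[j]
            if u[ui] < min(cum, 1.0) or j == k - 1:
                pick = j
                break
        ui += 1
        expected[i_from, pick] += 1
    np.testing.assert_array_equal(res.contingency.to_numpy(), expected)


def test_conservation_and_deterministic_absorption(small_pixels,
                                                   small_matrix):
    n_valid = int((small_pixels["elevation"] >= -0.2).sum())
    prev_absorbed = -1
    for rise in (0.0, 0.2, 0.4, 1.2):
        absorbed = set()
        for seed in (1, 2, 3):
            res = b.run_simulation(small_pixels, small_matrix,
                                   b.SLRScenario(rise), seed=seed)
            assert res.contingency.to_numpy().sum() == n_valid
            absorbed.add(res.absorbed)
        assert len(absorbed) == 1  # identical across replicates
        a = absorbed.pop()
        assert a >= prev_absorbed  # non-decreasing in rise
        prev_absorbed = a


def test_single_replicate_summary():
    rng = np.random.default_rng(4)
    px = _pixels(rng.normal(1.0, 0.3, 500), ["A"] * 500, ["A"])
    m = b.build_matrix(px, step=0.01)
    res = b.replicate_simulations(px, m, b.SLRScenario(0.0), n_reps=1,
                                  base_seed=9)
    s = res.summary("total")
    assert (s["hi97.5"] - s["lo2.5"]).max() == 0.0
    assert s.loc["A", "median"] == res.replicates_total[0, 0]


def test_percentiles_match_sort_oracle(small_pixels, small_matrix):
    res = b.replicate_simulations(small_pixels, small_matrix,
                                  b.SLRScenario(0.2), n_reps=21, base_seed=5)
    s = res.summary("total")

    def quantile_sorted(v, q):
        v = np.sort(v)
        pos = q * (v.size - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, v.size - 1)
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    for i, c in enumerate(small_matrix.communities):
        v = res.replicates_total[:, i]
        assert s.loc[c, "median"] == pytest.approx(quantile_sorted(v, 0.5))
        assert s.loc[c, "lo2.5"] == pytest.approx(quantile_sorted(v, 0.025))
        assert s.loc[c, "hi97.5"] == pytest.approx(quantile_sorted(v, 0.975))


def test_no_change_fixed_point_small(small_pixels, small_matrix):
    """At zero rise the simulation reproduces current community proportions
    (the model's self-consistency validation)."""
    res = b.replicate_simulations(small_pixels, small_matrix,
                                  b.SLRScenario(0.0), n_reps=30, base_seed=1)
    init = small_pixels["community"].value_counts(normalize=True).reindex(
        list(small_matrix.communities)).fillna(0.0)
    med = res.summary("total")["median"]
    assert (med - init).abs().max() < 0.02


def test_subsample_full_size_degenerates_to_plain_replicates(
        small_pixels, small_matrix):
    sc = b.SLRScenario(0.2)
    sens = b.subsample_sensitivity(small_pixels, small_matrix, [sc],
                                   sizes=(len(small_pixels),), reps=5,
                                   base_seed=3)
    direct = b.replicate_simulations(small_pixels, small_matrix, sc,
                                     n_reps=5, base_seed=3)
    res = sens[len(small_pixels)][sc.label]
    np.testing.assert_array_equal(res.replicates_total,
                                  direct.replicates_total)


def test_oversized_subsample_skipped_with_warning(small_pixels,
                                                  small_matrix):
    with pytest.warns(UserWarning):
        sens = b.subsample_sensitivity(
            small_pixels, small_matrix, [b.SLRScenario(0.0)],
            sizes=(10**7, 200), reps=3, base_seed=0)
    assert list(sens) == [200]


def test_scrb_loses_more_than_average_under_high_rise(small_pixels,
                                                      small_matrix):
    """Under a 1.2 m rise the highest community (oak scrub) loses a larger
    fraction of its area than the landscape as a whole."""
    res = b.replicate_simulations(small_pixels, small_matrix,
                                  b.SLRScenario(1.2), n_reps=20, base_seed=8)
    init = small_pixels["community"].value_counts().reindex(
        list(small_matrix.communities)).fillna(0).astype(float)
    n = init.sum()
    med_counts = res.summary("total")["median"] * n
    scrb_loss = 1.0 - med_counts["SCRB"] / init["SCRB"]
    mean_loss = 1.0 - med_counts.sum() / n
    assert scrb_loss > mean_loss
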