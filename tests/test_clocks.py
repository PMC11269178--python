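"""Mutation clock, derived-pair decay statistic and recombination-clock fit."""

import numpy as np
import pandas as pd
import pytest

from paleoclock.clocks import (ClockConfig, PairDecayCurve, desk_scale_bins,
                               fit_recombination_clock, jackknife_recclock,
                               mutation_clock, pair_curves, pair_statistic,
                               pair_statistic_bruteforce)
from paleoclock.genmap import GeneticMap
from paleoclock.genotypes import derived_fraction
from tests.conftest import build_matrix


# -- mutation clock ---------------------------------------------------------

def test_mutation_clock_forced_arithmetic():
    calls = np.zeros((2, 300), np.int8)
    calls[0, :230] = 1                       # pi = 230 / 1e7 = 2.3e-5
    m = build_matrix(calls, positions=range(1, 301), chrom_lengths={"1": 1e7})
    res = mutation_clock(m, ClockConfig(mu=2.3e-8))
    assert res.loc[res["sample"] == "s0", "g_mut"].iloc[0] == pytest.approx(1000.0)
    assert res.loc[res["sample"] == "s1", "g_mut"].iloc[0] == 0.0


def test_mutation_clock_linear_in_mu():
    calls = np.zeros((1, 100), np.int8)
    calls[0, ::2] = 1
    m = build_matrix(calls, positions=range(1, 101), chrom_lengths={"1": 1e6})
    g1 = mutation_clock(m, ClockConfig(mu=1e-8))["g_mut"].iloc[0]
    g2 = mutation_clock(m, ClockConfig(mu=2e-8))["g_mut"].iloc[0]
    assert g1 == pytest.approx(2 * g2)


def test_mutation_clock_jackknife_zero_for_duplicated_chromosomes():
    rng = np.random.default_rng(0)
    half = rng.integers(0, 2, size=(3, 50)).astype(np.int8)
    calls = np.hstack([half, half])
    m = build_matrix(calls,
                     positions=list(range(1, 51)) * 2,
                     chroms=["1"] * 50 + ["2"] * 50,
                     chrom_lengths={"1": 1e6, "2": 1e6})
    res = mutation_clock(m, ClockConfig(mu=1e-8))
    assert np.allclose(res["var_jk"], 0.0)
    assert (res["var_jk"] >= 0).all()


def test_mutation_clock_tracks_truth(small_cohort, small_matrix):
    """pi / mu approximates the true mean genealogical path length."""
    _, cohort, truth = small_cohort
    cfg = ClockConfig(mu=2.3e-8)
    res = mutation_clock(small_matrix, cfg).set_index("sample")
    tr = truth.table.set_index("sample")
    rel = (res["g_mut"] / tr["mean_path_gen"]).to_numpy()
    assert np.mean(rel) == pytest.approx(1.0, abs=0.05)


# -- pair statistic ---------------------------------------------------------

def _toy_map(length=1e6, n_chrom=1):
    return GeneticMap.uniform({str(c + 1): length for c in range(n_chrom)})


def test_all_derived_sample_has_unit_pair_probability():
    calls = np.ones((1, 4), np.int8)
    m = build_matrix(calls, positions=[1000, 200_000, 500_000, 900_000],
                     chrom_lengths={"1": 1e6})
    cfg = ClockConfig(distance_bins=np.array([0.1, 10.0, 100.0]))
    curve = pair_statistic(m, "s0", _toy_map(), cfg)
    occupied = curve.n_pairs > 0
    assert occupied.any()
    assert np.allclose(curve.p_both[occupied], 1.0)
    assert np.allclose(curve.n_i[occupied], 1.0 / curve.pi_panel)


def test_zero_derived_sample_flagged():
    calls = np.zeros((1, 4), np.int8)
    m = build_matrix(calls, positions=[1000, 2000, 3000, 4000],
                     chrom_lengths={"1": 1e6})
    with pytest.raises(ValueError, match="no derived calls"):
        pair_statistic(m, "s0", _toy_map(), ClockConfig())


@pytest.mark.parametrize("seed", [0, 1])
def test_exact_pair_statistic_matches_bruteforce_oracle(seed):
    """The prefix-sum path equals exhaustive pair enumeration exactly."""
    rng = np.random.default_rng(seed)
    n_sites = 400
    pos1 = np.sort(rng.choice(np.arange(1, 1_000_000), 250, replace=False))
    pos2 = np.sort(rng.choice(np.arange(1, 600_000), n_sites - 250, replace=False))
    calls = rng.choice(np.array([-1, 0, 1], np.int8), size=(3, n_sites),
                       p=[0.2, 0.5, 0.3])
    m = build_matrix(calls,
                     positions=np.concatenate([pos1, pos2]),
                     chroms=["1"] * 250 + ["2"] * (n_sites - 250),
                     chrom_lengths={"1": 1e6, "2": 6e5})
    gmap = _toy_map(1e6, 2)
    cfg = ClockConfig(distance_bins=desk_scale_bins(), seed=seed)
    curves = pair_curves(m, gmap, cfg)
    for s in ("s0", "s2"):
        oracle = pair_statistic_bruteforce(m, s, gmap, cfg)
        fast = curves[m.sample_index(s)]
        assert np.array_equal(fast.n_pairs, oracle.n_pairs)
        both = fast.n_pairs > 0
        assert np.allclose(fast.p_both[both], oracle.p_both[both])
        assert fast.pi_panel == pytest.approx(oracle.pi_panel)


def test_subsampled_pair_statistic_reproducible_and_bounded():
    rng = np.random.default_rng(7)
    calls = rng.choice(np.array([0, 1], np.int8), size=(2, 300))
    m = build_matrix(calls,
                     positions=np.sort(rng.choice(np.arange(1, 900_000), 300,
                                                  replace=False)),
                     chrom_lengths={"1": 1e6})
    cfg = ClockConfig(distance_bins=np.array([0.1, 1.0, 10.0]),
                      max_pairs_per_bin=50, seed=5)
    c1 = pair_curves(m, _toy_map(), cfg)[0]
    c2 = pair_curves(m, _toy_map(), cfg)[0]
    assert np.array_equal(c1.n_pairs, c2.n_pairs)
    assert np.allclose(np.nan_to_num(c1.p_both), np.nan_to_num(c2.p_both))
    assert (c1.n_pairs <= 50).all()


def test_masked_chromosomes_excluded():
    calls = np.ones((1, 4), np.int8)
    m = build_matrix(calls, positions=[1000, 2000, 1000, 2000],
                     chroms=["1", "1", "2", "2"],
                     chrom_lengths={"1": 1e6, "2": 1e6})
    cfg = ClockConfig(distance_bins=np.array([0.001, 1.0]),
                      masked_chromosomes=frozenset({"2"}))
    curve = pair_curves(m, _toy_map(1e6, 2), cfg)[0]
    assert curve.n_pairs.sum() == 1          # only the chromosome-1 pair


# -- recombination-clock fit ------------------------------------------------

def _model_curves(t, p, C, pis, mids, n_pairs):
    curves = []
    for i in range(len(t)):
        n2 = p[i] * (1.0 + C / t[i] ** 2)
        p_both = n2 * pis[i] ** 2
        curves.append(PairDecayCurve(f"s{i}", mids, n_pairs.copy(), p_both,
                                     pis[i], 1e4))
    return curves


def test_fit_recovers_noiseless_model_parameters():
    """Self-consistency: data generated from the fitted model is recovered
    exactly up to the global scale anchor."""
    mids = np.sqrt(desk_scale_bins()[:-1] * desk_scale_bins()[1:]) * 10
    C = 4e6 * np.exp(-mids / 0.5)
    t_true = np.array([4000.0, 3500.0, 3000.0, 2500.0])
    pis = np.full(4, 0.1)
    n_pairs = np.full(len(mids), 1e5)
    curves = _model_curves(t_true, np.ones(4), C, pis, mids, n_pairs)
    init = pd.DataFrame({"sample": [f"s{i}" for i in range(4)], "g_mut": t_true})
    fit = fit_recombination_clock(curves, ClockConfig(), init)
    assert fit.converged
    # anchored geometric mean matches the init's, so recovery is absolute
    assert np.allclose(fit.t_i.to_numpy(), t_true, rtol=1e-4)


def test_fit_recovers_nuisance_amplitudes():
    mids = np.sqrt(desk_scale_bins()[:-1] * desk_scale_bins()[1:]) * 10
    C = 4e6 * np.exp(-mids / 0.5)
    t_true = np.array([4000.0, 3000.0, 2000.0])
    p_true = np.array([1.1, 1.0, 0.9])
    curves = _model_curves(t_true, p_true, C, np.full(3, 0.1), mids,
                           np.full(len(mids), 1e5))
    init = pd.DataFrame({"sample": [f"s{i}" for i in range(3)], "g_mut": t_true})
    fit = fit_recombination_clock(curves, ClockConfig(), init,
                                  nuisance="intercept")
    assert np.allclose(fit.p_i.to_numpy(), p_true, rtol=1e-3)
    assert np.allclose(fit.t_i.to_numpy(), t_true, rtol=0.05)


def test_grid_search_oracle_agrees_on_single_sample():
    """Coarse grid search over t_i with the decay curve fixed finds the same
    optimum region as the alternating least-squares fit."""
    mids = np.sqrt(desk_scale_bins()[:-1] * desk_scale_bins()[1:]) * 10
    C = 4e6 * np.exp(-mids / 0.5)
    t_true = np.array([3200.0])
    pis = np.array([0.1])
    n_pairs = np.full(len(mids), 1e5)
    rng = np.random.default_rng(0)
    curves = _model_curves(t_true, np.ones(1), C, pis, mids, n_pairs)
    curves[0].p_both = curves[0].p_both * (1 + rng.normal(0, 0.002, len(mids)))
    init = pd.DataFrame({"sample": ["s0"], "g_mut": [3200.0]})
    fit = fit_recombination_clock(curves, ClockConfig(), init)
    # profile RSS over a grid of candidate t values, shape fixed at truth
    y = curves[0].n2_i - 1.0
    w = curves[0].n_pairs
    grid = np.linspace(1500, 6000, 301)
    rss = [(w * (y - C / tg ** 2) ** 2).sum() for tg in grid]
    t_grid = grid[int(np.argmin(rss))]
    assert fit.t_i.iloc[0] == pytest.approx(t_grid, rel=0.05)


def test_fit_rejects_empty_input():
    with pytest.raises(ValueError):
        fit_recombination_clock([], ClockConfig())


# -- jackknife --------------------------------------------------------------

def test_jackknife_zero_variance_for_duplicated_chromosomes():
    rng = np.random.default_rng(1)
    pos = np.sort(rng.choice(np.arange(1, 900_000), 120, replace=False))
    half = rng.choice(np.array([0, 1], np.int8), size=(4, 120), p=[0.7, 0.3])
    calls = np.hstack([half, half])
    m = build_matrix(calls, positions=list(pos) * 2,
                     chroms=["1"] * 120 + ["2"] * 120,
                     chrom_lengths={"1": 1e6, "2": 1e6})
    cfg = ClockConfig(distance_bins=desk_scale_bins())
    res = jackknife_recclock(m, _toy_map(1e6, 2), cfg)
    assert np.allclose(res["var_jk"], 0.0, atol=1e-6)
    assert (res["var_jk"] >= -1e-12).all()


def test_jackknife_requires_two_chromosomes():
    calls = np.ones((1, 3), np.int8)
    m = build_matrix(calls, positions=[10, 20, 30], chrom_lengths={"1": 1e6})
    with pytest.raises(ValueError):
        jackknife_recclock(m, _toy_map(), ClockConfig())


# -- normalization invariance ----------------------------------------------

def test_normalized_statistic_invariant_to_downsampling(small_cohort,
                                                        small_matrix,
                                                        uniform_map):
    """Dividing by the panel derived fraction makes N_i insensitive to
    random call dropout (keep_prob 1.0 vs 0.5), by construction."""
    from paleoclock.genotypes import downsample_calls
    cfg = ClockConfig(distance_bins=desk_scale_bins(), seed=0)
    full = pair_curves(small_matrix, uniform_map, cfg)
    half = pair_curves(downsample_calls(small_matrix, 0.5, seed=2),
                       uniform_map, cfg)
    ratios = []
    for cf, ch in zip(full[:30], half[:30]):
        ok = (cf.n_pairs > 200) & (ch.n_pairs > 200)
        ratios.append(np.nanmean(ch.n_i[ok] / cf.n_i[ok]))
    assert np.nanmean(ratios) == pytest.approx(1.0, abs=0.05)
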