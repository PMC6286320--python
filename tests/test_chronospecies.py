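"""Chronospecies delimitation and range statistics."""

import numpy as np
import pytest
from scipy.stats import binomtest

import bdchrono as bc
from bdchrono.chronospecies import (
    MODE_ROOT,
    BDCParams,
    RangeSet,
    SpeciesRange,
    assign_chronospecies,
    calibrate_anagenesis,
    range_bin_statistics,
    range_statistics,
)


def test_parameter_validation():
    with pytest.raises(ValueError):
        BDCParams(0.2, 0.1, beta=1.2)
    with pytest.raises(ValueError):
        BDCParams(0.2, 0.1, lambda_a=-0.1)
    with pytest.raises(ValueError):
        SpeciesRange("a", 1.0, 2.0, extant=False)  # extinction above origination
    with pytest.raises(ValueError):
        SpeciesRange("a", 2.0, 1.0, extant=True)   # extant must end at 0


def test_pure_budding_one_species_per_tip(small_tree):
    rs = assign_chronospecies(small_tree, BDCParams(0.2, 0.1), seed=1)
    assert len(rs) == len(small_tree.tips())
    B, D, S = range_statistics(rs)
    assert B == len(rs) - 1
    assert D == sum(1 for r in rs if not r.extant)
    assert B - D == rs.n_extant - 1  # bookkeeping identity


def test_pure_bifurcation_one_species_per_edge(small_tree):
    rs = assign_chronospecies(small_tree, BDCParams(0.2, 0.1, beta=1.0), seed=2)
    assert len(rs) == 2 * len(small_tree.tips()) - 1


def test_fully_cryptic_single_range(small_tree):
    rs = assign_chronospecies(small_tree, BDCParams(0.2, 0.1, kappa=1.0), seed=3)
    assert len(rs) == 1
    r = rs.ranges[0]
    assert r.t_origination == small_tree.origin_age
    assert r.t_extinction == min(small_tree.age[t] for t in small_tree.tips())


def test_ranges_tile_the_tree(small_tree):
    """Without cryptic merging, species ranges partition the total tree
    length (root edge included)."""
    for seed, beta, la in [(4, 0.0, 0.0), (5, 0.5, 0.1), (6, 1.0, 0.3)]:
        rs = assign_chronospecies(
            small_tree, BDCParams(0.2, 0.1, beta=beta, lambda_a=la), seed=seed
        )
        S = sum(r.duration for r in rs)
        assert S == pytest.approx(small_tree.total_length(), rel=1e-9)


def test_anagenesis_poisson_expectation(small_tree):
    """Mean number of extra species over replicates is lam_a x tree length."""
    la = 0.15
    L = small_tree.total_length()
    base = len(small_tree.tips())
    rng = np.random.default_rng(12)
    extra = [
        len(assign_chronospecies(small_tree,
                                 BDCParams(0.2, 0.1, lambda_a=la), rng)) - base
        for _ in range(300)
    ]
    expect = la * L
    se = np.sqrt(expect / 300)
    assert abs(np.mean(extra) - expect) < 3 * se


def test_node_mode_frequencies_match_beta():
    rng = np.random.default_rng(21)
    tree = bc.simulate_tree(bc.RateSchedule.constant(0.3, 0.05), 400, rng)
    beta = 0.3
    n_nodes = len(tree.tips()) - 1
    # each bifurcating node contributes two bifurcation-mode daughters;
    # pool several independent assignments for power
    n_assign = 8
    n_bif = sum(
        sum(1 for r in assign_chronospecies(tree, BDCParams(0.3, 0.05,
                                                            beta=beta), rng)
            if r.mode == "bifurcation")
        for _ in range(n_assign)
    )
    assert binomtest(n_bif // 2, n_assign * n_nodes, beta).pvalue > 0.01


def test_event_ages_are_node_or_tip_ages(small_tree):
    """With kappa = 0 and no anagenesis, every range endpoint is a node
    age, a tip age or the origin."""
    rs = assign_chronospecies(small_tree, BDCParams(0.2, 0.1, beta=0.4), seed=9)
    known = set(small_tree.age) | {small_tree.origin_age}
    for r in rs:
        assert any(abs(r.t_origination - a) < 1e-12 for a in known)
        assert any(abs(r.t_extinction - a) < 1e-12 for a in known)


def test_empirical_rates_recover_bdc_map():
    """(B/S, D/S) over replicates converge to the mapped (lam*, mu*)."""
    rng = np.random.default_rng(30)
    sched = bc.RateSchedule.constant(0.2, 0.16)
    for beta, la in [(0.0, 0.0), (0.5, 0.04), (0.7, 0.16)]:
        truth = bc.fossil_rates_from_bdc(0.2, 0.16, beta, la)
        ls, ms = [], []
        for _ in range(25):
            tree = bc.simulate_tree(sched, 120, rng)
            B, D, S = range_statistics(
                assign_chronospecies(tree, BDCParams(0.2, 0.16, beta=beta,
                                                     lambda_a=la), rng)
            )
            ls.append(B / S)
            ms.append(D / S)
        for est, true in [(ls, truth.lambda_star), (ms, truth.mu_star)]:
            se = np.std(est, ddof=1) / np.sqrt(len(est))
            assert abs(np.mean(est) - true) < 3 * se


def test_range_statistics_examples():
    solo = RangeSet([SpeciesRange("a", 10.0, 0.0, extant=True, mode=MODE_ROOT)])
    assert range_statistics(solo) == (0, 0, 10.0)
    pair = RangeSet([
        SpeciesRange("a", 10.0, 0.0, extant=True, mode=MODE_ROOT),
        SpeciesRange("b", 4.0, 0.0, extant=False, mode="budding"),
    ])
    B, D, S = range_statistics(pair)
    assert (B, D, S) == (1, 1, 14.0)
    with pytest.raises(ValueError):
        range_statistics(RangeSet([]))


def test_range_statistics_after_subsampling_without_root():
    """When the root range is lost the oldest survivor is the start."""
    rs = RangeSet([
        SpeciesRange("b", 8.0, 3.0, extant=False, mode="budding"),
        SpeciesRange("c", 5.0, 0.0, extant=True, mode="budding"),
    ])
    assert range_statistics(rs) == (1, 1, 10.0)


def test_bin_statistics_sum_to_global(small_tree):
    rs = assign_chronospecies(small_tree, BDCParams(0.2, 0.1, beta=0.5,
                                                    lambda_a=0.1), seed=40)
    B, D, S = range_statistics(rs)
    bins = range_bin_statistics(rs, [0.0, 3.0, 8.0, 15.0])
    assert bins.shape == (4, 3)
    assert bins[:, 0].sum() == B
    assert bins[:, 1].sum() == D
    assert bins[:, 2].sum() == pytest.approx(S, rel=1e-9)


def test_calibrate_anagenesis(small_tree):
    base = len(assign_chronospecies(small_tree, BDCParams(0.2, 0.1, beta=0.5),
                                    seed=0))
    target = base + 15
    la, pruned = calibrate_anagenesis(small_tree, beta=0.5,
                                      target_ranges=target, seed=7)
    assert len(pruned) == target
    assert la >= 0.1 and round(la / 0.1) == pytest.approx(la / 0.1)
    with pytest.raises(ValueError):
        calibrate_anagenesis(small_tree, beta=0.5, target_ranges=2, seed=7)
    with pytest.raises(RuntimeError):
        calibrate_anagenesis(small_tree, beta=0.5, target_ranges=10 ** 6,
                             seed=7, max_lambda_a=0.2)


def test_calibration_monotone_in_lambda_a(small_tree):
    rng = np.random.default_rng(50)
    means = []
    for la in (0.05, 0.3, 1.0):
        counts = [len(assign_chronospecies(small_tree,
                                           BDCParams(0.2, 0.1, lambda_a=la),
                                           rng)) for _ in range(40)]
        means.append(np.mean(counts))
    assert means[0] < means[1] < means[2]
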