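"""Tree simulation conditioned on the number of extant tips."""

import math

import numpy as np
import pytest
from scipy.stats import ks_2samp, poisson

import bdchrono as bc
from bdchrono.treesim import RateSchedule, SimulationError

from conftest import mrca_branching_ages


def test_schedule_validation():
    with pytest.raises(ValueError):
        RateSchedule(((0.0, 10.0, 0.2, 0.1),))          # does not reach inf
    with pytest.raises(ValueError):
        RateSchedule(((5.0, math.inf, 0.2, 0.1),))      # gap at the present
    with pytest.raises(ValueError):
        RateSchedule(((0.0, 10.0, 0.2, 0.1), (12.0, math.inf, 0.2, 0.1)))
    s = RateSchedule.constant(0.2, 0.16)
    assert s.is_constant and s.rates_at(3.0) == (0.2, 0.16)
    assert RateSchedule.constant(0.2, 0.2).intervals  # lam == mu permitted


@pytest.mark.parametrize("method", ["gsa", "cpp"])
def test_single_species_is_pendant_edge(method):
    tree = bc.simulate_tree(RateSchedule.constant(0.4, 0.0), 1, seed=3,
                            method=method)
    assert tree.n_extant_tips == 1
    assert sum(1 for i in range(tree.n_nodes) if tree.children[i]) == 0
    assert tree.origin_age > 0


@pytest.mark.parametrize("method", ["gsa", "cpp"])
def test_tip_count_is_exact(method):
    rng = np.random.default_rng(7)
    for _ in range(25):
        tree = bc.simulate_tree(RateSchedule.constant(0.3, 0.12), 17, rng,
                                method=method)
        assert tree.n_extant_tips == 17
        tree.validate()


def test_forward_and_analytic_samplers_agree():
    """Origin-age distributions of the two independent samplers are
    statistically indistinguishable (they target the same process)."""
    rng = np.random.default_rng(55)
    sched = RateSchedule.constant(0.3, 0.1)
    a = [bc.simulate_tree(sched, 12, rng, method="gsa").origin_age
         for _ in range(500)]
    b = [bc.simulate_tree(sched, 12, rng, method="cpp").origin_age
         for _ in range(500)]
    assert ks_2samp(a, b).pvalue > 0.01


def test_piecewise_with_uniform_rates_matches_constant():
    """A multi-interval schedule whose pieces share one rate pair is the
    constant-rate model; cross-checked against the forward sampler."""
    rng = np.random.default_rng(56)
    const = RateSchedule.constant(0.3, 0.1)
    split = RateSchedule(((0.0, 5.0, 0.3, 0.1), (5.0, 12.0, 0.3, 0.1),
                          (12.0, math.inf, 0.3, 0.1)))
    a = [bc.simulate_tree(const, 12, rng, method="gsa").origin_age
         for _ in range(500)]
    b = [bc.simulate_tree(split, 12, rng, method="cpp").origin_age
         for _ in range(500)]
    assert ks_2samp(a, b).pvalue > 0.01


def test_yule_branching_is_poisson_in_lineage_time():
    """With mu = 0 the forward process accumulates branching events as a
    Poisson process over lineage-time at rate lam (3 SE tolerance).

    Tested on unconditioned forward runs: conditioning on the extant
    tip count deliberately tilts the events-per-length ratio (the
    present is placed inside an n-lineage span), so the raw Poisson law
    only applies to the generator itself.
    """
    from bdchrono.treesim import _gsa_run

    rng = np.random.default_rng(8)
    lam = 0.25
    events, exposure = 0, 0.0
    for _ in range(40):
        birth, death, parent, spans = _gsa_run(rng, lam, 0.0, 5, 200, 10 ** 6)
        t_end = max(birth)
        events += len(birth) - 1
        exposure += sum(t_end - b for b in birth)
    rate = events / exposure
    se = np.sqrt(events) / exposure
    assert abs(rate - lam) < 3 * se


@pytest.mark.parametrize("method", ["gsa", "cpp"])
def test_prune_extinct_matches_mrca_oracle(method):
    rng = np.random.default_rng(31)
    for _ in range(15):
        tree = bc.simulate_tree(RateSchedule.constant(0.3, 0.15), 10, rng,
                                method=method)
        phylo, pruned = bc.prune_extinct(tree)
        oracle = mrca_branching_ages(tree, tree.extant_tips())
        assert np.allclose(sorted(phylo.branching_ages), sorted(oracle))
        assert phylo.n == 10
        assert phylo.origin_age == tree.origin_age
        # no extinct tips -> branching ages equal all internal node ages
        if len(tree.tips()) == 10:
            internal = sorted(tree.age[i] for i in range(tree.n_nodes)
                              if tree.children[i])
            assert np.allclose(sorted(phylo.branching_ages), internal)


def test_prune_all_extinct_subtree_lowers_crown():
    """If one child subtree of the root dies out entirely, the pruned
    crown is younger than the complete tree's first split."""
    rng = np.random.default_rng(77)
    found = False
    for _ in range(200):
        tree = bc.simulate_tree(RateSchedule.constant(0.25, 0.2), 6, rng)
        root_kids = tree.children[tree.root]
        if not root_kids:
            continue
        n_ext = [0, 0]
        for j, c in enumerate(root_kids):
            stack = [c]
            while stack:
                x = stack.pop()
                if not tree.children[x]:
                    n_ext[j] += tree.age[x] == 0.0
                stack.extend(tree.children[x])
        if 0 in n_ext and sum(n_ext) >= 2:
            phylo, _ = bc.prune_extinct(tree)
            assert phylo.crown_age < tree.age[tree.root]
            found = True
            break
    assert found, "no tree with a fully extinct root subtree in 200 draws"


def test_prune_requires_survivors():
    tree = bc.CompleteTree(5.0)
    tree.add_node(2.0, -1)  # one extinct tip
    with pytest.raises(ValueError):
        bc.prune_extinct(tree)


def test_subsample_extant():
    rng = np.random.default_rng(13)
    tree = bc.simulate_tree(RateSchedule.constant(0.3, 0.1), 40, rng)
    _, pruned = bc.prune_extinct(tree)
    # rho = 1 is the identity
    phylo1, _ = bc.subsample_extant(pruned, 1.0, rng)
    phylo0, _ = bc.prune_extinct(pruned)
    assert np.allclose(phylo1.branching_ages, phylo0.branching_ages)
    assert phylo1.rho == 1.0
    # retained branching ages are MRCA ages of retained tips
    phylo, sub = bc.subsample_extant(pruned, 0.5, rng)
    kept = sub.extant_tips()
    assert phylo.n == len(kept)
    assert phylo.rho == 0.5
    # binomial expectation of retained tips
    rng2 = np.random.default_rng(14)
    kept_counts = [bc.subsample_extant(pruned, 0.5, rng2)[0].n for _ in range(150)]
    assert abs(np.mean(kept_counts) - 20) < 3 * np.sqrt(40 * 0.25) / np.sqrt(150)
    with pytest.raises(SimulationError):
        bc.subsample_extant(pruned, 0.005, np.random.default_rng(0))


def test_subsample_ages_subset_of_mrca_oracle():
    rng = np.random.default_rng(15)
    tree = bc.simulate_tree(RateSchedule.constant(0.3, 0.1), 15, rng)
    _, pruned = bc.prune_extinct(tree)
    phylo, sub = bc.subsample_extant(pruned, 0.6, rng)
    oracle = mrca_branching_ages(sub, sub.extant_tips())
    assert np.allclose(sorted(phylo.branching_ages), sorted(oracle))
    full = sorted(a for i, a in enumerate(pruned.age) if pruned.children[i])
    for a in phylo.branching_ages:
        assert any(abs(a - f) < 1e-12 for f in full)


def test_newick_round_trip_via_dendropy(small_tree):
    import dendropy

    s = small_tree.newick()
    t = dendropy.Tree.get(data=s, schema="newick")
    assert len(t.leaf_nodes()) == len(small_tree.tips())
    # total length is preserved (root edge included)
    total = sum(e.length for e in t.preorder_edge_iter() if e.length)
    assert total == pytest.approx(small_tree.total_length(), rel=1e-9)


def test_event_log_schema(small_tree):
    log = small_tree.event_log()
    assert set(log.columns) == {"node_id", "age", "event"}
    assert (log["event"] == "branching").sum() == len(small_tree.tips()) - 1
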