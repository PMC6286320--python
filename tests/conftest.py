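import numpy as np
import pytest

import bdchrono as bc


@pytest.fixture(scope="session")
def small_tree():
    """A modest complete tree with extinct lineages (seeded)."""
    return bc.simulate_tree(bc.RateSchedule.constant(0.2, 0.1), 30, seed=101)


@pytest.fixture(scope="session")
def compatible_dataset():
    """One 200-tip dataset generated under bifurcation + anagenesis.

    Returns (phylo, stats, true FossilRates) for reuse across the
    model-testing and Bayesian tests.
    """
    rng = np.random.default_rng(2024)
    tree = bc.simulate_tree(bc.RateSchedule.constant(0.2, 0.16), 200, rng)
    ranges = bc.assign_chronospecies(
        tree, bc.BDCParams(0.2, 0.16, beta=0.5, lambda_a=0.04), rng
    )
    phylo, _ = bc.prune_extinct(tree)
    truth = bc.fossil_rates_from_bdc(0.2, 0.16, 0.5, 0.04)
    return phylo, bc.range_statistics(ranges), truth


@pytest.fixture(scope="session")
def strong_compatible_dataset():
    """A dataset generated at the strong worked setting beta=0.7,
    lambda_a=0.16, whose rate quadruple is (0.2, 0.16, 0.5, 0.46)."""
    rng = np.random.default_rng(777)
    tree = bc.simulate_tree(bc.RateSchedule.constant(0.2, 0.16), 200, rng)
    ranges = bc.assign_chronospecies(
        tree, bc.BDCParams(0.2, 0.16, beta=0.7, lambda_a=0.16), rng
    )
    phylo, _ = bc.prune_extinct(tree)
    return phylo, bc.range_statistics(ranges)


@pytest.fixture(scope="session")
def budding_dataset():
    """A pure-budding (equal-rates) dataset of the same size."""
    rng = np.random.default_rng(515)
    tree = bc.simulate_tree(bc.RateSchedule.constant(0.2, 0.16), 200, rng)
    ranges = bc.assign_chronospecies(tree, bc.BDCParams(0.2, 0.16), rng)
    phylo, _ = bc.prune_extinct(tree)
    return phylo, bc.range_statistics(ranges)


def mrca_branching_ages(tree, tips):
    """Brute-force oracle: branching ages of the tree induced on ``tips``
    via pairwise most-recent-common-ancestor lookups."""
    import itertools

    paths = {}
    for tip in tips:
        path, x = [], tip
        while x >= 0:
            path.append(x)
            x = tree.parent[x]
        paths[tip] = path
    nodes = set()
    for a, b in itertools.combinations(tips, 2):
        sa = set(paths[a])
        for x in paths[b]:
            if x in sa:
                nodes.add(x)
                break
    return sorted((tree.age[x] for x in nodes), reverse=True)
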