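"""Simulation of complete birth-death trees conditioned on extant tip count.

Two exact samplers are provided behind :func:`simulate_tree`:

* a forward general-sampling-algorithm (GSA) simulator for constant
  rates: the process is run forward until it is well past ``n`` tips
  (or extinct), every time span during which exactly ``n`` lineages are
  alive is recorded, one span point is drawn with probability
  proportional to span duration and the run is truncated there, making
  that point the present;

* an analytic sampler for piecewise schedules anchored to the present
  (and optionally for constant rates): the origin age is drawn from its
  GSA-implied density ``f(T) \\propto p1(T) u(T)^{n-1}`` (the geometric
  law of the population size), the reconstructed tree of the ``n``
  survivors is drawn via the coalescent-point-process representation
  (``n - 1`` i.i.d. node depths with density ``\\propto lam(t) p1(t)``),
  and fully extinct subtrees are grafted onto every surviving branch as
  a Poisson process with rate ``lam(t) p0(t)``, each subtree simulated
  forward conditioned on extinction before the present.

The two samplers target the same distribution; the test suite checks
their origin-age distributions against each other.

Ages are always times before present (present = 0, increasing into the
past).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._bdprob import PiecewiseBD

__all__ = [
    "RateSchedule",
    "CompleteTree",
    "PhyloData",
    "simulate_tree",
    "prune_extinct",
    "subsample_extant",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Raised when a simulation cannot be completed under its guards."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateSchedule:
    """Piecewise-constant birth-death rates anchored to the present.

    ``intervals`` is an ordered tuple of ``(start_age, end_age, lam, mu)``
    tiling ``[0, inf)`` with no gaps or overlaps; a single interval
    encodes the constant-rate model.  ``end_age`` of the last interval
    must be ``math.inf``.
    """

    intervals: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("schedule needs at least one interval")
        prev_end = 0.0
        for start, end, lam, mu in self.intervals:
            if start != prev_end:
                raise ValueError("intervals must tile [0, inf) without gaps")
            if end <= start:
                raise ValueError("interval end must exceed its start")
            if lam <= 0 or mu < 0:
                raise ValueError("require lam > 0 and mu >= 0")
            prev_end = end
        if not math.isinf(prev_end):
            raise ValueError("last interval must extend to infinity")

    @classmethod
    def constant(cls, lam: float, mu: float) -> "RateSchedule":
        return cls(((0.0, math.inf, lam, mu),))

    @property
    def is_constant(self) -> bool:
        return len(self.intervals) == 1

    @property
    def boundaries(self) -> np.ndarray:
        return np.array([iv[0] for iv in self.intervals])

    @property
    def lams(self) -> np.ndarray:
        return np.array([iv[2] for iv in self.intervals])

    @property
    def mus(self) -> np.ndarray:
        return np.array([iv[3] for iv in self.intervals])

    def rates_at(self, age: float) -> tuple[float, float]:
        for start, end, lam, mu in self.intervals:
            if start <= age < end:
                return lam, mu
        raise ValueError(f"age {age} not covered by schedule")

    def kernel(self, rho: float = 1.0) -> PiecewiseBD:
        return PiecewiseBD(self.boundaries, self.lams, self.mus, rho=rho)


class CompleteTree:
    """A rooted, time-calibrated binary tree including extinct lineages.

    Nodes are stored in arrays; index order is topological (every node
    appears after its parent).  Tip ages of exactly ``0.0`` mark extant
    tips.  A single root edge runs from the origin age ``t0`` down to
    the first node.
    """

    def __init__(self, origin_age: float):
        self.origin_age = float(origin_age)
        self.parent: list[int] = []
        self.age: list[float] = []
        self.children: list[list[int]] = []

    def add_node(self, age: float, parent: int) -> int:
        nid = len(self.age)
        self.age.append(float(age))
        self.parent.append(parent)
        self.children.append([])
        if parent >= 0:
            self.children[parent].append(nid)
        return nid

    # -- queries ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.age)

    @property
    def root(self) -> int:
        return 0

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def tips(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    def extant_tips(self) -> list[int]:
        return [i for i in self.tips() if self.age[i] == 0.0]

    @property
    def n_extant_tips(self) -> int:
        return len(self.extant_tips())

    def edge_start_age(self, i: int) -> float:
        """Age at which the edge leading into node ``i`` begins."""
        p = self.parent[i]
        return self.origin_age if p < 0 else self.age[p]

    def total_length(self) -> float:
        """Sum of all edge lengths, root edge included."""
        return sum(self.edge_start_age(i) - self.age[i] for i in range(self.n_nodes))

    def validate(self) -> None:
        n_tips = len(self.tips())
        n_internal = sum(1 for i in range(self.n_nodes) if self.children[i])
        if n_internal != n_tips - 1:
            raise ValueError("tree is not binary: internal nodes != tips - 1")
        for i in range(self.n_nodes):
            if self.children[i] and len(self.children[i]) != 2:
                raise ValueError(f"node {i} has {len(self.children[i])} children")
            if self.age[i] >= self.edge_start_age(i) and self.n_nodes > 1:
                raise ValueError(f"node {i} is not younger than its parent")
        if self.age[self.root] >= self.origin_age:
            raise ValueError("root node must be younger than the origin")

    def newick(self, include_root_edge: bool = True) -> str:
        """Newick string with branch lengths in time units.

        Tips are labelled ``t<id>``, internal nodes ``n<id>``.
        """
        parts: dict[int, str] = {}
        for i in range(self.n_nodes - 1, -1, -1):
            bl = self.edge_start_age(i) - self.age[i]
            if not self.children[i]:
                parts[i] = f"t{i}:{bl:.12g}"
            else:
                kids = ",".join(parts.pop(c) for c in self.children[i])
                parts[i] = f"({kids})n{i}:{bl:.12g}"
        s = parts[self.root]
        if not include_root_edge:
            s = s.rsplit(":", 1)[0]
        return s + ";"

    def event_log(self):
        """Tree events as a table (node id, age, event type) for debugging."""
        import pandas as pd

        rows = []
        for i in range(self.n_nodes):
            if self.children[i]:
                kind = "branching"
            elif self.age[i] == 0.0:
                kind = "extant_tip"
            else:
                kind = "extinction"
            rows.append((i, self.age[i], kind))
        return pd.DataFrame(rows, columns=["node_id", "age", "event"])


@dataclass
class PhyloData:
    """Branching ages of an extant-species phylogeny.

    ``branching_ages`` are sorted oldest first; the first entry is the
    crown age.  ``origin_age`` is the stem age if known.  ``rho`` is the
    probability that an extant species is included.
    """

    n: int
    branching_ages: np.ndarray
    origin_age: float | None = None
    rho: float = 1.0

    def __post_init__(self) -> None:
        self.branching_ages = np.sort(np.asarray(self.branching_ages, float))[::-1]
        if self.n != len(self.branching_ages) + 1:
            raise ValueError("need n - 1 branching ages for n tips")
        if np.any(self.branching_ages < 0):
            raise ValueError("branching ages must be non-negative")
        if self.origin_age is not None and self.n >= 2:
            if self.origin_age < self.branching_ages[0]:
                raise ValueError("origin age must be at least the crown age")
        if not 0.0 < self.rho <= 1.0:
            raise ValueError("rho must lie in (0, 1]")

    @property
    def crown_age(self) -> float:
        if self.n < 2:
            raise ValueError("crown age undefined for n < 2")
        return float(self.branching_ages[0])


# ---------------------------------------------------------------------------
# forward GSA simulator (constant rates)
# ---------------------------------------------------------------------------


def _gsa_run(rng, lam, mu, n, m_cap, max_events):
    """One unconditioned forward run.

    Returns ``(birth, death, parent, spans)`` where ``spans`` are the
    forward-time intervals during which exactly ``n`` lineages were
    alive, or None if there are none (the run died before reaching n).
    """
    birth = [0.0]
    death = [math.inf]
    parent = [-1]
    alive = [0]
    t = 0.0
    spans: list[tuple[float, float]] = []
    total_rate = lam + mu
    p_birth = lam / total_rate
    n_events = 0
    while alive and len(alive) < m_cap:
        n_alive = len(alive)
        t_next = t + rng.exponential(1.0 / (n_alive * total_rate))
        if n_alive == n:
            spans.append((t, t_next))
        t = t_next
        idx = rng.integers(n_alive)
        if rng.random() < p_birth:
            birth.append(t)
            death.append(math.inf)
            parent.append(alive[idx])
            alive.append(len(birth) - 1)
        else:
            lin = alive[idx]
            death[lin] = t
            alive[idx] = alive[-1]
            alive.pop()
        n_events += 1
        if n_events > max_events:
            raise SimulationError(
                f"forward run exceeded {max_events} events; "
                "check the rate regime or raise max_events"
            )
    if not spans:
        return None
    return birth, death, parent, spans


def _truncate_run(birth, death, parent, present):
    """Cut a forward run at ``present``; ages are times before it."""
    starts, ends, parents = [], [], []
    keep = {}
    for i in range(len(birth)):
        if birth[i] >= present:
            continue
        keep[i] = len(starts)
        starts.append(present - birth[i])
        ends.append(max(present - death[i], 0.0) if death[i] <= present else 0.0)
        parents.append(keep[parent[i]] if parent[i] >= 0 else -1)
    return starts, ends, parents


def _lineages_to_tree(origin_age, starts, ends, parents) -> CompleteTree:
    """Convert budding-style lineage records (ages) into a binary tree.

    Each lineage spans ``[end, start]`` in age; a child lineage born at
    age ``a`` on its parent creates a binary node at ``a``.
    """
    tree = CompleteTree(origin_age)
    n_lin = len(starts)
    kids: list[list[int]] = [[] for _ in range(n_lin)]
    for i in range(n_lin):
        if parents[i] >= 0:
            kids[parents[i]].append(i)
    # events per lineage sorted old -> young; lineage order is birth order,
    # so parents precede children.
    attach_node = [-1] * n_lin  # node to hang the lineage's chain under
    for i in range(n_lin):
        events = sorted(kids[i], key=lambda c: starts[c], reverse=True)
        cur = attach_node[i]
        for c in events:
            nid = tree.add_node(starts[c], cur)
            attach_node[c] = nid
            cur = nid
        tree.add_node(ends[i], cur)  # terminal tip of this lineage
    return tree


def _simulate_gsa(rng, schedule, n, oversampling, max_events, max_attempts,
                  n_pilot: int = 6):
    """Forward GSA with runs weighted by their n-lineage occupation time.

    A run that holds n lineages for a total duration z must be sampled
    with probability proportional to z (the present is uniform over the
    pooled occupation measure).  Qualifying pilot runs calibrate a cap
    z_cap = 3 max(z); runs are then accepted with probability z / z_cap
    (clamped at 1 for the rare run exceeding the cap) and the present
    is drawn uniformly within the accepted run's spans.
    """
    if not schedule.is_constant:
        raise SimulationError("the forward GSA sampler supports constant rates only")
    lam, mu = schedule.intervals[0][2], schedule.intervals[0][3]
    m_cap = max(oversampling * n, n + 1)
    pilots = []
    z_cap = None
    for _ in range(max_attempts):
        res = _gsa_run(rng, lam, mu, n, m_cap, max_events)
        if res is None:
            continue
        z = sum(b - a for a, b in res[3])
        if z_cap is None:
            pilots.append((res, z))
            if len(pilots) < n_pilot:
                continue
            z_cap = 3.0 * max(p[1] for p in pilots)
            queue = pilots
        else:
            queue = [(res, z)]
        for (birth, death, parent, spans), z_run in queue:
            if rng.random() >= min(1.0, z_run / z_cap):
                continue
            durations = [b - a for a, b in spans]
            x = rng.uniform(0.0, sum(durations))
            cum = 0.0
            for (a, b), d in zip(spans, durations):
                if x <= cum + d:
                    present = a + (x - cum)
                    break
                cum += d
            tree = _lineages_to_tree(present,
                                     *_truncate_run(birth, death, parent, present))
            if tree.n_extant_tips != n:
                raise SimulationError("internal error: truncated run lost tips")
            return tree
    raise SimulationError(f"no accepted run in {max_attempts} attempts")


# ---------------------------------------------------------------------------
# analytic (coalescent point process) sampler
# ---------------------------------------------------------------------------


def _sample_origin(rng, kernel: PiecewiseBD, n: int, grid_size: int = 4096) -> float:
    """Draw the origin age from f(T) ~ p1(T) u(T)^(n-1)."""
    t_hi = 1.0
    for _ in range(60):
        grid = np.linspace(1e-9, t_hi, grid_size)
        logf = kernel.log_pn(grid, n)
        m = logf.max()
        if logf[-1] < m - 34.0:  # tail negligible beyond t_hi
            break
        t_hi *= 2.0
    else:
        raise SimulationError("origin-age density does not decay; bad schedule?")
    w = np.exp(logf - m)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    return float(np.interp(rng.random(), cdf, grid))


def _sample_node_depths(rng, kernel: PiecewiseBD, T: float, n: int,
                        grid_size: int = 8192) -> np.ndarray:
    """n-1 i.i.d. node depths with density ~ lam(t) p1(t) on (0, T).

    The CDF is u(t)/u(T) (identity du/dt = lam p1 for rho = 1).
    """
    grid = np.linspace(0.0, T, grid_size)
    u = kernel.u(grid)
    u[0] = 0.0
    u = np.maximum.accumulate(u)  # guard tiny numeric non-monotonicity
    x = rng.uniform(0.0, u[-1], size=n - 1)
    return np.interp(x, u, grid)


def _try_extinct_subtree(rng, schedule, start_age, max_events):
    """One forward attempt at a subtree from ``start_age``.

    Returns lineage records if every lineage died before the present,
    None if any lineage survived (the attempt is then invalid as an
    extinct subtree).
    """
    starts = [start_age]
    ends: list[float | None] = [None]
    parents = [-1]
    alive = [0]
    a = start_age
    n_events = 0
    while alive:
        lam, mu = schedule.rates_at(a)
        bin_lo = 0.0
        for s, e, _, _ in schedule.intervals:
            if s <= a < e:
                bin_lo = s
                break
        total = len(alive) * (lam + mu)
        a_next = a - rng.exponential(1.0 / total)
        if a_next < bin_lo:
            if bin_lo == 0.0:
                return None  # a lineage reaches the present alive
            a = bin_lo - 1e-12
            continue
        a = a_next
        idx = rng.integers(len(alive))
        if rng.random() < lam / (lam + mu):
            starts.append(a)
            ends.append(None)
            parents.append(alive[idx])
            alive.append(len(starts) - 1)
        else:
            ends[alive[idx]] = a
            alive[idx] = alive[-1]
            alive.pop()
        n_events += 1
        if n_events > max_events:
            return None
    return starts, ends, parents


def _graft_lineages(tree: CompleteTree, parent_id: int, starts, ends, parents) -> None:
    """Attach a lineage-record subtree below ``parent_id`` of ``tree``."""
    n_lin = len(starts)
    kids: list[list[int]] = [[] for _ in range(n_lin)]
    for i in range(n_lin):
        if parents[i] >= 0:
            kids[parents[i]].append(i)
    attach = [parent_id] + [-1] * (n_lin - 1)
    for i in range(n_lin):
        cur = attach[i]
        for c in sorted(kids[i], key=lambda c: starts[c], reverse=True):
            nid = tree.add_node(starts[c], cur)
            attach[c] = nid
            cur = nid
        tree.add_node(ends[i], cur)


def _simulate_cpp(rng, schedule, n, max_events):
    kernel = schedule.kernel(rho=1.0)
    T = _sample_origin(rng, kernel, n)
    depths = _sample_node_depths(rng, kernel, T, n) if n > 1 else np.array([])

    # reconstructed tree via sequential merging of adjacent tip clusters
    # recon nodes: list of (age, left_child, right_child); children < 0
    # encode tips as -(tip_index + 1)
    recon_age: list[float] = []
    recon_kids: list[tuple[int, int]] = []
    order = np.argsort(depths)
    # union-find over tip positions
    parent_uf = list(range(n))

    def find(i):
        while parent_uf[i] != i:
            parent_uf[i] = parent_uf[parent_uf[i]]
            i = parent_uf[i]
        return i

    croot = {i: -(i + 1) for i in range(n)}
    for gap in order:  # gap g sits between tips g and g+1
        a, b = find(gap), find(gap + 1)
        nid = len(recon_age)
        recon_age.append(float(depths[gap]))
        recon_kids.append((croot[a], croot[b]))
        parent_uf[b] = a
        croot[a] = nid
    recon_root = croot[find(0)] if n > 1 else -1

    tree = CompleteTree(T)
    p0 = kernel.p0

    def attachments(age_lo: float, age_hi: float) -> list[tuple]:
        """Extinct subtrees attached along an edge.

        Along a lineage conditioned to survive, hidden branchings occur
        at rate 2 lam(a) p0(a): branching at the survival-tilted rate
        with either daughter being the one that dies out.  Candidates
        are proposed at rate 2 lam(a); where p0(a) is appreciable the
        point is p0-thinned and its subtree drawn conditioned on
        extinction (rejection), where p0(a) is small a single
        unconditioned subtree is attempted and the point discarded if
        it survives -- both realise the same thinned process, the
        switch only bounds the work per point.
        """
        out = []
        for (s, e, lam, _mu) in schedule.intervals:
            lo, hi = max(age_lo, s), min(age_hi, e)
            if hi <= lo:
                continue
            for a in rng.uniform(lo, hi, size=rng.poisson(2.0 * lam * (hi - lo))):
                p = float(p0(np.array([a]))[0])
                if p <= 0.0:
                    continue
                if p >= 0.05:
                    if rng.random() >= p:
                        continue
                    for _ in range(10000):
                        sub = _try_extinct_subtree(rng, schedule, a, max_events)
                        if sub is not None:
                            break
                    else:
                        raise SimulationError(
                            "could not draw a conditioned extinct subtree"
                        )
                else:
                    sub = _try_extinct_subtree(rng, schedule, a, max_events)
                    if sub is None:
                        continue
                out.append((a, sub))
        return sorted(out, key=lambda t: t[0], reverse=True)

    def add_decorated_edge(parent_id: int, age_hi: float, node_age: float) -> int:
        """Insert attachment nodes along [node_age, age_hi], return the
        id under which the reconstructed node itself should hang."""
        cur = parent_id
        for a, sub in attachments(node_age, age_hi):
            nid = tree.add_node(a, cur)
            _graft_lineages(tree, nid, *sub)
            cur = nid
        return cur

    # iterative assembly, stem edge first
    stack = [(recon_root, -1, T)]
    while stack:
        rnode, parent_id, age_hi = stack.pop()
        if rnode < 0:  # a sampled extant tip
            cur = add_decorated_edge(parent_id, age_hi, 0.0)
            tree.add_node(0.0, cur)
        else:
            a = recon_age[rnode]
            cur = add_decorated_edge(parent_id, age_hi, a)
            nid = tree.add_node(a, cur)
            left, right = recon_kids[rnode]
            stack.append((left, nid, a))
            stack.append((right, nid, a))
    return tree


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def simulate_tree(
    schedule: RateSchedule,
    n_extant: int,
    seed=None,
    method: str = "auto",
    oversampling: int = 10,
    max_events: int = 10**6,
    max_attempts: int = 10000,
) -> CompleteTree:
    """Simulate a complete birth-death tree with exactly ``n_extant``
    extant tips at the present.

    ``method`` is ``"cpp"`` (analytic coalescent-point-process sampler,
    any schedule; the default), ``"gsa"`` (forward general sampling
    algorithm with occupation-time run weighting, constant rates only;
    useful as an independent cross-check) or ``"auto"`` (= cpp).
    """
    if n_extant < 1:
        raise ValueError("n_extant must be >= 1")
    rng = np.random.default_rng(seed)
    if method == "auto":
        method = "cpp"
    if method == "gsa":
        tree = _simulate_gsa(rng, schedule, n_extant, oversampling,
                             max_events, max_attempts)
    elif method == "cpp":
        tree = _simulate_cpp(rng, schedule, n_extant, max_events)
    else:
        raise ValueError(f"unknown method {method!r}")
    return tree


def _induced_tree(tree: CompleteTree, keep: set[int]) -> CompleteTree:
    """Tree induced on a subset of tips, unary nodes suppressed.

    The origin age (stem) is preserved.
    """
    n = tree.n_nodes
    n_keep = [0] * n
    for i in range(n - 1, -1, -1):
        if not tree.children[i]:
            n_keep[i] = 1 if i in keep else 0
        if tree.parent[i] >= 0:
            n_keep[tree.parent[i]] += n_keep[i]
    if n_keep[tree.root] == 0:
        raise ValueError("no tips retained")
    out = CompleteTree(tree.origin_age)
    stack = [(tree.root, -1)]
    while stack:
        node, parent_id = stack.pop()
        kept_kids = [c for c in tree.children[node] if n_keep[c] > 0]
        while len(kept_kids) == 1:  # suppress unary pass-through nodes
            node = kept_kids[0]
            kept_kids = [c for c in tree.children[node] if n_keep[c] > 0]
        nid = out.add_node(tree.age[node], parent_id)
        for c in kept_kids:
            stack.append((c, nid))
    return out


def prune_extinct(tree: CompleteTree) -> tuple[PhyloData, CompleteTree]:
    """Prune all extinct taxa, returning the extant phylogeny.

    Branching ages of the result are exactly the ages of the most
    recent common ancestors among surviving tips; the origin age is
    preserved as the stem age.
    """
    extant = set(tree.extant_tips())
    if not extant:
        raise ValueError("clade is entirely extinct; nothing to prune to")
    pruned = _induced_tree(tree, extant)
    ages = [pruned.age[i] for i in range(pruned.n_nodes) if pruned.children[i]]
    phylo = PhyloData(
        n=len(extant),
        branching_ages=np.array(ages),
        origin_age=tree.origin_age,
        rho=1.0,
    )
    return phylo, pruned


def subsample_extant(
    tree: CompleteTree, rho: float, seed=None
) -> tuple[PhyloData, CompleteTree]:
    """Retain each extant tip independently with probability ``rho``.

    Operates on a tree (topology is needed to recompute MRCA ages);
    the returned :class:`PhyloData` records ``rho``.
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError("rho must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    extant = tree.extant_tips()
    kept = {i for i in extant if rng.random() < rho}
    if len(kept) < 2:
        raise SimulationError(
            f"only {len(kept)} tips survived subsampling at rho={rho}"
        )
    pruned = _induced_tree(tree, kept)
    ages = [pruned.age[i] for i in range(pruned.n_nodes) if pruned.children[i]]
    phylo = PhyloData(
        n=len(kept),
        branching_ages=np.array(ages),
        origin_age=tree.origin_age,
        rho=rho,
    )
    return phylo, pruned
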