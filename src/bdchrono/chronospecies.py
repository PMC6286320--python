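"""Chronospecies delimitation on complete birth-death trees.

Given a complete tree, each branching node is a bifurcation with
probability ``beta`` (the ancestor ends, two new morphospecies start)
and a budding event otherwise (one daughter, chosen uniformly,
continues the ancestral morphospecies).  Anagenetic replacement points
fall along every branch as a Poisson process with rate ``lambda_a``,
each ending the current morphospecies and starting a new one.  A
speciation event of any mode is *cryptic* with probability ``kappa``,
in which case the daughter keeps the ancestor's identity and the two
are merged in the range record (one range spanning from the earliest
origination to the latest extinction).

The output is the set of true stratigraphic ranges together with the
sufficient statistics of the range likelihood: the number of
origination events ``B`` (the start of the process is not a speciation
event), the number of extinction events ``D`` (any range ending before
the present, whether by true extinction, bifurcation or anagenetic
replacement) and the summed range durations ``S``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .treesim import CompleteTree

__all__ = [
    "BDCParams",
    "SpeciesRange",
    "RangeSet",
    "assign_chronospecies",
    "range_statistics",
    "range_bin_statistics",
    "calibrate_anagenesis",
]

MODE_ROOT = "root"
MODE_BUDDING = "budding"
MODE_BIFURCATION = "bifurcation"
MODE_ANAGENESIS = "anagenesis"
MODE_OBSERVED = "observed"  # ranges reconstructed from fossil occurrences


@dataclass(frozen=True)
class BDCParams:
    """Generating parameters of the birth-death chronospecies process."""

    lambda_: float
    mu: float
    beta: float = 0.0
    lambda_a: float = 0.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if self.mu < 0 or self.lambda_a < 0:
            raise ValueError("mu and lambda_a must be non-negative")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must lie in [0, 1]")
        if not 0 <= self.kappa <= 1:
            raise ValueError("kappa must lie in [0, 1]")


@dataclass
class SpeciesRange:
    """One chronospecies: origination and extinction ages plus origin mode."""

    species_id: str
    t_origination: float
    t_extinction: float
    extant: bool
    parent_id: str | None = None
    mode: str = MODE_OBSERVED

    def __post_init__(self) -> None:
        if self.t_extinction < 0 or self.t_origination < self.t_extinction:
            raise ValueError(
                f"range {self.species_id}: need t_origination >= t_extinction >= 0"
            )
        if self.extant and self.t_extinction != 0.0:
            raise ValueError(f"extant range {self.species_id} must end at age 0")

    @property
    def duration(self) -> float:
        return self.t_origination - self.t_extinction


@dataclass
class RangeSet:
    """A collection of stratigraphic ranges."""

    ranges: list[SpeciesRange] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ranges)

    def __iter__(self):
        return iter(self.ranges)

    @property
    def n_extant(self) -> int:
        return sum(1 for r in self.ranges if r.extant)

    def statistics(self) -> tuple[int, int, float]:
        return range_statistics(self)


def assign_chronospecies(
    tree: CompleteTree, params: BDCParams, seed=None
) -> RangeSet:
    """Delimit chronospecies on a complete tree and emit their ranges."""
    rng = np.random.default_rng(seed)
    # per-species bookkeeping; a species may span several tree segments
    # (cryptic events leave it alive on more than one lineage)
    starts: list[float] = []
    ends: list[list[float]] = []
    parents: list[int] = []
    modes: list[str] = []

    def new_species(origin_age: float, parent: int, mode: str) -> int:
        starts.append(origin_age)
        ends.append([])
        parents.append(parent)
        modes.append(mode)
        return len(starts) - 1

    root_sp = new_species(tree.origin_age, -1, MODE_ROOT)
    stack = [(tree.root, tree.origin_age, root_sp)]
    while stack:
        node, edge_start, sp = stack.pop()
        length = edge_start - tree.age[node]
        # anagenetic replacement points along this edge, old -> young
        k = rng.poisson(params.lambda_a * length)
        if k:
            for a in sorted(rng.uniform(tree.age[node], edge_start, size=k),
                            reverse=True):
                if rng.random() < params.kappa:
                    continue  # cryptic: no recognisable replacement
                ends[sp].append(a)
                sp = new_species(a, sp, MODE_ANAGENESIS)
        node_age = tree.age[node]
        kids = tree.children[node]
        if not kids:  # tip: the current species ends here
            ends[sp].append(node_age)
            continue
        bifurcating = rng.random() < params.beta
        cryptic = rng.random() < params.kappa
        if cryptic:
            # daughters keep the ancestral identity, no range event
            stack.append((kids[0], node_age, sp))
            stack.append((kids[1], node_age, sp))
        elif bifurcating:
            ends[sp].append(node_age)
            stack.append((kids[0], node_age, new_species(node_age, sp, MODE_BIFURCATION)))
            stack.append((kids[1], node_age, new_species(node_age, sp, MODE_BIFURCATION)))
        else:
            ends[sp].append(node_age)  # segment boundary; species continues
            cont = int(rng.integers(2))
            stack.append((kids[cont], node_age, sp))
            stack.append((kids[1 - cont], node_age,
                          new_species(node_age, sp, MODE_BUDDING)))
    # a budding continuation re-enters the child edge with the same id;
    # merge its segments: range = [origination, last end]
    out = []
    for i in range(len(starts)):
        t_o = starts[i]
        t_e = min(ends[i])
        out.append(
            SpeciesRange(
                species_id=f"sp{i}",
                t_origination=t_o,
                t_extinction=t_e,
                extant=t_e == 0.0,
                parent_id=None if parents[i] < 0 else f"sp{parents[i]}",
                mode=modes[i],
            )
        )
    return RangeSet(out)


def range_statistics(ranges: RangeSet) -> tuple[int, int, float]:
    """Sufficient statistics (B, D, S) of the range likelihood.

    ``B`` counts origination events: every range except the process
    start (the root species, or -- after subsampling -- the oldest
    retained range, which is treated as the start).  ``D`` counts
    extinct ranges.  ``S`` is the summed duration.
    """
    if not len(ranges):
        raise ValueError("empty range set")
    has_root = any(r.mode == MODE_ROOT for r in ranges)
    if has_root:
        B = sum(1 for r in ranges if r.mode != MODE_ROOT)
    else:
        B = len(ranges) - 1
    D = sum(1 for r in ranges if not r.extant)
    S = float(sum(r.duration for r in ranges))
    if S <= 0:
        raise ValueError("summed range duration is zero; degenerate data")
    return B, D, S


def range_bin_statistics(ranges: RangeSet, boundaries) -> np.ndarray:
    """Per-bin (B_b, D_b, S_b) for the skyline range likelihood.

    ``boundaries`` are the younger bin edges starting at 0; the last
    bin extends beyond the oldest range.  Summing rows recovers the
    global (B, D, S).
    """
    b = np.asarray(boundaries, dtype=float)
    if b[0] != 0 or np.any(np.diff(b) <= 0):
        raise ValueError("bin boundaries must increase from 0")
    hi = np.append(b[1:], np.inf)
    has_root = any(r.mode == MODE_ROOT for r in ranges)
    start_id = None
    if not has_root and len(ranges):
        start_id = max(ranges, key=lambda r: r.t_origination).species_id
    out = np.zeros((len(b), 3))
    for r in ranges:
        is_start = (r.mode == MODE_ROOT) or (r.species_id == start_id)
        if not is_start:
            j = int(np.searchsorted(b, r.t_origination, side="right") - 1)
            out[j, 0] += 1
        if not r.extant:
            j = int(np.searchsorted(b, r.t_extinction, side="right") - 1)
            out[j, 1] += 1
        lo_ov = np.minimum(hi, r.t_origination)
        hi_ov = np.maximum(b, r.t_extinction)
        out[:, 2] += np.maximum(lo_ov - hi_ov, 0.0)
    return out


def calibrate_anagenesis(
    tree: CompleteTree,
    beta: float,
    target_ranges: int,
    step: float = 0.1,
    seed=None,
    kappa: float = 0.0,
    max_lambda_a: float = 10.0,
) -> tuple[float, RangeSet]:
    """Smallest grid value of lambda_a whose realised range count
    reaches ``target_ranges``; the result is uniformly pruned to the
    target count exactly.

    The grid is ``step, 2 step, ...`` up to ``max_lambda_a``.
    """
    rng = np.random.default_rng(seed)
    base = assign_chronospecies(
        tree, BDCParams(1.0, 0.0, beta=beta, lambda_a=0.0, kappa=kappa), rng
    )
    if target_ranges < len(base):
        raise ValueError(
            f"target_ranges={target_ranges} below the {len(base)} species "
            "already present without anagenesis"
        )
    lam_a = step
    while lam_a <= max_lambda_a + 1e-12:
        rs = assign_chronospecies(
            tree, BDCParams(1.0, 0.0, beta=beta, lambda_a=lam_a, kappa=kappa), rng
        )
        if len(rs) >= target_ranges:
            idx = rng.choice(len(rs), size=target_ranges, replace=False)
            pruned = RangeSet([rs.ranges[i] for i in sorted(idx)])
            return lam_a, pruned
        lam_a = round(lam_a + step, 12)
    raise RuntimeError(
        f"range count target {target_ranges} unreachable with lambda_a "
        f"<= {max_lambda_a}"
    )
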