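"""Readers and writers for on-disk artifacts.

Conventions (worth stating prominently, because mixing age and
forward-time conventions is the classic failure mode in this domain):
all ages are times before present, present = 0, increasing into the
past.  Tables are TSV (UTF-8, '.' decimal separator) to avoid locale
issues; trees are Newick with branch lengths in time units.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .chronospecies import RangeSet, SpeciesRange
from .fossilize import OccurrenceTable
from .treesim import CompleteTree, PhyloData

__all__ = [
    "read_newick",
    "write_newick",
    "phylo_from_newick",
    "read_ranges",
    "write_ranges",
    "read_occurrences",
    "write_occurrences",
    "write_trace",
    "read_trace",
    "RunConfig",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def read_newick(path) -> dendropy.Tree:
    """Read a rooted Newick tree, insisting on well-formed branch lengths."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise ParseError(f"cannot parse Newick file {path}: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # the root edge may legitimately be absent
        if edge.length is None:
            raise ParseError(f"{path}: edge into {edge.head_node} lacks a length")
        if edge.length < 0:
            raise ParseError(f"{path}: negative branch length {edge.length}")
    return tree


def write_newick(tree, path) -> None:
    """Write a CompleteTree or dendropy.Tree to a Newick file."""
    path = Path(path)
    if isinstance(tree, CompleteTree):
        path.write_text(tree.newick() + "\n")
    else:
        tree.write(path=str(path), schema="newick", suppress_rooting=True)


def _node_ages(tree: dendropy.Tree) -> dict:
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + node.edge.length
    max_depth = max(depth[leaf] for leaf in tree.leaf_node_iter())
    return {node: max_depth - d for node, d in depth.items()}, max_depth


def phylo_from_newick(
    source, rho: float = 1.0, origin_age: float | None = None,
    ultrametric_tol: float = 1e-6,
) -> PhyloData:
    """Branching ages of a dated extant-species tree.

    The tree must be ultrametric within ``ultrametric_tol`` (all tips
    at the present).  If the Newick carries a root edge length, the
    origin (stem) age is taken as crown age plus that length unless
    ``origin_age`` overrides it.
    """
    tree = read_newick(source) if not isinstance(source, dendropy.Tree) else source
    ages, _ = _node_ages(tree)
    tip_ages = [ages[leaf] for leaf in tree.leaf_node_iter()]
    if max(tip_ages) > ultrametric_tol:
        raise ParseError(
            f"tree is not ultrametric: tip age spread {max(tip_ages):.3g} "
            f"exceeds tolerance {ultrametric_tol:g}"
        )
    branching = sorted(
        (ages[n] for n in tree.preorder_internal_node_iter()), reverse=True
    )
    n = sum(1 for _ in tree.leaf_node_iter())
    if origin_age is None and tree.seed_node.edge.length is not None:
        origin_age = branching[0] + tree.seed_node.edge.length
    return PhyloData(n=n, branching_ages=np.array(branching),
                     origin_age=origin_age, rho=rho)


# ---------------------------------------------------------------------------
# ranges and occurrences
# ---------------------------------------------------------------------------

_RANGE_COLS = ["species_id", "origination_age", "extinction_age", "status",
               "parent_id", "mode"]


def write_ranges(ranges: RangeSet, path) -> None:
    rows = [
        {
            "species_id": r.species_id,
            "origination_age": r.t_origination,
            "extinction_age": r.t_extinction,
            "status": "extant" if r.extant else "extinct",
            "parent_id": r.parent_id if r.parent_id is not None else "",
            "mode": r.mode,
        }
        for r in ranges
    ]
    pd.DataFrame(rows, columns=_RANGE_COLS).to_csv(path, sep="\t", index=False)


def read_ranges(path) -> RangeSet:
    df = pd.read_csv(path, sep="\t", dtype={"species_id": str, "parent_id": str})
    missing = set(_RANGE_COLS[:4]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: range table lacks columns {sorted(missing)}")
    if df["species_id"].duplicated().any():
        dups = df["species_id"][df["species_id"].duplicated()].tolist()
        raise ParseError(f"{path}: duplicate species ids {dups}")
    out = []
    for i, row in df.iterrows():
        t_o, t_e = float(row["origination_age"]), float(row["extinction_age"])
        extant = str(row["status"]).strip().lower() == "extant"
        if t_e > t_o:
            raise ParseError(
                f"{path}, row {i}: extinction age {t_e} exceeds origination {t_o}"
            )
        if t_o < 0 or t_e < 0:
            raise ParseError(f"{path}, row {i}: negative age")
        if extant and t_e != 0.0:
            raise ParseError(f"{path}, row {i}: extant range must end at age 0")
        parent = row.get("parent_id", "")
        parent = None if (pd.isna(parent) or parent == "") else str(parent)
        mode = row.get("mode", "observed")
        mode = "observed" if pd.isna(mode) else str(mode)
        out.append(SpeciesRange(str(row["species_id"]), t_o, t_e, extant,
                                parent_id=parent, mode=mode))
    return RangeSet(out)


def write_occurrences(occ: OccurrenceTable, path) -> None:
    occ.data[["species_id", "age"]].to_csv(path, sep="\t", index=False)


def read_occurrences(path) -> OccurrenceTable:
    """Read an occurrence TSV.

    Accepts the native two-column layout with a ``species_id\\tage``
    header, or a headerless two-column file (species, age) as used by
    simple occurrence exports.
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    headerless = False
    if len(first) >= 2:
        try:
            float(first[1])
            headerless = True
        except ValueError:
            headerless = False
    if headerless:
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                         names=["species_id", "age"], dtype={0: str})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"species_id": str})
        if "species_id" not in df.columns or "age" not in df.columns:
            raise ParseError(
                f"{path}: expected columns species_id and age, got {list(df.columns)}"
            )
        df = df[["species_id", "age"]]
    if df["age"].isna().any() or (df["age"] < 0).any():
        raise ParseError(f"{path}: occurrence ages must be non-negative numbers")
    return OccurrenceTable(df)


def write_trace(sample, path) -> None:
    """Posterior draws as a TSV trace (iteration, logpost, parameters)."""
    df = sample.draws.copy()
    df.insert(0, "logpost", sample.logpost)
    df.insert(0, "iteration", np.arange(sample.burnin, sample.burnin + len(df)))
    df.to_csv(path, sep="\t", index=False)


def read_trace(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Flat key-value settings for a simulation / analysis run.

    Unknown keys are rejected on load; every run writes its resolved
    configuration next to its outputs.
    """

    lambda_: float = 0.2
    mu: float = 0.16
    beta: float = 0.0
    lambda_a: float = 0.0
    kappa: float = 0.0
    n_extant: int = 200
    rho: float = 1.0
    shift_ages: list[float] | None = None      # older-interval edges
    shift_lambdas: list[float] | None = None   # rates older than each edge
    shift_mus: list[float] | None = None
    removal_scheme: str | None = None          # uniform | extinct_only | extant_only
    removal_prob: float = 0.0
    psi: float | None = None
    include_extant_at_present: bool = True
    alpha_levels: tuple[float, ...] = (0.95, 0.99)
    condition: str = "origin"
    method: str = "auto"
    restarts: int = 5
    iterations: int = 50000
    burnin: float = 0.25
    bins: list[float] | None = None
    seed: int = 1
    n_reps: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["alpha_levels"] = list(d["alpha_levels"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def schedule(self):
        from .treesim import RateSchedule
        import math

        if not self.shift_ages:
            return RateSchedule.constant(self.lambda_, self.mu)
        edges = [0.0, *self.shift_ages]
        lams = [self.lambda_, *(self.shift_lambdas or [])]
        mus = [self.mu, *(self.shift_mus or [])]
        if len(lams) != len(edges) or len(mus) != len(edges):
            raise ParseError("shift_lambdas/shift_mus must match shift_ages")
        intervals = []
        for j in range(len(edges)):
            hi = edges[j + 1] if j + 1 < len(edges) else math.inf
            intervals.append((edges[j], hi, lams[j], mus[j]))
        return RateSchedule(tuple(intervals))
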