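"""Dated-tree operations: IO, ultrametricity checks, time-slicing, pruning,
posterior sampling and Brownian covariance matrices.

A :class:`Chronogram` wraps a rooted :class:`dendropy.Tree` whose edge lengths
are in millions of years (My) and whose tips are contemporaneous (age 0).
Evolutionary units are delimited by slicing the chronogram at a fixed age
before present: every edge that spans the slice defines one unit containing
all tips descending from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "PhyloCovariance",
    "UnitDelimitation",
    "TreeError",
    "read_trees",
    "write_trees",
    "cut_at_age",
    "prune_to_units",
    "retain_tips",
    "sample_posterior",
    "phylo_covariance",
]

#: default relative tolerance (fraction of root depth) for ultrametricity
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised on malformed trees or contract violations in tree operations."""


def _edge_len(node: dendropy.Node) -> float:
    length = node.edge.length
    return 0.0 if length is None else float(length)


@dataclass
class Chronogram:
    """A rooted tree with edge lengths in My; tips assumed contemporaneous."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tips
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate tip labels in chronogram")

    # -- basic accessors ---------------------------------------------------
    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def _depths(self) -> dict[dendropy.Node, float]:
        """Distance of every node from the root."""
        depths: dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            depths[node] = (0.0 if parent is None else depths[parent]) + (
                _edge_len(node) if parent is not None else 0.0
            )
        return depths

    @property
    def root_depth(self) -> float:
        depths = self._depths()
        return max(depths[leaf] for leaf in self.tree.leaf_node_iter())

    @property
    def max_ultrametric_deviation(self) -> float:
        """Max minus min root-to-tip path length, in My."""
        depths = self._depths()
        tip_depths = [depths[leaf] for leaf in self.tree.leaf_node_iter()]
        return max(tip_depths) - min(tip_depths)

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        depth = self.root_depth
        if depth == 0:
            return True
        return self.max_ultrametric_deviation <= rtol * depth

    def node_ages(self) -> dict[dendropy.Node, float]:
        """Age (time before present) of every node; tips have age ~0."""
        depths = self._depths()
        root_depth = max(depths[leaf] for leaf in self.tree.leaf_node_iter())
        return {node: root_depth - d for node, d in depths.items()}

    # -- construction / serialization --------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Chronogram":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:
            raise TreeError(f"could not parse newick string: {exc}") from exc
        return cls(tree)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def clone(self) -> "Chronogram":
        return Chronogram(self.tree.clone(depth=1))


@dataclass
class UnitDelimitation:
    """Partition of the tip set into evolutionary units at a fixed cut age."""

    cut_age: float
    units: dict[str, tuple[str, ...]]
    representatives: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.representatives:
            self.representatives = {
                uid: min(members) for uid, members in self.units.items()
            }
        for uid, rep in self.representatives.items():
            if rep not in self.units[uid]:
                raise TreeError(f"representative {rep!r} not a member of unit {uid!r}")

    @property
    def n_units(self) -> int:
        return len(self.units)

    def membership(self) -> dict[str, str]:
        """tip label -> unit id."""
        out: dict[str, str] = {}
        for uid, members in self.units.items():
            for tip in members:
                out[tip] = uid
        return out


@dataclass
class PhyloCovariance:
    """Tip-by-tip Brownian covariance: C[i, j] = root-to-MRCA path length."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise TreeError("covariance shape does not match label count")

    def reorder(self, labels: list[str]) -> "PhyloCovariance":
        idx = [self.labels.index(lab) for lab in labels]
        return PhyloCovariance(list(labels), self.matrix[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# IO


def read_trees(path: str, schema: str = "newick") -> list[Chronogram]:
    """Read one or more dated trees from a Newick or NEXUS file.

    Non-ultrametric trees are returned but flagged with a warning carrying
    their maximum root-to-tip deviation.
    """
    if schema not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree schema {schema!r}")
    try:
        tree_list = dendropy.TreeList.get(path=path, schema=schema)
    except Exception as exc:  # dendropy raises several parser error types
        raise TreeError(f"could not parse {path!r} as {schema}: {exc}") from exc
    chronos = [Chronogram(t) for t in tree_list]
    for i, chrono in enumerate(chronos):
        if not chrono.is_ultrametric():
            warnings.warn(
                f"tree {i} in {path!r} is not ultrametric "
                f"(max deviation {chrono.max_ultrametric_deviation:.6g} My)",
                stacklevel=2,
            )
    return chronos


def write_trees(trees: list[Chronogram], path: str, schema: str = "newick") -> None:
    taxa = dendropy.TaxonNamespace()
    tree_list = dendropy.TreeList(taxon_namespace=taxa)
    for chrono in trees:
        tree_list.append(
            dendropy.Tree.get(
                data=chrono.as_newick(), schema="newick", taxon_namespace=taxa
            )
        )
    tree_list.write(path=path, schema=schema)


# ---------------------------------------------------------------------------
# time slicing


def cut_at_age(chrono: Chronogram, cut_age: float) -> UnitDelimitation:
    """Delimit evolutionary units by slicing the chronogram at ``cut_age``.

    Every edge whose parent is older than ``cut_age`` and whose child is at
    or below ``cut_age`` spans the slice; the tips descending from that edge
    form one unit.  A node sitting exactly at ``cut_age`` therefore yields a
    single unit for the whole clade below it (closed slice on the rootward
    side).  Unit ids are assigned in order of the lexicographically smallest
    member label.
    """
    if cut_age <= 0:
        raise ValueError("cut_age must be positive")
    root_depth = chrono.root_depth
    if cut_age >= root_depth:
        warnings.warn(
            f"cut_age {cut_age} >= root depth {root_depth:.6g}: single unit",
            stacklevel=2,
        )
        members = tuple(sorted(chrono.tips))
        return UnitDelimitation(cut_age, {"u01": members})

    ages = chrono.node_ages()
    groups: list[tuple[str, ...]] = []
    for node in chrono.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        if ages[parent] > cut_age >= ages[node]:
            tips = tuple(
                sorted(leaf.taxon.label for leaf in node.leaf_iter())
            )
            groups.append(tips)
    groups.sort(key=lambda tips: tips[0])
    width = max(2, len(str(len(groups))))
    units = {f"u{i + 1:0{width}d}": tips for i, tips in enumerate(groups)}
    delim = UnitDelimitation(cut_age, units)
    # sanity: the units must partition the tip set
    member_union = sorted(t for tips in units.values() for t in tips)
    if member_union != sorted(chrono.tips):
        raise TreeError("internal error: units do not partition the tip set")
    return delim


def prune_to_units(
    chrono: Chronogram,
    delim: UnitDelimitation,
    drop_units: tuple[str, ...] = (),
) -> Chronogram:
    """Retain one representative tip per unit, preserving all node depths.

    ``drop_units`` removes whole units (e.g. a unit with no phenotypic data)
    before pruning.  The pruned tree keeps the original root, so it remains
    ultrametric at the original root depth.
    """
    unknown = set(drop_units) - set(delim.units)
    if unknown:
        raise TreeError(f"unknown unit id(s) in drop list: {sorted(unknown)}")
    keep = {
        rep for uid, rep in delim.representatives.items() if uid not in drop_units
    }
    return retain_tips(chrono, keep)


def retain_tips(chrono: Chronogram, keep) -> Chronogram:
    """Prune to a tip subset, preserving every retained node's depth."""
    keep = set(keep)
    missing = keep - set(chrono.tips)
    if missing:
        raise TreeError(f"representatives not in tree: {sorted(missing)}")
    if not keep:
        raise TreeError("pruning would remove every tip")

    pruned = chrono.clone()
    tree = pruned.tree
    # drop unwanted leaves, then merge resulting unifurcations (root kept)
    changed = True
    while changed:
        changed = False
        for leaf in list(tree.leaf_node_iter()):
            if leaf.taxon is None or leaf.taxon.label not in keep:
                parent = leaf.parent_node
                if parent is None:
                    raise TreeError("pruning would remove the root")
                parent.remove_child(leaf)
                changed = True
    for node in list(tree.preorder_node_iter()):
        children = node.child_nodes()
        if len(children) == 1 and node.parent_node is not None:
            child = children[0]
            child.edge.length = _edge_len(child) + _edge_len(node)
            parent = node.parent_node
            parent.remove_child(node)
            parent.add_child(child)
    tree.update_taxon_namespace()
    return Chronogram(tree)


# ---------------------------------------------------------------------------
# posterior sampling


def sample_posterior(
    trees: list[Chronogram],
    k: int,
    seed: int | np.random.Generator | None = None,
    replace: bool = False,
) -> list[Chronogram]:
    """Uniform random sample of ``k`` trees from a posterior collection."""
    if not trees:
        raise TreeError("empty tree collection")
    if not replace and k > len(trees):
        raise ValueError(
            f"cannot sample {k} trees without replacement from {len(trees)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(trees), size=k, replace=replace)
    return [trees[i] for i in idx]


# ---------------------------------------------------------------------------
# Brownian covariance


def phylo_covariance(
    chrono: Chronogram, force_ultrametric: bool = False
) -> PhyloCovariance:
    """Expected Brownian covariance among tips.

    ``C[i, j]`` is the depth (from the root) of the MRCA of tips *i* and *j*;
    the diagonal holds tip depths.  Trees beyond the ultrametricity tolerance
    are rejected unless ``force_ultrametric`` extends every tip to the
    maximum depth.
    """
    work = chrono
    if not chrono.is_ultrametric():
        if not force_ultrametric:
            raise TreeError(
                "tree is not ultrametric (max deviation "
                f"{chrono.max_ultrametric_deviation:.6g} My); "
                "pass force_ultrametric=True to extend tips"
            )
        work = chrono.clone()
        depths = work._depths()
        target = max(depths[leaf] for leaf in work.tree.leaf_node_iter())
        for leaf in work.tree.leaf_node_iter():
            leaf.edge.length = _edge_len(leaf) + (target - depths[leaf])

    labels = work.tips
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    depths = work._depths()

    tip_sets: dict[dendropy.Node, list[int]] = {}
    for node in work.tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            tip_sets[node] = [i]
            C[i, i] = depths[node]
        else:
            child_sets = [tip_sets.pop(c) for c in node.child_nodes()]
            d = depths[node]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            C[i, j] = C[j, i] = d
            tip_sets[node] = [i for s in child_sets for i in s]
    return PhyloCovariance(labels, C)
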