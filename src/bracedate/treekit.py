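"""Rooted-tree data model and Newick/Nexus I/O.

All downstream machinery (the approximate likelihood, the priors, the
sampler) works on flat numpy arrays indexed by a *canonical* node
numbering, so that trees read from different files — or produced by
different programs that order children differently — map onto the same
branch index space.  Canonicalisation is by tip-label bipartitions:
children are ordered by their smallest descendant tip label and nodes are
numbered in post-order, tips first.  The branch above a non-root node
shares that node's index; the root (index ``n_nodes - 1``) has no branch.

Ages are measured backward from the present in Ma: every tip sits at age 0
and each internal node is strictly older than its children.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "RootedTopology",
    "BranchLengthTree",
    "TimeTree",
    "PosteriorSample",
    "parse_newick",
    "read_tree_sample",
    "mrca",
    "branch_durations",
    "write_dated_tree",
]


class TreeError(ValueError):
    """Raised on malformed, unrooted, or mutually incompatible trees."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RootedTopology:
    """A strictly bifurcating rooted topology with canonical node indices.

    Attributes
    ----------
    tip_labels
        Unique tip labels; ``tip_labels[i]`` names node ``i`` for
        ``i < n_tips``.
    parent
        ``parent[v]`` is the parent node of ``v``; ``-1`` for the root.
    children
        ``children[v]`` is a tuple of child indices (empty for tips,
        length 2 for internal nodes).
    """

    tip_labels: tuple[str, ...]
    parent: np.ndarray
    children: tuple[tuple[int, ...], ...]
    clades: tuple[frozenset[str], ...] = field(repr=False, default=())

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_branches(self) -> int:
        """Branches above non-root nodes; branch index == node index."""
        return self.n_nodes - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def internal_nodes(self) -> np.ndarray:
        return np.arange(self.n_tips, self.n_nodes)

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    def postorder(self) -> np.ndarray:
        """Node indices in post-order (children before parents).

        By construction of the canonical numbering, internal indices are
        already in post-order completion order; interleaving tips before
        their parents yields a valid post-order.
        """
        order: list[int] = []
        seen = [False] * self.n_nodes

        def visit(v: int) -> None:
            for c in self.children[v]:
                visit(c)
            order.append(v)

        visit(self.root)
        del seen
        return np.asarray(order, dtype=np.intp)

    def tip_index(self, label: str) -> int:
        try:
            return self.tip_labels.index(label)
        except ValueError:
            raise TreeError(f"unknown tip label {label!r}") from None

    def clade(self, v: int) -> frozenset[str]:
        return self.clades[v]

    def subtree_nodes(self, v: int) -> list[int]:
        """All nodes in the subtree rooted at ``v``, including ``v``."""
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(self.children[u])
        return out

    def __eq__(self, other: object) -> bool:  # structural equality
        if not isinstance(other, RootedTopology):
            return NotImplemented
        return (
            self.tip_labels == other.tip_labels
            and np.array_equal(self.parent, other.parent)
            and self.children == other.children
        )

    def __hash__(self) -> int:
        return hash((self.tip_labels, self.parent.tobytes(), self.children))


@dataclass
class BranchLengthTree:
    """Per-branch expected substitutions/site on a fixed topology."""

    topology: RootedTopology
    lengths: np.ndarray  # shape (n_branches,), >= 0

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.shape != (self.topology.n_branches,):
            raise TreeError(
                f"expected {self.topology.n_branches} branch lengths, "
                f"got shape {self.lengths.shape}"
            )
        if np.any(self.lengths < 0) or not np.all(np.isfinite(self.lengths)):
            raise TreeError("branch lengths must be finite and non-negative")


@dataclass
class TimeTree:
    """Node ages in Ma before present on a fixed topology.

    Tips are contemporaneous at age 0 and each internal node is strictly
    older than its children.
    """

    topology: RootedTopology
    ages: np.ndarray  # shape (n_nodes,)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.validate()

    def validate(self) -> None:
        top = self.topology
        if self.ages.shape != (top.n_nodes,):
            raise TreeError("one age per node required")
        if np.any(self.ages[: top.n_tips] != 0.0):
            raise TreeError("all tip ages must be 0")
        nonroot = np.arange(top.n_nodes - 1)
        if np.any(self.ages[top.parent[nonroot]] <= self.ages[nonroot]):
            raise TreeError("every internal node must be strictly older than its children")
        if self.ages[top.root] <= 0:
            raise TreeError("root age must be positive")

    @property
    def root_age(self) -> float:
        return float(self.ages[self.topology.root])


@dataclass
class PosteriorSample:
    """An ordered sample of branch-length trees on one shared topology.

    ``lengths`` is an (n_trees, n_branches) matrix in the topology's
    canonical branch index space.
    """

    topology: RootedTopology
    lengths: np.ndarray
    source: str = "<memory>"
    burn_in: int = 0
    stride: int = 1

    def __post_init__(self) -> None:
        self.lengths = np.atleast_2d(np.asarray(self.lengths, dtype=float))
        if self.lengths.shape[1] != self.topology.n_branches:
            raise TreeError("sample branch dimension does not match topology")
        if len(self) < 2:
            raise TreeError("a posterior sample needs at least 2 trees")

    def __len__(self) -> int:
        return self.lengths.shape[0]

    def trees(self) -> Iterable[BranchLengthTree]:
        for row in self.lengths:
            yield BranchLengthTree(self.topology, row)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _canonicalise(tree: dendropy.Tree) -> tuple[RootedTopology, np.ndarray | None]:
    """Build the canonical topology (and lengths, if all present)."""
    root = tree.seed_node
    if len(root.child_nodes()) != 2:
        raise TreeError(
            "unrooted input: the tree has a top-level multifurcation; "
            "please supply a rooted (bifurcating at the root) tree"
        )

    labels: list[str] = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise TreeError("every tip must carry a label")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")
    if len(labels) < 2:
        raise TreeError("a tree needs at least 2 tips")

    # smallest descendant tip label per node, for deterministic child order
    def min_label(nd: dendropy.Node) -> str:
        if nd.is_leaf():
            return nd.taxon.label
        return min(min_label(c) for c in nd.child_nodes())

    n_tips = len(labels)
    tip_ids: dict[int, int] = {}
    internal_order: list[dendropy.Node] = []
    tip_order: list[dendropy.Node] = []

    def visit(nd: dendropy.Node) -> None:
        if nd.is_leaf():
            tip_order.append(nd)
            return
        kids = nd.child_nodes()
        if len(kids) != 2:
            raise TreeError("multifurcating internal node: supply a bifurcating tree")
        for c in sorted(kids, key=min_label):
            visit(c)
        internal_order.append(nd)

    visit(root)

    index: dict[dendropy.Node, int] = {}
    for i, nd in enumerate(tip_order):
        index[nd] = i
    for k, nd in enumerate(internal_order):
        index[nd] = n_tips + k

    n_nodes = n_tips + len(internal_order)
    parent = np.full(n_nodes, -1, dtype=np.intp)
    children: list[tuple[int, ...]] = [()] * n_nodes
    clades: list[frozenset[str]] = [frozenset()] * n_nodes
    tip_labels = tuple(nd.taxon.label for nd in tip_order)

    lengths = np.full(n_nodes - 1, np.nan)
    have_lengths = True
    for nd, i in index.items():
        if nd is root:
            continue
        parent[i] = index[nd.parent_node]
        if nd.edge.length is None:
            have_lengths = False
        else:
            lengths[i] = nd.edge.length
    for nd in internal_order:
        children[index[nd]] = tuple(sorted(index[c] for c in nd.child_nodes()))
    for i, lab in enumerate(tip_labels):
        clades[i] = frozenset([lab])
    for nd in internal_order:
        i = index[nd]
        clades[i] = frozenset().union(*(clades[c] for c in children[i]))

    top = RootedTopology(
        tip_labels=tip_labels,
        parent=parent,
        children=tuple(children),
        clades=tuple(clades),
    )
    return top, (lengths if have_lengths else None)


def _parse_dendropy(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc


def parse_newick(text: str) -> tuple[RootedTopology, BranchLengthTree | None]:
    """Parse a single rooted Newick string.

    Returns the canonical topology and, when every branch in the input
    carries a length, the corresponding :class:`BranchLengthTree`
    (otherwise ``None``).  A top-level trifurcation is rejected as
    unrooted input.
    """
    top, lengths = _canonicalise(_parse_dendropy(text))
    if lengths is None:
        return top, None
    return top, BranchLengthTree(top, lengths)


def map_onto(topology: RootedTopology, other: RootedTopology,
             lengths: np.ndarray) -> np.ndarray:
    """Re-index branch lengths from ``other``'s numbering into ``topology``'s.

    Branch identity is established by tip-label bipartitions (clades);
    raises :class:`TreeError` when the topologies differ.
    """
    if set(topology.tip_labels) != set(other.tip_labels):
        raise TreeError("tip label sets differ")
    lut = {topology.clades[v]: v for v in range(topology.n_branches)}
    out = np.empty(topology.n_branches)
    for v in range(other.n_branches):
        tgt = lut.get(other.clades[v])
        if tgt is None:
            raise TreeError("topology mismatch: clade "
                            f"{sorted(other.clades[v])} not present")
        out[tgt] = lengths[v]
    return out


def _iter_tree_strings(text: str) -> Iterable[str]:
    """Yield Newick strings from a Newick list or a Nexus trees block."""
    stripped = text.lstrip()
    if stripped[:6].upper() == "#NEXUS":
        trees = dendropy.TreeList.get(
            data=text, schema="nexus", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        for t in trees:
            yield t.as_string(schema="newick", suppress_rooting=True)
    else:
        for line in text.splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                yield line


def read_tree_sample(path, burn_in: int = 0, stride: int = 1) -> PosteriorSample:
    """Read a posterior tree sample, discarding burn-in and thinning.

    Trees at positions ``burn_in, burn_in + stride, ...`` (0-based) are
    retained and mapped onto the shared canonical branch index of the
    first retained tree.  All trees must share one topology; the first
    discordant tree is named in the error.
    """
    if burn_in < 0 or stride < 1:
        raise ValueError("burn_in must be >= 0 and stride >= 1")
    with open(path) as fh:
        text = fh.read()

    topology: RootedTopology | None = None
    rows: list[np.ndarray] = []
    for pos, tree_str in enumerate(_iter_tree_strings(text)):
        if pos < burn_in or (pos - burn_in) % stride != 0:
            continue
        top_i, blt = parse_newick(tree_str)
        if blt is None:
            raise TreeError(f"tree at position {pos} lacks branch lengths")
        if topology is None:
            topology = top_i
            rows.append(blt.lengths)
        else:
            try:
                rows.append(map_onto(topology, top_i, blt.lengths))
            except TreeError as exc:
                raise TreeError(
                    f"tree at position {pos} in {path} does not match the "
                    f"shared topology: {exc}"
                ) from exc
    if topology is None or not rows:
        raise TreeError(f"no trees retained from {path} "
                        f"(burn_in={burn_in}, stride={stride})")
    return PosteriorSample(topology, np.vstack(rows), source=str(path),
                           burn_in=burn_in, stride=stride)


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------


def mrca(topology: RootedTopology, taxa: Iterable[str]) -> int:
    """Most recent common ancestor of a set of tip labels.

    The MRCA of a single tip is that tip.
    """
    taxa = set(taxa)
    if not taxa:
        raise ValueError("taxa must be nonempty")
    nodes = [topology.tip_index(t) for t in sorted(taxa)]
    # walk each tip's ancestor path; the MRCA is the first common node.
    v = nodes[0]
    target = frozenset(taxa)
    while not target <= topology.clades[v]:
        v = int(topology.parent[v])
        if v < 0:  # pragma: no cover - clades cover root
            raise TreeError("no common ancestor found")
    return v


def branch_durations(tree: TimeTree) -> np.ndarray:
    """Per-branch time spans in Ma: age(parent) - age(child), all > 0."""
    top = tree.topology
    nonroot = np.arange(top.n_branches)
    d = tree.ages[top.parent[nonroot]] - tree.ages[nonroot]
    if np.any(d <= 0):
        raise TreeError("violated age ordering: non-positive branch duration")
    return d


# ---------------------------------------------------------------------------
# annotated output
# ---------------------------------------------------------------------------


def _newick_annotated(tree: TimeTree, node_annot: dict[int, str]) -> str:
    top = tree.topology

    def render(v: int) -> str:
        if top.is_tip(v):
            core = _quote_label(top.tip_labels[v])
        else:
            core = "(" + ",".join(render(c) for c in top.children[v]) + ")"
        comment = node_annot.get(v, "")
        p = top.parent[v]
        if p >= 0:
            bl = tree.ages[p] - tree.ages[v]
            return f"{core}{comment}:{bl:.8g}"
        return f"{core}{comment}"

    return render(top.root) + ";"


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.\-]+$")


def _quote_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_dated_tree(tree: TimeTree, summary, path) -> None:
    """Write a dated tree as Nexus with per-internal-node age annotations.

    ``summary`` must provide ``mean_age``, ``hpd_lower`` and ``hpd_upper``
    mappings covering every internal node (a :class:`~bracedate.sampler.
    TraceSummary` does).  Annotations are embedded as
    ``[&age=...,hpd={...,...}]`` comments; the file round-trips through
    :func:`parse_newick`.
    """
    top = tree.topology
    annot: dict[int, str] = {}
    for v in top.internal_nodes:
        v = int(v)
        try:
            mean = summary.mean_age[v]
            lo = summary.hpd_lower[v]
            hi = summary.hpd_upper[v]
        except (KeyError, IndexError):
            raise TreeError(f"summary is missing internal node {v}") from None
        if not (lo <= mean <= hi):
            raise TreeError(
                f"refusing to write node {v}: HPD ({lo}, {hi}) does not "
                f"bracket the mean {mean}"
            )
        annot[v] = f"[&age={mean:.8g},hpd={{{lo:.8g},{hi:.8g}}}]"

    newick = _newick_annotated(tree, annot)
    with open(path, "w") as fh:
        fh.write("#NEXUS\nbegin trees;\n")
        fh.write(f"  tree dated = [&R] {newick}\n")
        fh.write("end;\n")


def read_dated_tree_newick(path) -> tuple[RootedTopology, BranchLengthTree | None]:
    """Re-parse a file written by :func:`write_dated_tree`."""
    with open(path) as fh:
        text = fh.read()
    m = re.search(r"tree\s+\S+\s*=\s*(?:\[&R\]\s*)?(.*;)", text, re.S)
    if not m:
        raise TreeError(f"no tree found in {path}")
    newick = re.sub(r"\[[^\]]*\]", "", m.group(1))
    return parse_newick(newick)
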