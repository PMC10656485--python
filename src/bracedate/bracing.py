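"""Constraint resolution and cross-brace discovery.

A cross-brace ties nodes that represent the same speciation event seen
through different gene copies — ancient paralogs from a pre-root gene
duplication, or the nuclear/mitochondrial/plastid clades created by
endosymbiotic genome transfer — to a common, jointly estimated age.

Discovery works on a *copy map* assigning each tip a (species, copy)
pair.  Within each copy subtree, every internal node is identified by the
set of species it subtends intersected with the species shared by all
copies; nodes in different copies with the same intersected species set
mark the same speciation event and are grouped into one brace.  The
intersection makes the matching robust to asymmetric taxon loss between
copies, which is the rule rather than the exception in organellar data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import yaml

from .priors import Brace, Calibration, RelativeConstraint
from .treekit import RootedTopology, TreeError, mrca

__all__ = ["CopyMap", "ConstraintSet", "find_equivalent_nodes",
           "assemble_constraints", "load_constraint_config",
           "save_constraint_config", "read_copy_map", "write_copy_map"]


@dataclass(frozen=True)
class CopyMap:
    """Per-tip assignment of (species, copy), e.g. ``Homo_nuc -> (Homo, nuc)``."""

    assignment: Mapping[str, tuple[str, str]]

    def species(self, tip: str) -> str:
        return self.assignment[tip][0]

    def copy(self, tip: str) -> str:
        return self.assignment[tip][1]

    @property
    def copy_labels(self) -> tuple[str, ...]:
        return tuple(sorted({c for _, c in self.assignment.values()}))

    def tips_of_copy(self, copy: str) -> frozenset[str]:
        return frozenset(t for t, (_, c) in self.assignment.items() if c == copy)

    def species_of_copy(self, copy: str) -> frozenset[str]:
        return frozenset(s for _, (s, c) in self.assignment.items() if c == copy)

    def validate_against(self, topology: RootedTopology) -> None:
        missing = set(topology.tip_labels) - set(self.assignment)
        if missing:
            raise TreeError(f"copy map missing tips: {sorted(missing)}")
        if len(self.copy_labels) < 2:
            raise TreeError("copy map must define at least 2 copy labels")


@dataclass
class ConstraintSet:
    """Calibrations, braces, and relative constraints resolved to nodes."""

    topology: RootedTopology
    calibrations: tuple[Calibration, ...] = ()
    braces: tuple[Brace, ...] = ()
    relatives: tuple[RelativeConstraint, ...] = ()

    def root_calibration(self) -> Calibration | None:
        """The calibration on the root node, if any (merged max wins)."""
        root = self.topology.root
        best = None
        for cal in self.calibrations:
            if cal.node == root and cal.max_age is not None:
                if best is None or cal.max_age < best.max_age:
                    best = cal
        return best


def _copy_monophyletic(topology: RootedTopology, tips: frozenset[str]) -> bool:
    if len(tips) == 1:
        return True
    node = mrca(topology, tips)
    return topology.clades[node] == tips


def find_equivalent_nodes(topology: RootedTopology, copies: CopyMap,
                          scope: Iterable[str] | None = None,
                          sigma: float = 1.0,
                          strict: bool = False) -> list[Brace]:
    """Discover brace groups of equivalent speciation nodes across copies.

    Parameters
    ----------
    scope
        Optional species set; only nodes whose (intersected) species sets
        are subsets of the scope are braced — e.g. brace only within
        eukaryotes.
    sigma
        Softness (Ma) assigned to every emitted brace.
    strict
        Require exact species-set equality instead of equality after
        intersection with the species shared by all copies.

    Returns braces sorted deterministically by their species sets; each
    group has >= 2 member nodes spanning >= 2 species.
    """
    copies.validate_against(topology)
    labels = copies.copy_labels
    bad = [c for c in labels
           if not _copy_monophyletic(topology, copies.tips_of_copy(c))]
    if bad:
        raise TreeError(f"copy subtrees not monophyletic for copies: {bad}")

    shared = frozenset.intersection(*(copies.species_of_copy(c) for c in labels))
    if scope is not None:
        shared = shared & frozenset(scope)
    if not shared:
        raise TreeError("no species shared between copies (within scope)")

    if len(labels) < 2:
        return []

    # candidate keys: intersected species sets realised by internal nodes
    keys: set[frozenset[str]] = set()
    per_copy_species: dict[str, frozenset[str]] = {
        c: copies.species_of_copy(c) for c in labels}
    for c in labels:
        sub = topology.subtree_nodes(mrca(topology, copies.tips_of_copy(c)))
        for v in sub:
            if topology.is_tip(v):
                continue
            spp = frozenset(copies.species(t) for t in topology.clades[v])
            key = spp if strict else (spp & shared)
            if scope is not None and not key <= frozenset(scope):
                continue
            if len(key) >= 2:
                keys.add(key)

    braces: list[Brace] = []
    for key in sorted(keys, key=lambda k: (len(k), tuple(sorted(k)))):
        members: list[int] = []
        for c in labels:
            if not key <= per_copy_species[c]:
                continue
            tips = [t for t in copies.tips_of_copy(c)
                    if copies.species(t) in key]
            node = mrca(topology, tips)
            node_spp = frozenset(copies.species(t) for t in topology.clades[node])
            node_key = node_spp if strict else (node_spp & shared)
            if node_key != key:
                continue  # this copy realises a coarser event
            members.append(node)
        if len(set(members)) >= 2:
            name = "brace_" + "+".join(sorted(key))
            braces.append(Brace(
                taxa_groups=(),
                nodes=tuple(sorted(set(members))),
                sigma=sigma,
                name=name,
            ))
    return braces


def _resolve_node(topology: RootedTopology, taxa: Iterable[str],
                  node: int | None, what: str) -> int:
    if node is not None:
        if not 0 <= node < topology.n_nodes:
            raise TreeError(f"{what}: node index {node} out of range")
        return int(node)
    taxa = list(taxa)
    if not taxa:
        raise TreeError(f"{what}: empty taxon selector")
    return mrca(topology, taxa)


def assemble_constraints(topology: RootedTopology,
                         calibrations: Sequence[Calibration] = (),
                         braces: Sequence[Brace] = (),
                         relatives: Sequence[RelativeConstraint] = (),
                         copy_map: CopyMap | None = None) -> ConstraintSet:
    """Resolve selectors onto nodes and validate the combined set.

    Duplicate entries are merged, the older-than relation is checked for
    cycles, and a warning (not an error) is issued when a brace ties
    nodes with different descendant species sets (requires ``copy_map``
    to translate tips to species).
    """
    resolved_cals: list[Calibration] = []
    for cal in calibrations:
        node = _resolve_node(topology, cal.taxa, cal.node,
                             f"calibration {cal.name!r}")
        resolved_cals.append(replace(cal, node=node))

    resolved_braces: list[Brace] = []
    for br in braces:
        if br.nodes:
            nodes = tuple(_resolve_node(topology, (), n, f"brace {br.name!r}")
                          for n in br.nodes)
        else:
            nodes = tuple(_resolve_node(topology, grp, None,
                                        f"brace {br.name!r}")
                          for grp in br.taxa_groups)
        if len(set(nodes)) < 2:
            raise TreeError(f"brace {br.name!r} resolves to a single node")
        if copy_map is not None:
            spp = [frozenset(copy_map.species(t) for t in topology.clades[n])
                   for n in nodes]
            if len(set(spp)) > 1:
                warnings.warn(
                    f"brace {br.name!r} ties nodes with different descendant "
                    f"species sets; proceeding (user override)",
                    stacklevel=2,
                )
        resolved_braces.append(replace(br, nodes=tuple(sorted(set(nodes)))))

    resolved_rels: list[RelativeConstraint] = []
    for rel in relatives:
        young = _resolve_node(topology, rel.younger_taxa, rel.younger,
                              f"relative {rel.name!r} (younger)")
        old = _resolve_node(topology, rel.older_taxa, rel.older,
                            f"relative {rel.name!r} (older)")
        if young == old:
            raise TreeError(f"relative constraint {rel.name!r} resolves to "
                            f"one node")
        resolved_rels.append(replace(rel, younger=young, older=old))

    # acyclicity of older-than (edge younger -> older) via DFS
    edges: dict[int, set[int]] = {}
    for rel in resolved_rels:
        edges.setdefault(rel.younger, set()).add(rel.older)
    state: dict[int, int] = {}  # 0 visiting, 1 done

    def dfs(v: int) -> None:
        state[v] = 0
        for w in edges.get(v, ()):
            if state.get(w) == 0:
                raise TreeError("older-than constraints form a cycle "
                                f"involving node {w}")
            if w not in state:
                dfs(w)
        state[v] = 1

    for v in list(edges):
        if v not in state:
            dfs(v)

    def dedup(items):
        seen, out = set(), []
        for it in items:
            key = repr(replace(it, name=""))
            if key not in seen:
                seen.add(key)
                out.append(it)
        return tuple(out)

    return ConstraintSet(
        topology=topology,
        calibrations=dedup(resolved_cals),
        braces=dedup(resolved_braces),
        relatives=dedup(resolved_rels),
    )


# ---------------------------------------------------------------------------
# config file I/O (YAML)
# ---------------------------------------------------------------------------


def load_constraint_config(path) -> tuple[list[Calibration], list[Brace],
                                          list[RelativeConstraint]]:
    """Read a calibration/brace/constraint config file.

    Structure::

        calibrations:
          - {name: root, taxa: [A, B], min: 3800, max: 4520,
             steepness_min: 95, steepness_max: 113}
        braces:
          - {name: leca, groups: [[A_nuc, B_nuc], [A_mit, B_mit]], sigma: 5}
        older_than:
          - {name: ..., younger: [P1, P2], older: [A_nuc, B_nuc], softness: 10}

    Steepness defaults to 2.5% of the corresponding boundary age.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    cals: list[Calibration] = []
    for i, entry in enumerate(doc.get("calibrations") or []):
        a = entry.get("min")
        b = entry.get("max")
        cals.append(Calibration(
            taxa=frozenset(entry.get("taxa") or []),
            node=entry.get("node"),
            min_age=a,
            max_age=b,
            steepness_min=entry.get("steepness_min",
                                    0.025 * a if a else 1.0),
            steepness_max=entry.get("steepness_max",
                                    0.025 * b if b else 1.0),
            name=entry.get("name", f"calibration_{i}"),
        ))
    braces: list[Brace] = []
    for i, entry in enumerate(doc.get("braces") or []):
        braces.append(Brace(
            taxa_groups=tuple(frozenset(g) for g in entry.get("groups") or []),
            nodes=tuple(entry.get("nodes") or ()),
            sigma=entry.get("sigma", 1.0),
            name=entry.get("name", f"brace_{i}"),
        ))
    rels: list[RelativeConstraint] = []
    for i, entry in enumerate(doc.get("older_than") or []):
        rels.append(RelativeConstraint(
            younger_taxa=frozenset(entry.get("younger") or []),
            older_taxa=frozenset(entry.get("older") or []),
            younger=entry.get("younger_node"),
            older=entry.get("older_node"),
            softness=entry.get("softness", 1.0),
            name=entry.get("name", f"older_than_{i}"),
        ))
    return cals, braces, rels


def save_constraint_config(path, calibrations: Sequence[Calibration] = (),
                           braces: Sequence[Brace] = (),
                           relatives: Sequence[RelativeConstraint] = ()) -> None:
    """Write constraints back out in the round-trippable config format."""
    doc: dict = {}
    if calibrations:
        doc["calibrations"] = [
            {k: v for k, v in {
                "name": c.name,
                "taxa": sorted(c.taxa) or None,
                "node": c.node,
                "min": c.min_age,
                "max": c.max_age,
                "steepness_min": c.steepness_min,
                "steepness_max": c.steepness_max,
            }.items() if v is not None}
            for c in calibrations]
    if braces:
        doc["braces"] = [
            {k: v for k, v in {
                "name": b.name,
                "groups": [sorted(g) for g in b.taxa_groups] or None,
                "nodes": list(b.nodes) or None,
                "sigma": b.sigma,
            }.items() if v is not None}
            for b in braces]
    if relatives:
        doc["older_than"] = [
            {k: v for k, v in {
                "name": r.name,
                "younger": sorted(r.younger_taxa) or None,
                "older": sorted(r.older_taxa) or None,
                "younger_node": r.younger,
                "older_node": r.older,
                "softness": r.softness,
            }.items() if v is not None}
            for r in relatives]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_copy_map(path) -> CopyMap:
    """Two-column TSV: tip label, ``species:copy``."""
    assignment: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tip, tag = line.split("\t")
            species, copy = tag.rsplit(":", 1)
            assignment[tip] = (species, copy)
    return CopyMap(assignment)


def write_copy_map(path, copies: CopyMap) -> None:
    with open(path, "w") as fh:
        for tip, (species, copy) in sorted(copies.assignment.items()):
            fh.write(f"{tip}\t{species}:{copy}\n")
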