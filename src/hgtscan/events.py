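"""Transfer direction and per-orthogroup event aggregation.

A transfer call made per query gene is refined in two steps.  First the
stopping clade is tested for *ingroup monophyly*: treating the clade's
ancestral node as the root, all focal-lineage and sister sequences
inside it must form a single clade nested within the outgroup sequences.
When they do, the focal lineage can confidently be called the *acceptor*
of the transfer; when they branch interspersed with the outgroups the
direction stays *unresolved* (the gene may equally have been donated).
Second, per-query calls are deduplicated into events: queries of one
orthogroup whose stopping clades contain the same focal+sister leaves
describe the same transfer and merge into one event, so event counts
stay below gene counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .tree_io import AnnotatedGeneTree, FOCAL_ROLES, Node
from .walk import Category, HGT_CATEGORIES, WalkResult


class Direction(str, enum.Enum):
    ACCEPTOR = "acceptor"
    UNRESOLVED = "unresolved"

    def __str__(self) -> str:
        return self.value


@dataclass
class HgtEvent:
    """One deduplicated transfer event inside an orthogroup."""

    og_id: str
    event_id: str
    category: Category
    genes: tuple[str, ...]
    focal_leaves: frozenset[str]  # event key: query+ingroup+sister in the clade
    clade_leaves: frozenset[str]  # full stopping-clade leaf set
    donor_lineages: frozenset[str]
    direction: Direction
    ingroup_monophyletic: bool


def _focal_leaf_names(tree: AnnotatedGeneTree, node: Node) -> set[str]:
    return {
        name
        for name in node.leaf_names()
        if tree.roles[name].role in FOCAL_ROLES
    }


def is_ingroup_monophyletic(tree: AnnotatedGeneTree, clade_node: Node) -> bool:
    """Test whether the focal (query+ingroup+sister) leaves of a stopping
    clade form one clade when the stopping clade's ancestor is taken as
    the root.

    Equivalent formulation used here: the MRCA of the focal leaves
    *within the clade subtree* contains no outgroup leaf.  Invariant to
    branch lengths and child order.
    """
    focal = _focal_leaf_names(tree, clade_node)
    all_in_clade = set(clade_node.leaf_names())
    outgroup = all_in_clade - focal
    if not outgroup:
        raise ValueError("monophyly test undefined: clade has no outgroup leaves")
    if not focal:
        raise ValueError("clade has no focal leaves")
    mrca = _mrca_within(clade_node, focal)
    return set(mrca.leaf_names()) <= focal


def _mrca_within(root: Node, target_names: set[str]) -> Node:
    """MRCA of the named leaves inside the subtree rooted at ``root``."""

    def descend(node: Node) -> Node:
        while True:
            if node.is_leaf:
                return node
            holding = [
                c
                for c in node.children
                if target_names & set(c.leaf_names())
            ]
            if len(holding) == 1:
                node = holding[0]
            else:
                return node

    return descend(root)


def infer_direction(result: WalkResult, tree: AnnotatedGeneTree) -> Direction:
    """Acceptor iff the stopping clade is ingroup-monophyletic.

    Only defined for transfer categories; a vertical (``ancestral``),
    ``ingroup_only`` or ``undetermined`` walk has no direction.
    """
    if result.category not in HGT_CATEGORIES:
        raise ValueError(
            f"direction undefined for category {result.category}"
        )
    assert result.stop is not None
    if is_ingroup_monophyletic(tree, result.stop.node):
        return Direction.ACCEPTOR
    return Direction.UNRESOLVED


def aggregate_events(
    results: Sequence[WalkResult],
    tree: AnnotatedGeneTree,
    event_key: str = "focal",
) -> list[HgtEvent]:
    """Deduplicate transfer-category walk results of one orthogroup into
    events.

    The default event key is the stopping clade's focal+sister leaf set,
    so two queries whose clades differ only in outgroup resolution still
    merge; ``event_key="full"`` keys on the complete clade leaf set.  An
    event's direction is ``acceptor`` only when every member walk is;
    donor lineages are unioned.
    """
    if event_key not in ("focal", "full"):
        raise ValueError(f"unknown event_key {event_key!r}")
    ogs = {r.og_id for r in results}
    if len(ogs) > 1:
        raise ValueError(f"results span multiple orthogroups: {sorted(ogs)}")
    groups: dict[frozenset, list[WalkResult]] = {}
    for r in results:
        if r.category not in HGT_CATEGORIES:
            continue
        assert r.stop is not None
        if event_key == "focal":
            key = frozenset(_focal_leaf_names(tree, r.stop.node))
        else:
            key = frozenset(r.stop.node.leaf_names())
        groups.setdefault(key, []).append(r)

    events = []
    ordered = sorted(groups.items(), key=lambda kv: min(r.query for r in kv[1]))
    for i, (key, members) in enumerate(ordered, start=1):
        members = sorted(members, key=lambda r: r.query)
        directions = [infer_direction(r, tree) for r in members]
        mono = [d is Direction.ACCEPTOR for d in directions]
        direction = Direction.ACCEPTOR if all(mono) else Direction.UNRESOLVED
        clade_leaves = frozenset(
            name for r in members for name in r.stop.node.leaf_names()
        )
        events.append(
            HgtEvent(
                og_id=members[0].og_id,
                event_id=f"{members[0].og_id}.e{i}",
                category=members[0].category,
                genes=tuple(r.query for r in members),
                focal_leaves=frozenset(key) if event_key == "focal" else frozenset(
                    _focal_leaf_names(tree, members[0].stop.node)
                ),
                clade_leaves=clade_leaves,
                donor_lineages=frozenset().union(
                    *(r.donor_lineages for r in members)
                ),
                direction=direction,
                ingroup_monophyletic=all(mono),
            )
        )
    return events
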