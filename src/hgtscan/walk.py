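"""Sister-clade scanning classifier for horizontal gene transfer.

From each focal ("query") leaf of a gene tree the walk climbs through
its nested ancestors, restricted to highly supported clades (edges whose
support fails the cutoff are first contracted into polytomies), and
accumulates the roles of the sequences encountered.  The walk stops the
first time one of the following fires, in this precedence:

* ``ancestral`` — at least ``min_sisters`` sister-lineage sequences:
  the gene is vertically inherited.
* ``ancestral_hgt`` — at least one sister plus at least
  ``min_outgroup_per_lineage`` outgroup sequences from a single major
  lineage: a transfer predating the focal lineage's split from its
  sisters.
* ``single_hgt`` / ``multi_hgt`` — no sisters, only focal-lineage and
  outgroup sequences, with the per-lineage outgroup minimum reached by
  one lineage; ``single`` when the clade's outgroup composition is one
  lineage, ``multi`` when it spans several.

If no criterion fires by the root, a tree of exclusively focal
(query/ingroup) leaves is ``ingroup_only``; any other composition is
``undetermined`` (mixed trees that exhaust the walk support no call).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .tree_io import AnnotatedGeneTree, GeneTree, Node


class Category(str, enum.Enum):
    ANCESTRAL = "ancestral"
    ANCESTRAL_HGT = "ancestral_hgt"
    SINGLE_HGT = "single_hgt"
    MULTI_HGT = "multi_hgt"
    INGROUP_ONLY = "ingroup_only"
    UNDETERMINED = "undetermined"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


HGT_CATEGORIES = frozenset(
    {Category.ANCESTRAL_HGT, Category.SINGLE_HGT, Category.MULTI_HGT}
)


@dataclass(frozen=True)
class WalkParams:
    """Thresholds of the walk; the defaults are the reference parameter
    set (support cutoff 0.85 applied strictly, 5 sisters for a vertical
    call, 3 outgroup sequences of one major lineage for a transfer call).
    """

    support_threshold: float = 0.85
    min_sisters: int = 5
    min_outgroup_per_lineage: int = 3
    rooting_strategy: str = "farthest_leaf"  # farthest_leaf | midpoint | as_is
    strict_greater: bool = True
    single_lineage_rule: str = "all"  # all | majority
    majority_fraction: float = 0.9

    def __post_init__(self):
        if not (0.0 <= self.support_threshold <= 1.0):
            raise ValueError("support_threshold must lie in [0, 1]")
        if self.min_sisters < 1 or self.min_outgroup_per_lineage < 1:
            raise ValueError("count thresholds must be >= 1")
        if self.rooting_strategy not in ("farthest_leaf", "midpoint", "as_is"):
            raise ValueError(f"unknown rooting strategy {self.rooting_strategy!r}")
        if self.single_lineage_rule not in ("all", "majority"):
            raise ValueError(f"unknown single_lineage_rule {self.single_lineage_rule!r}")

    def is_supported(self, support: Optional[float]) -> bool:
        """Leaf edges and edges without a label count as resolved."""
        if support is None:
            return True
        if self.strict_greater:
            return support > self.support_threshold
        return support >= self.support_threshold


@dataclass
class CladeCounts:
    """Cumulative role composition of one clade on the walk path."""

    node: Node
    n_leaves: int
    n_query: int
    n_ingroup: int
    n_sister: int
    n_outgroup_by_lineage: dict[str, int]

    @property
    def n_outgroup(self) -> int:
        return sum(self.n_outgroup_by_lineage.values())

    def leaf_names(self) -> list[str]:
        return self.node.leaf_names()


@dataclass
class WalkResult:
    query: str
    og_id: str
    category: Category
    stop: Optional[CladeCounts]
    trace: list[CladeCounts]
    donor_lineages: frozenset[str]
    stop_index: Optional[int]

    @property
    def is_hgt(self) -> bool:
        return self.category in HGT_CATEGORIES


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def _leaf_distances(tree: GeneTree, start: Node) -> dict[Node, float]:
    """Path lengths from ``start`` to every leaf (missing lengths count 0)."""
    dist: dict[Node, float] = {start: 0.0}
    stack = [start]
    while stack:
        node = stack.pop()
        neighbours = list(node.children)
        if node.parent is not None:
            neighbours.append(node.parent)
        for nb in neighbours:
            if nb in dist:
                continue
            # the edge between node and nb is stored on the child side
            edge_len = nb.length if nb.parent is node else node.length
            dist[nb] = dist[node] + (edge_len or 0.0)
            stack.append(nb)
    return {n: d for n, d in dist.items() if n.is_leaf}


def _reroot_at_edge(tree: GeneTree, child: Node, dist_below: Optional[float]) -> GeneTree:
    """Re-root on the edge above ``child``; the new root splits that edge
    ``dist_below`` from the child (``None`` keeps the full length on the
    child side).  Edge supports travel with their bipartitions: when an
    edge flips orientation its support moves to the node that becomes the
    child side.  Mutates and returns ``tree``."""
    old_parent = child.parent
    if old_parent is None:
        raise ValueError("cannot re-root on the root itself")
    edge_len = child.length
    path = []
    node = old_parent
    while node is not None:
        path.append(node)
        node = node.parent
    old_root = path[-1]
    # saved[i] = (length, support) of the old edge path[i] -> path[i+1]
    saved = [(p.length, p.support) for p in path]

    path[0].children.remove(child)
    for i in range(len(path) - 1):
        path[i + 1].children.remove(path[i])
        path[i].children.append(path[i + 1])
        path[i + 1].length, path[i + 1].support = saved[i]
    if dist_below is None or edge_len is None:
        child_len, parent_len = edge_len, 0.0
    else:
        child_len, parent_len = dist_below, max(edge_len - dist_below, 0.0)
    child.length = child_len
    # the split edge's bipartition is now the root bipartition; its support
    # stays on `child`, the other half carries none
    path[0].length, path[0].support = parent_len, None

    new_root = Node(children=[child, path[0]])
    tree.root = new_root
    tree.relink()

    # the old root may now be a unary pass-through (it had two children
    # and lost one to the reversal): splice it out, merging the two
    # halves of what is a single unrooted edge
    if len(old_root.children) == 1:
        lone = old_root.children[0]
        holder = old_root.parent
        idx = holder.children.index(old_root)
        if old_root.length is not None or lone.length is not None:
            lone.length = (old_root.length or 0.0) + (lone.length or 0.0)
        if lone.support is None:
            lone.support = old_root.support
        holder.children[idx] = lone
        tree.relink()
    return tree


def root_tree(tree: AnnotatedGeneTree, strategy: str = "farthest_leaf") -> AnnotatedGeneTree:
    """Return a rooted copy of the tree.

    ``farthest_leaf`` places the root on the terminal edge of the leaf
    farthest (by path length) from the lexicographically first query
    leaf, ties broken by leaf name; ``midpoint`` roots at the midpoint of
    the longest leaf-to-leaf path; ``as_is`` keeps the input rooting and
    refuses basal polytomies.
    """
    work = tree.copy()
    gt = work.tree
    if strategy == "as_is":
        if not gt.is_rooted:
            raise ValueError(
                "tree is unrooted (basal polytomy); choose a rooting strategy"
            )
        return work
    if len(gt.leaves()) < 2:
        raise ValueError("rooting needs at least 2 leaves")
    if strategy == "farthest_leaf":
        queries = work.query_leaves()
        start_name = queries[0] if queries else sorted(gt.leaf_names())[0]
        start = gt.find_leaf(start_name)
        dists = _leaf_distances(gt, start)
        # deterministic tie-break: largest distance, then smallest name
        best = max(d for leaf, d in dists.items() if leaf is not start)
        cands = sorted(
            (leaf.name for leaf, d in dists.items()
             if leaf is not start and abs(d - best) <= 1e-12),
        )
        target = gt.find_leaf(cands[0])
        if target.parent is gt.root and gt.is_rooted:
            return work  # already rooted on this terminal edge
        _reroot_at_edge(gt, target, dist_below=None)
        return AnnotatedGeneTree(gt, work.roles, work.og_id)
    if strategy == "midpoint":
        best = (-1.0, None, None)  # (distance, name_a, name_b)
        leaves = sorted(gt.leaves(), key=lambda n: n.name)
        for a in leaves:
            dists = _leaf_distances(gt, a)
            for b in leaves:
                if b.name <= a.name:
                    continue
                d = dists[b]
                if d > best[0] + 1e-12:
                    best = (d, a, b)
        diameter, a, b = best
        if a is None:
            raise ValueError("midpoint rooting needs >= 2 leaves")
        # walk from a towards b accumulating half the diameter
        path = _path_between(a, b)
        half = diameter / 2.0
        acc = 0.0
        for u, v in zip(path, path[1:]):
            step = (v.length if v.parent is u else u.length) or 0.0
            if acc + step >= half - 1e-12:
                # root on the edge between u and v
                child = v if v.parent is u else u
                within = half - acc
                dist_below = (step - within) if child is v else within
                _reroot_at_edge(gt, child, dist_below=dist_below)
                return AnnotatedGeneTree(gt, work.roles, work.og_id)
            acc += step
        raise AssertionError("midpoint not found on diameter path")
    raise ValueError(f"unknown rooting strategy {strategy!r}")


def _path_between(a: Node, b: Node) -> list[Node]:
    anc_a = []
    n = a
    while n is not None:
        anc_a.append(n)
        n = n.parent
    seen = set(id(x) for x in anc_a)
    tail = []
    n = b
    while id(n) not in seen:
        tail.append(n)
        n = n.parent
    mrca = n
    head = anc_a[: anc_a.index(mrca) + 1]
    return head + list(reversed(tail))


# ---------------------------------------------------------------------------
# collapsing
# ---------------------------------------------------------------------------

def collapse_low_support(
    tree: AnnotatedGeneTree, params: WalkParams
) -> AnnotatedGeneTree:
    """Contract every internal edge whose support fails the cutoff into a
    polytomy, so that only highly supported clades remain evaluation
    units.  Edges without a support label (leaf edges, the root) are kept.
    Idempotent."""
    work = tree.copy()
    gt = work.tree
    changed = True
    while changed:
        changed = False
        for node in list(gt.root.preorder()):
            kept: list[Node] = []
            for child in node.children:
                if (
                    not child.is_leaf
                    and child.support is not None
                    and not params.is_supported(child.support)
                ):
                    kept.extend(child.children)
                    changed = True
                else:
                    kept.append(child)
            node.children = kept
    gt.relink()
    return AnnotatedGeneTree(gt, work.roles, work.og_id)


# ---------------------------------------------------------------------------
# the walk
# ---------------------------------------------------------------------------

def _clade_counts(annotated: AnnotatedGeneTree, node: Node) -> CladeCounts:
    n_query = n_ingroup = n_sister = 0
    by_lineage: dict[str, int] = {}
    leaves = node.leaves()
    for leaf in leaves:
        tr = annotated.roles[leaf.name]
        if tr.role == "query":
            n_query += 1
        elif tr.role == "ingroup":
            n_ingroup += 1
        elif tr.role == "sister":
            n_sister += 1
        else:
            by_lineage[tr.lineage] = by_lineage.get(tr.lineage, 0) + 1
    return CladeCounts(
        node=node,
        n_leaves=len(leaves),
        n_query=n_query,
        n_ingroup=n_ingroup,
        n_sister=n_sister,
        n_outgroup_by_lineage=by_lineage,
    )


def nested_clades(tree: AnnotatedGeneTree, query: str) -> list[CladeCounts]:
    """Cumulative clade compositions along the query's ancestor path, from
    its parent up to and including the root."""
    leaf = tree.tree.find_leaf(query)  # raises KeyError if absent
    trace = []
    node = leaf.parent
    while node is not None:
        trace.append(_clade_counts(tree, node))
        node = node.parent
    return trace


def _firing_category(counts: CladeCounts, params: WalkParams) -> Optional[Category]:
    if counts.n_sister >= params.min_sisters:
        return Category.ANCESTRAL
    by_lin = counts.n_outgroup_by_lineage
    max_lineage = max(by_lin.values(), default=0)
    if counts.n_sister >= 1 and max_lineage >= params.min_outgroup_per_lineage:
        return Category.ANCESTRAL_HGT
    if counts.n_sister == 0:
        total = counts.n_outgroup
        qualifying = [
            lin
            for lin, n in by_lin.items()
            if n >= params.min_outgroup_per_lineage
        ]
        present = [lin for lin, n in by_lin.items() if n > 0]
        if len(qualifying) == 1:
            share = by_lin[qualifying[0]] / total
            if params.single_lineage_rule == "all":
                if len(present) == 1:
                    return Category.SINGLE_HGT
            elif share >= params.majority_fraction:
                return Category.SINGLE_HGT
        if (
            total >= params.min_outgroup_per_lineage
            and len(present) >= 2
            and qualifying
        ):
            return Category.MULTI_HGT
    return None


def classify_counts(
    trace: list[CladeCounts], params: WalkParams
) -> tuple[Category, Optional[int]]:
    """Scan a nested-clade trace in walk order and return the category and
    the index of the stopping clade (``None`` when no criterion fires)."""
    if not trace:
        raise ValueError("empty trace")
    prev: Optional[CladeCounts] = None
    for counts in trace:
        if prev is not None:
            monotone = (
                counts.n_query >= prev.n_query
                and counts.n_ingroup >= prev.n_ingroup
                and counts.n_sister >= prev.n_sister
                and all(
                    counts.n_outgroup_by_lineage.get(lin, 0) >= n
                    for lin, n in prev.n_outgroup_by_lineage.items()
                )
            )
            if not monotone:
                raise ValueError("trace counts are not cumulative")
        prev = counts
    for idx, counts in enumerate(trace):
        cat = _firing_category(counts, params)
        if cat is not None:
            return cat, idx
    whole = trace[-1]
    if whole.n_sister == 0 and whole.n_outgroup == 0:
        return Category.INGROUP_ONLY, None
    return Category.UNDETERMINED, None


def _donors(counts: CladeCounts, params: WalkParams) -> frozenset[str]:
    return frozenset(
        lin
        for lin, n in counts.n_outgroup_by_lineage.items()
        if n >= params.min_outgroup_per_lineage
    )


def _walk_prepared(
    prepared: AnnotatedGeneTree, query: str, params: WalkParams
) -> WalkResult:
    trace = nested_clades(prepared, query)
    category, stop_index = classify_counts(trace, params)
    stop = trace[stop_index] if stop_index is not None else None
    donors = (
        _donors(stop, params)
        if stop is not None and category in HGT_CATEGORIES
        else frozenset()
    )
    return WalkResult(
        query=query,
        og_id=prepared.og_id,
        category=category,
        stop=stop,
        trace=trace,
        donor_lineages=donors,
        stop_index=stop_index,
    )


def prepare_tree(tree: AnnotatedGeneTree, params: WalkParams) -> AnnotatedGeneTree:
    """Root then collapse: the form on which all walks of a tree run."""
    rooted = root_tree(tree, params.rooting_strategy)
    return collapse_low_support(rooted, params)


def walk_query(
    tree: AnnotatedGeneTree, query: str, params: WalkParams = WalkParams()
) -> WalkResult:
    """Classify a single query leaf (roots and collapses internally)."""
    prepared = prepare_tree(tree, params)
    return _walk_prepared(prepared, query, params)


def classify_tree(
    tree: AnnotatedGeneTree, params: WalkParams = WalkParams()
) -> list[WalkResult]:
    """One walk per query leaf, in lexicographic leaf-name order.  The
    tree is rooted and collapsed once; all queries share that form."""
    queries = tree.query_leaves()
    if not queries:
        raise ValueError(
            f"orthogroup {tree.og_id}: no query leaves; tree is inadmissible"
        )
    prepared = prepare_tree(tree, params)
    return [_walk_prepared(prepared, q, params) for q in queries]
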