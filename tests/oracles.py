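"""Independent brute-force oracle for the sister-clade walk.

Instead of rooting/collapsing/tracing, the oracle enumerates every
*supported* clade of a rooted tree that contains the query (a clade is
supported when its subtending edge has no support label or passes the
cutoff), sorts them by leaf count, and applies the stopping criteria in
that order with plain counting.  Collapsing an unsupported edge removes
exactly the clade below it and nothing else, so the supported-clade set
equals the clade set of the collapsed tree; agreement with the walk is
therefore exact, not approximate.
"""

from collections import Counter

import numpy as np

from hgtscan.tree_io import AnnotatedGeneTree, GeneTree, Node, TaxonRole
from hgtscan.walk import WalkParams


def oracle_walk(annotated: AnnotatedGeneTree, query: str, params: WalkParams):
    """Return (category_name, stop_leafset_or_None, donor_frozenset)."""
    tree = annotated.tree
    if not tree.is_rooted:
        raise ValueError("oracle expects a rooted tree")
    clades = []
    for node in tree.root.preorder():
        if node.is_leaf:
            continue
        supported = (
            node is tree.root
            or node.support is None
            or (
                node.support > params.support_threshold
                if params.strict_greater
                else node.support >= params.support_threshold
            )
        )
        if supported:
            leafset = frozenset(node.leaf_names())
            if query in leafset:
                clades.append(leafset)
    clades.sort(key=len)

    roles = annotated.roles
    all_leaves = frozenset(tree.leaf_names())
    for leafset in clades:
        counts = Counter()
        lineages = Counter()
        for name in leafset:
            tr = roles[name]
            counts[tr.role] += 1
            if tr.role == "outgroup":
                lineages[tr.lineage] += 1
        n_sister = counts["sister"]
        if n_sister >= params.min_sisters:
            return "ancestral", leafset, frozenset()
        top = max(lineages.values(), default=0)
        qualifying = frozenset(
            lin for lin, n in lineages.items()
            if n >= params.min_outgroup_per_lineage
        )
        if n_sister >= 1 and top >= params.min_outgroup_per_lineage:
            return "ancestral_hgt", leafset, qualifying
        if n_sister == 0:
            total = sum(lineages.values())
            if len(qualifying) == 1 and len(lineages) == 1:
                return "single_hgt", leafset, qualifying
            if (
                total >= params.min_outgroup_per_lineage
                and len(lineages) >= 2
                and qualifying
            ):
                return "multi_hgt", leafset, qualifying
    whole = Counter(roles[name].role for name in all_leaves)
    if whole["sister"] == 0 and whole["outgroup"] == 0:
        return "ingroup_only", None, frozenset()
    return "undetermined", None, frozenset()


ROLE_POOL = (
    TaxonRole("ingroup"),
    TaxonRole("sister"),
    TaxonRole("outgroup", "L1"),
    TaxonRole("outgroup", "L2"),
)

SUPPORT_POOL = (None, 0.3, 0.5, 0.85, 0.86, 0.95, 1.0)


def random_instance(rng: np.random.Generator, max_leaves: int = 8):
    """A random rooted annotated tree with exactly one query leaf, random
    roles from a two-lineage outgroup vocabulary, and random supports
    straddling the cutoff."""
    n = int(rng.integers(3, max_leaves + 1))
    leaves = [Node(name=f"t{i}") for i in range(n)]
    nodes = list(leaves)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(Node(children=[a, b]))
    root = nodes[0]
    for node in root.preorder():
        if node is root:
            continue
        node.length = float(rng.exponential(1.0))
        if not node.is_leaf:
            node.support = SUPPORT_POOL[int(rng.integers(len(SUPPORT_POOL)))]
    q = int(rng.integers(n))
    roles = {}
    for i, leaf in enumerate(leaves):
        if i == q:
            roles[leaf.name] = TaxonRole("query")
        else:
            roles[leaf.name] = ROLE_POOL[int(rng.integers(len(ROLE_POOL)))]
    annotated = AnnotatedGeneTree(GeneTree(root), roles, "OGrand")
    return annotated, leaves[q].name
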