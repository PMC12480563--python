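"""Gene-tree and taxonomy input/output.

Gene trees arrive as newick text in the dialect emitted by fast
approximate-ML tree builders: internal-node labels are branch support
values in [0, 1] (local supports or bootstrap proportions), not node
names.  Leaf roles — ``query`` (focal sequences under evaluation),
``ingroup`` (other focal-lineage sequences), ``sister`` (the focal
lineage's closest relatives) and ``outgroup`` (everything else, binned
into major lineages) — are supplied as a separate tab-separated map,
since tree files carry no taxonomic provenance.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import dendropy

logger = logging.getLogger(__name__)

ROLES = ("query", "ingroup", "sister", "outgroup")

#: Roles whose sequences belong to the focal lineage or its closest
#: relatives; the complement ("outgroup") supplies candidate HGT donors.
FOCAL_ROLES = frozenset({"query", "ingroup", "sister"})


class NewickParseError(ValueError):
    """Malformed newick input (unbalanced parentheses, duplicate leaves...)."""


class TreeValidationError(ValueError):
    """Structurally valid newick that violates a gene-tree invariant."""


class TaxonomyError(ValueError):
    """Malformed or inconsistent taxonomy map."""


class Node:
    """One vertex of a gene tree.

    ``length`` and ``support`` describe the edge between this node and
    its parent.  ``support`` is ``None`` when the edge carries no label
    (leaf edges, the root, and unlabeled internal edges); absence is
    distinct from 0 or 1 and such edges are never collapsed.
    """

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=None, support=None, children=None):
        self.name: Optional[str] = name
        self.length: Optional[float] = length
        self.support: Optional[float] = support
        self.children: list[Node] = children if children is not None else []
        self.parent: Optional[Node] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.name or '·'} n_children={len(self.children)}>"


@dataclass
class GeneTree:
    """A gene tree: topology, branch lengths, per-edge supports.

    A tree is *rooted* when the root has exactly two children; a basal
    polytomy (typically a trifurcation) marks an unrooted tree stored in
    the conventional rooted data layout.
    """

    root: Node

    def __post_init__(self):
        self.relink()
        self.validate()

    # -- structure maintenance -------------------------------------------
    def relink(self) -> None:
        """Rebuild parent pointers after any topology surgery."""
        self.root.parent = None
        for node in self.root.preorder():
            for child in node.children:
                child.parent = node

    def validate(self) -> None:
        names = self.leaf_names()
        if len(names) < 1:
            raise TreeValidationError("tree has no leaves")
        seen = set()
        for name in names:
            if name is None:
                raise TreeValidationError("unnamed leaf")
            if name in seen:
                raise NewickParseError(f"duplicate leaf name: {name!r}")
            seen.add(name)
        for node in self.root.preorder():
            if node.support is not None and not (0.0 <= node.support <= 1.0):
                raise TreeValidationError(
                    f"support {node.support} outside [0, 1]"
                )
            if node.length is not None and node.length < 0:
                raise TreeValidationError(f"negative branch length {node.length}")

    # -- queries ----------------------------------------------------------
    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def find_leaf(self, name: str) -> Node:
        for leaf in self.root.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(f"leaf {name!r} not in tree")

    def bipartitions(self) -> dict[frozenset, Optional[float]]:
        """Map each non-trivial bipartition (as the smaller/canonical leaf
        half) to its support.  Used to assert that re-rooting preserves
        the support of every bipartition it does not create or destroy."""
        all_leaves = frozenset(self.leaf_names())
        out: dict[frozenset, Optional[float]] = {}
        for node in self.root.preorder():
            if node is self.root or node.is_leaf:
                continue
            below = frozenset(node.leaf_names())
            other = all_leaves - below
            if not other:
                continue
            key = min(below, other, key=lambda s: (len(s), sorted(s)))
            if key in out and out[key] is None:
                out[key] = node.support
            elif key not in out:
                out[key] = node.support
        return out

    def copy(self) -> "GeneTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length, node.support)
            new.children = [clone(c) for c in node.children]
            return new

        return GeneTree(clone(self.root))


# ---------------------------------------------------------------------------
# newick reading / writing
# ---------------------------------------------------------------------------

def parse_gene_tree(newick_text: str) -> GeneTree:
    """Parse one newick statement into a :class:`GeneTree`.

    Internal-node labels, when numeric, are read as edge supports
    (tree-builder convention); labels on a 0–100 scale are rescaled to
    [0, 1] with a warning when any label exceeds 1.  Unquoted
    underscores are preserved verbatim.
    """
    text = newick_text.strip()
    if not text:
        raise NewickParseError("empty newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        raise NewickParseError(f"malformed newick: {exc}") from exc

    def convert(dnode) -> Node:
        name = None
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.is_leaf() and dnode.label is not None:
            name = dnode.label
        node = Node(name=name, length=dnode.edge.length)
        node.children = [convert(c) for c in dnode.child_nodes()]
        if node.children and dnode.label is not None:
            try:
                node.support = float(dnode.label)
            except ValueError:
                # non-numeric internal label: keep as a name, no support
                node.name = dnode.label
        return node

    root = convert(dtree.seed_node)
    root.support = None  # a root label does not describe a bipartition
    _rescale_supports(root)
    return GeneTree(root)


def _rescale_supports(root: Node) -> None:
    supports = [n.support for n in root.preorder() if n.support is not None]
    if not supports:
        return
    top = max(supports)
    if top > 100.0 or min(supports) < 0.0:
        raise TreeValidationError(
            f"internal label {top if top > 100 else min(supports)} cannot be "
            "a support on either a [0,1] or a percentage scale"
        )
    if top > 1.0:
        logger.warning(
            "internal labels exceed 1; interpreting as percentages and "
            "rescaling supports to [0, 1]"
        )
        for n in root.preorder():
            if n.support is not None:
                n.support = n.support / 100.0


def _fmt_length(x: float) -> str:
    return f"{x:.10g}"


def write_gene_tree(tree: GeneTree) -> str:
    """Serialize to newick; supports become internal labels (6 significant
    digits), quoting names only when the newick grammar requires it."""

    def needs_quotes(name: str) -> bool:
        special = set("()[]{}/\\,;:=*'\"`<>+- \t\n")
        return any(ch in special for ch in name)

    def fmt_name(name: str) -> str:
        if needs_quotes(name):
            return "'" + name.replace("'", "''") + "'"
        return name

    def emit(node: Node) -> str:
        if node.is_leaf:
            out = fmt_name(node.name)
        else:
            out = "(" + ",".join(emit(c) for c in node.children) + ")"
            if node.support is not None:
                out += f"{node.support:.6g}"
            elif node.name is not None:
                out += fmt_name(node.name)
        if node.length is not None:
            out += f":{_fmt_length(node.length)}"
        return out

    return emit(tree.root) + ";"


def read_trees(path: str) -> list[GeneTree]:
    """Read one or more newick trees from a file (one per line)."""
    trees = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line:
                trees.append(parse_gene_tree(line))
    return trees


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonRole:
    """Role of one sequence; ``lineage`` names the major lineage and is
    required exactly when the role is ``outgroup``."""

    role: str
    lineage: Optional[str] = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise TaxonomyError(f"unknown role {self.role!r}")
        if self.role == "outgroup":
            if not self.lineage:
                raise TaxonomyError("outgroup role requires a lineage")
        elif self.lineage:
            raise TaxonomyError(
                f"lineage given for non-outgroup role {self.role!r}"
            )


@dataclass
class TaxonomyMap:
    """Leaf-name → role assignment plus the major-lineage vocabulary."""

    roles: dict[str, TaxonRole]
    lineages: tuple[str, ...]

    def __post_init__(self):
        vocab = set(self.lineages)
        for seq, tr in self.roles.items():
            if tr.lineage is not None and tr.lineage not in vocab:
                raise TaxonomyError(
                    f"lineage {tr.lineage!r} of {seq!r} not in vocabulary"
                )


def load_taxonomy_map(
    table_text: str, extra_lineages: Iterable[str] = ()
) -> TaxonomyMap:
    """Parse a tab-separated taxonomy table.

    Expected header: ``seq_id<TAB>role<TAB>lineage`` (lineage column may
    be empty for non-outgroup roles).  The lineage vocabulary is the set
    of observed outgroup lineages plus ``extra_lineages``, in first-seen
    order.
    """
    handle = io.StringIO(table_text)
    header = handle.readline().rstrip("\n").split("\t")
    if [h.strip().lower() for h in header[:3]] != ["seq_id", "role", "lineage"]:
        raise TaxonomyError(
            "taxonomy map must start with header 'seq_id\\trole\\tlineage'"
        )
    roles: dict[str, TaxonRole] = {}
    vocab: list[str] = []
    for lineno, line in enumerate(handle, start=2):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise TaxonomyError(f"line {lineno}: expected >=2 tab-separated fields")
        seq_id = parts[0].strip()
        role = parts[1].strip()
        lineage = parts[2].strip() if len(parts) > 2 else ""
        if seq_id in roles:
            raise TaxonomyError(f"duplicate seq_id {seq_id!r} (line {lineno})")
        if role == "outgroup" and not lineage:
            raise TaxonomyError(
                f"line {lineno}: outgroup row for {seq_id!r} lacks a lineage"
            )
        roles[seq_id] = TaxonRole(role, lineage or None)
        if lineage and lineage not in vocab:
            vocab.append(lineage)
    for lin in extra_lineages:
        if lin not in vocab:
            vocab.append(lin)
    return TaxonomyMap(roles=roles, lineages=tuple(vocab))


def read_taxonomy_map(path: str, extra_lineages: Iterable[str] = ()) -> TaxonomyMap:
    with open(path, encoding="utf-8") as handle:
        return load_taxonomy_map(handle.read(), extra_lineages)


def write_taxonomy_map(taxmap: TaxonomyMap) -> str:
    lines = ["seq_id\trole\tlineage"]
    for seq, tr in taxmap.roles.items():
        lines.append(f"{seq}\t{tr.role}\t{tr.lineage or ''}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# annotated trees
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedGeneTree:
    """A gene tree whose every leaf carries a resolved role, tied to one
    orthogroup."""

    tree: GeneTree
    roles: dict[str, TaxonRole]
    og_id: str

    def __post_init__(self):
        missing = [n for n in self.tree.leaf_names() if n not in self.roles]
        if missing:
            raise TreeValidationError(
                f"leaves without roles: {', '.join(sorted(missing))}"
            )

    def role_of(self, leaf_name: str) -> TaxonRole:
        return self.roles[leaf_name]

    def query_leaves(self) -> list[str]:
        return sorted(
            n for n in self.tree.leaf_names() if self.roles[n].role == "query"
        )

    def has_query(self) -> bool:
        return any(self.roles[n].role == "query" for n in self.tree.leaf_names())

    def copy(self) -> "AnnotatedGeneTree":
        return AnnotatedGeneTree(self.tree.copy(), dict(self.roles), self.og_id)


def annotate_tree(
    tree: GeneTree,
    taxmap: TaxonomyMap,
    og_id: str,
    on_missing: str = "error",
) -> AnnotatedGeneTree:
    """Join a gene tree with the taxonomy map.

    ``on_missing`` controls leaves absent from the map: ``error`` raises,
    ``drop`` prunes them, ``outgroup_unknown`` assigns them
    role=outgroup / lineage="Unknown".
    """
    if on_missing not in ("error", "drop", "outgroup_unknown"):
        raise ValueError(f"unknown on_missing policy {on_missing!r}")
    names = tree.leaf_names()
    unmapped = [n for n in names if n not in taxmap.roles]
    if unmapped and on_missing == "error":
        raise TaxonomyError(
            "leaves missing from taxonomy map: " + ", ".join(sorted(unmapped))
        )
    work = tree.copy()
    if unmapped and on_missing == "drop":
        _prune_leaves(work, set(unmapped))
    roles = {}
    for name in work.leaf_names():
        if name in taxmap.roles:
            roles[name] = taxmap.roles[name]
        else:  # outgroup_unknown
            roles[name] = TaxonRole("outgroup", "Unknown")
    annotated = AnnotatedGeneTree(work, roles, og_id)
    if not annotated.has_query():
        logger.warning("orthogroup %s: no query leaves after annotation", og_id)
    return annotated


def _prune_leaves(tree: GeneTree, names: set[str]) -> None:
    """Remove the named leaves, suppressing resulting unary nodes (their
    edge lengths add; the surviving edge keeps the support of the deeper
    bipartition, which the pruning leaves intact)."""
    changed = True
    while changed:
        changed = False
        for node in list(tree.root.preorder()):
            node.children = [
                c for c in node.children if not (c.is_leaf and c.name in names)
            ]
        # suppress unary internal nodes
        for node in list(tree.root.preorder()):
            for i, child in enumerate(list(node.children)):
                if not child.is_leaf and len(child.children) == 1:
                    grand = child.children[0]
                    if child.length is not None or grand.length is not None:
                        grand.length = (child.length or 0.0) + (grand.length or 0.0)
                    node.children[i] = grand
                    changed = True
        if len(tree.root.children) == 1 and not tree.root.children[0].is_leaf:
            new_root = tree.root.children[0]
            new_root.length = None
            new_root.support = None
            tree.root = new_root
            changed = True
    tree.relink()
    tree.validate()


# ---------------------------------------------------------------------------
# auxiliary tables
# ---------------------------------------------------------------------------

def load_orthogroup_table(table_text: str) -> dict[str, list[str]]:
    """Parse ``og_id<TAB>seq_ids`` with comma-separated members (the common
    ortholog-clustering output dialect)."""
    handle = io.StringIO(table_text)
    header = handle.readline().rstrip("\n").split("\t")
    if [h.strip().lower() for h in header[:2]] != ["og_id", "seq_ids"]:
        raise TaxonomyError("orthogroup table needs header 'og_id\\tseq_ids'")
    out: dict[str, list[str]] = {}
    for lineno, line in enumerate(handle, start=2):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        og, seqs = line.split("\t")[:2]
        if og in out:
            raise TaxonomyError(f"duplicate og_id {og!r} (line {lineno})")
        out[og] = [s for s in (t.strip() for t in seqs.split(",")) if s]
    return out


def load_contig_lengths(table_text: str) -> dict[str, tuple[str, int]]:
    """Parse ``gene_id<TAB>contig_id<TAB>contig_length_bp`` into
    gene → (contig, length)."""
    handle = io.StringIO(table_text)
    header = handle.readline().rstrip("\n").split("\t")
    if [h.strip().lower() for h in header[:3]] != [
        "gene_id",
        "contig_id",
        "contig_length_bp",
    ]:
        raise TaxonomyError(
            "contig table needs header 'gene_id\\tcontig_id\\tcontig_length_bp'"
        )
    out: dict[str, tuple[str, int]] = {}
    for lineno, line in enumerate(handle, start=2):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        gene, contig, length = line.split("\t")[:3]
        n = int(length)
        if n <= 0:
            raise TaxonomyError(f"non-positive contig length at line {lineno}")
        out[gene] = (contig, n)
    return out


def contig_lengths_for(
    genes: Iterable[str], table: dict[str, tuple[str, int]]
) -> list[int]:
    """Join gene ids through the contig table to contig lengths, skipping
    genes without a contig record."""
    return [table[g][1] for g in genes if g in table]
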