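"""Synthetic gene trees with planted evolutionary scenarios.

Each simulated orthogroup tree consists of a *planted core* that
realizes one scenario and a random background subtree:

* ``vertical`` — the query sits in a clade of at least ``min_sisters``
  sister-lineage leaves (vertically inherited gene).
* ``ancient_hgt`` — a (query + a few sisters) clade nested inside a
  clade of donor-lineage leaves: a transfer predating the focal/sister
  split.
* ``recent_hgt_single`` — the query (plus optional other focal leaves)
  nested inside a pure donor-lineage clade; no sisters anywhere.
* ``recent_hgt_multi`` — as above but the enclosing clade interleaves
  leaves of two or more donor lineages (built as a caterpillar of mixed
  tuples so no pure single-lineage sub-clade fires first).
* ``ingroup_only`` — every leaf is focal (query/ingroup).

Backbone topologies come from random joins (Yule-type), branch lengths
are Exp(1), supports either a point mass at 1 or i.i.d. Beta(α, β) per
internal edge.  The background contains one *anchor* leaf whose terminal
branch exceeds the sum of all other branches, pinning farthest-leaf and
midpoint rooting outside the planted core so the core stays a clade
under the default rooting.  Label noise re-draws a leaf's role/lineage
uniformly from the vocabulary excluding its truth, stressing both the
count thresholds and the monophyly test.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tree_io import (
    AnnotatedGeneTree,
    GeneTree,
    Node,
    TaxonRole,
    write_gene_tree,
)
from .walk import Category, WalkParams, WalkResult, classify_tree
from .events import Direction, infer_direction

SCENARIOS = (
    "vertical",
    "ancient_hgt",
    "recent_hgt_single",
    "recent_hgt_multi",
    "ingroup_only",
)

#: planted scenario -> category the classifier should recover
SCENARIO_CATEGORY = {
    "vertical": Category.ANCESTRAL,
    "ancient_hgt": Category.ANCESTRAL_HGT,
    "recent_hgt_single": Category.SINGLE_HGT,
    "recent_hgt_multi": Category.MULTI_HGT,
    "ingroup_only": Category.INGROUP_ONLY,
}

DEFAULT_LINEAGES = (
    "Stramenopila",
    "Alveolata",
    "Opisthokonta",
    "Bacteria",
    "Viruses",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one planted tree.

    ``support_model`` is ``("fixed", v)`` or ``("beta", alpha, beta)``;
    the Beta(8, 2) preset puts roughly 14% of edges below the 0.85
    support cutoff, exercising polytomy collapse.
    """

    scenario: str
    n_leaves: int = 40
    donor_lineages: tuple[str, ...] = ("Stramenopila",)
    n_query: int = 1
    n_sisters: int = -1  # -1: scenario default
    support_model: tuple = ("fixed", 1.0)
    noise: float = 0.0
    seed: int = 0
    lineages: tuple[str, ...] = DEFAULT_LINEAGES
    min_sisters: int = 5
    min_outgroup: int = 3

    def resolved_sisters(self) -> int:
        if self.n_sisters >= 0:
            return self.n_sisters
        if self.scenario == "vertical":
            return self.min_sisters + 1
        if self.scenario == "ancient_hgt":
            return 2
        return 0

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_leaves < 4:
            raise ValueError("n_leaves must be >= 4")
        if self.n_query < 1:
            raise ValueError("n_query must be >= 1")
        if not (0.0 <= self.noise < 1.0):
            raise ValueError("noise must lie in [0, 1)")
        ns = self.resolved_sisters()
        if self.scenario == "vertical" and ns < self.min_sisters:
            raise ValueError("vertical scenario needs n_sisters >= min_sisters")
        if self.scenario == "ancient_hgt" and not (
            1 <= ns < self.min_sisters
        ):
            raise ValueError(
                "ancient_hgt needs 1 <= n_sisters < min_sisters"
            )
        if self.scenario in ("recent_hgt_single", "recent_hgt_multi") and ns != 0:
            raise ValueError(f"{self.scenario} requires zero sisters")
        if self.scenario == "recent_hgt_single" and len(self.donor_lineages) != 1:
            raise ValueError("recent_hgt_single takes exactly one donor lineage")
        if self.scenario == "recent_hgt_multi" and len(self.donor_lineages) < 2:
            raise ValueError("recent_hgt_multi needs >= 2 donor lineages")
        if self.scenario == "ancient_hgt" and len(self.donor_lineages) != 1:
            raise ValueError("ancient_hgt takes exactly one donor lineage")
        for lin in self.donor_lineages:
            if lin not in self.lineages:
                raise ValueError(f"donor lineage {lin!r} not in vocabulary")


@dataclass(frozen=True)
class SyntheticTruth:
    og_id: str
    category: Category
    donor_lineages: frozenset[str]
    direction: Optional[Direction]
    query_ids: tuple[str, ...]


@dataclass
class RecoverySummary:
    confusion: pd.DataFrame  # rows: truth, columns: predicted
    sensitivity: dict[str, float]
    precision: dict[str, float]
    category_accuracy: float
    direction_accuracy: Optional[float]
    n_trees: int
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def _random_join(nodes: list[Node], rng: np.random.Generator) -> Node:
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(Node(children=[a, b]))
    return nodes[0]


def _leaf(name: str) -> Node:
    return Node(name=name)


def simulate_tree(
    spec: ScenarioSpec, og_id: str = "OGsim"
) -> tuple[AnnotatedGeneTree, SyntheticTruth]:
    """Generate one annotated gene tree with its planted-truth record.

    Deterministic in ``spec`` (including its seed): the same spec yields
    a byte-identical newick and truth record.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p = f"{og_id}_"
    roles: dict[str, TaxonRole] = {}

    def add(name: str, role: str, lineage: Optional[str] = None) -> Node:
        roles[p + name] = TaxonRole(role, lineage)
        return _leaf(p + name)

    queries = [add(f"q{i:03d}", "query") for i in range(1, spec.n_query + 1)]
    n_sis = spec.resolved_sisters()
    core, planted_donors = _build_core(spec, queries, n_sis, add, rng)

    used = spec.n_query + n_sis
    if spec.scenario == "ancient_hgt":
        used += spec.min_outgroup
    elif spec.scenario == "recent_hgt_single":
        used += spec.min_outgroup + 1  # donors + one ingroup companion
    elif spec.scenario == "recent_hgt_multi":
        used += spec.min_outgroup * len(spec.donor_lineages)

    n_background = max(spec.n_leaves - used, 2)
    background_leaves = _background_leaves(spec, n_background, add, rng)
    if core is None:  # ingroup_only: queries mix freely with the background
        root = _random_join(queries + background_leaves, rng)
    else:
        root = Node(children=[core, _random_join(background_leaves, rng)])

    # branch lengths Exp(1), supports on internal edges
    anchor_node: Optional[Node] = None
    total_len = 0.0
    for node in root.preorder():
        if node is root:
            continue
        node.length = float(rng.exponential(1.0))
        total_len += node.length
        if not node.is_leaf:
            node.support = _draw_support(spec.support_model, rng)
        elif node.name == p + "anchor":
            anchor_node = node
    if anchor_node is not None:
        total_len -= anchor_node.length
        anchor_node.length = total_len + 1.0

    tree = GeneTree(root)
    truth = SyntheticTruth(
        og_id=og_id,
        category=SCENARIO_CATEGORY[spec.scenario],
        donor_lineages=frozenset(planted_donors),
        direction=(
            Direction.ACCEPTOR
            if SCENARIO_CATEGORY[spec.scenario]
            in (Category.ANCESTRAL_HGT, Category.SINGLE_HGT, Category.MULTI_HGT)
            else None
        ),
        query_ids=tuple(sorted(p + f"q{i:03d}" for i in range(1, spec.n_query + 1))),
    )

    # label noise: redraw role/lineage uniformly, excluding the truth
    if spec.noise > 0:
        options = [("query", None), ("ingroup", None), ("sister", None)] + [
            ("outgroup", lin) for lin in spec.lineages
        ]
        for name in sorted(roles):
            if rng.random() < spec.noise:
                current = (roles[name].role, roles[name].lineage)
                alts = [o for o in options if o != current]
                pick = alts[int(rng.integers(len(alts)))]
                roles[name] = TaxonRole(*pick)

    return AnnotatedGeneTree(tree, roles, og_id), truth


def _draw_support(model: tuple, rng: np.random.Generator) -> float:
    kind = model[0]
    if kind == "fixed":
        return float(model[1])
    if kind == "beta":
        return float(rng.beta(model[1], model[2]))
    raise ValueError(f"unknown support model {model!r}")


def _build_core(spec, queries, n_sis, add, rng):
    """Return (core subtree or None, planted donor lineages)."""
    if spec.scenario == "ingroup_only":
        return None, ()
    if spec.scenario == "vertical":
        sisters = [add(f"sis{i:03d}", "sister") for i in range(1, n_sis + 1)]
        return _random_join(queries + sisters, rng), ()
    if spec.scenario == "ancient_hgt":
        donor = spec.donor_lineages[0]
        sisters = [add(f"sis{i:03d}", "sister") for i in range(1, n_sis + 1)]
        inner = _random_join(queries + sisters, rng)
        donors = [
            add(f"don{i:03d}", "outgroup", donor)
            for i in range(1, spec.min_outgroup + 1)
        ]
        return Node(children=[inner, _random_join(donors, rng)]), (donor,)
    if spec.scenario == "recent_hgt_single":
        donor = spec.donor_lineages[0]
        companions = [add("ing001", "ingroup")]
        inner = _random_join(queries + companions, rng)
        donors = [
            add(f"don{i:03d}", "outgroup", donor)
            for i in range(1, spec.min_outgroup + 1)
        ]
        return Node(children=[inner, _random_join(donors, rng)]), (donor,)
    if spec.scenario == "recent_hgt_multi":
        # caterpillar of mixed-lineage tuples: counts grow in lockstep so
        # every donor lineage reaches the per-lineage minimum at the same
        # clade and no pure sub-clade triggers a single-lineage call first
        core = _random_join(list(queries), rng)
        k = 0
        for _ in range(spec.min_outgroup):
            tup = []
            for lin in spec.donor_lineages:
                k += 1
                tup.append(add(f"don{k:03d}", "outgroup", lin))
            core = Node(children=[core, _random_join(tup, rng)])
        return core, tuple(spec.donor_lineages)
    raise AssertionError(spec.scenario)


def _background_leaves(spec, n_background, add, rng):
    """Background composition: anchor + a role mix that cannot disturb the
    planted call (no sisters in sister-free scenarios)."""
    leaves = []
    if spec.scenario == "ingroup_only":
        leaves.append(add("anchor", "ingroup"))
        for i in range(1, n_background):
            leaves.append(add(f"ing{900 + i:03d}", "ingroup"))
        return leaves
    other = [lin for lin in spec.lineages if lin not in spec.donor_lineages]
    pool = other or list(spec.lineages)
    leaves.append(add("anchor", "outgroup", pool[0]))
    allow_sisters = spec.scenario in ("vertical", "ancient_hgt")
    for i in range(1, n_background):
        r = rng.random()
        if allow_sisters and r < 0.2:
            leaves.append(add(f"sis{900 + i:03d}", "sister"))
        elif r < 0.35:
            leaves.append(add(f"ing{900 + i:03d}", "ingroup"))
        else:
            lin = pool[int(rng.integers(len(pool)))]
            leaves.append(add(f"out{900 + i:03d}", "outgroup", lin))
    return leaves


# ---------------------------------------------------------------------------
# corpora
# ---------------------------------------------------------------------------

def simulate_corpus(
    mixture: Sequence[tuple[ScenarioSpec, int]], seed: int
) -> tuple[list[AnnotatedGeneTree], list[SyntheticTruth]]:
    """Generate a corpus from (spec, count) pairs; per-tree seeds derive
    from ``seed``, orthogroup ids run OG0000001, OG0000002, ..."""
    if not mixture:
        raise ValueError("empty scenario mixture")
    for _, count in mixture:
        if count < 1:
            raise ValueError("scenario counts must be >= 1")
    master = np.random.default_rng(seed)
    trees: list[AnnotatedGeneTree] = []
    truths: list[SyntheticTruth] = []
    og_no = 0
    for spec, count in mixture:
        for _ in range(count):
            og_no += 1
            og_id = f"OG{og_no:07d}"
            tree_seed = int(master.integers(0, 2**31 - 1))
            tree, truth = simulate_tree(replace(spec, seed=tree_seed), og_id)
            trees.append(tree)
            truths.append(truth)
    return trees, truths


def default_mixture(
    per_scenario: int = 40,
    noise: float = 0.0,
    support_model: tuple = ("fixed", 1.0),
    n_leaves: int = 40,
) -> list[tuple[ScenarioSpec, int]]:
    """The study mixture: all five scenarios in equal proportion."""
    donors = {
        "ancient_hgt": ("Stramenopila",),
        "recent_hgt_single": ("Alveolata",),
        "recent_hgt_multi": ("Stramenopila", "Opisthokonta"),
    }
    out = []
    for scen in SCENARIOS:
        out.append(
            (
                ScenarioSpec(
                    scenario=scen,
                    n_leaves=n_leaves,
                    donor_lineages=donors.get(scen, ("Stramenopila",)),
                    noise=noise,
                    support_model=support_model,
                ),
                per_scenario,
            )
        )
    return out


def write_corpus(
    trees: Sequence[AnnotatedGeneTree],
    truths: Sequence[SyntheticTruth],
    out_dir: str,
) -> None:
    """One newick file per tree, a combined taxonomy map, and the truth
    table."""
    os.makedirs(out_dir, exist_ok=True)
    tree_dir = os.path.join(out_dir, "trees")
    os.makedirs(tree_dir, exist_ok=True)
    roles: dict[str, TaxonRole] = {}
    for tree in trees:
        with open(
            os.path.join(tree_dir, f"{tree.og_id}.nwk"), "w", encoding="utf-8"
        ) as handle:
            handle.write(write_gene_tree(tree.tree) + "\n")
        roles.update(tree.roles)
    vocab: list[str] = []
    for tr in roles.values():
        if tr.lineage and tr.lineage not in vocab:
            vocab.append(tr.lineage)
    lines = ["seq_id\trole\tlineage"]
    for seq in sorted(roles):
        tr = roles[seq]
        lines.append(f"{seq}\t{tr.role}\t{tr.lineage or ''}")
    with open(os.path.join(out_dir, "taxonomy.tsv"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(os.path.join(out_dir, "truth.tsv"), "w", encoding="utf-8") as fh:
        fh.write("og_id\tscenario_category\tdonor_lineages\tdirection\tquery_ids\n")
        for t in truths:
            fh.write(
                "\t".join(
                    [
                        t.og_id,
                        t.category.value,
                        ",".join(sorted(t.donor_lineages)),
                        t.direction.value if t.direction else "",
                        ",".join(t.query_ids),
                    ]
                )
                + "\n"
            )


def read_truth_table(path: str) -> list[SyntheticTruth]:
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            og, cat, donors, direction, queries = line.split("\t")
            out.append(
                SyntheticTruth(
                    og_id=og,
                    category=Category(cat),
                    donor_lineages=frozenset(
                        d for d in donors.split(",") if d
                    ),
                    direction=Direction(direction) if direction else None,
                    query_ids=tuple(q for q in queries.split(",") if q),
                )
            )
    return out


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def predict_corpus(
    trees: Sequence[AnnotatedGeneTree], params: WalkParams = WalkParams()
) -> dict[str, list[WalkResult]]:
    """Classify every tree; trees left without query leaves (possible
    under heavy label noise) yield an empty result list."""
    out: dict[str, list[WalkResult]] = {}
    for tree in trees:
        if tree.has_query():
            out[tree.og_id] = classify_tree(tree, params)
        else:
            out[tree.og_id] = []
    return out


def evaluate_recovery(
    predictions: dict[str, list[WalkResult]],
    truths: Sequence[SyntheticTruth],
    trees: Optional[Sequence[AnnotatedGeneTree]] = None,
    params: WalkParams = WalkParams(),
    seed: Optional[int] = None,
) -> RecoverySummary:
    """Score predicted categories (and, when trees are supplied,
    directions) against the planted truth.

    The per-tree predicted category is the category of the tree's first
    query walk; a tree without any query walk counts as ``none`` (always
    wrong).  Direction accuracy is computed over truth-HGT trees: correct
    iff the predicted category is a transfer category and the inferred
    direction matches the planted one.
    """
    truth_by_og = {t.og_id: t for t in truths}
    missing = set(truth_by_og) ^ set(predictions)
    if missing:
        raise ValueError(f"og_ids do not align: {sorted(missing)[:5]} ...")
    tree_index = {t.og_id: t for t in trees} if trees is not None else {}
    prepared_cache: dict[str, AnnotatedGeneTree] = {}

    cats = [c.value for c in Category] + ["none"]
    confusion = pd.DataFrame(
        0, index=[c.value for c in Category], columns=cats, dtype=int
    )
    n_correct = 0
    n_dir_total = 0
    n_dir_correct = 0
    for og, truth in truth_by_og.items():
        results = predictions[og]
        if results:
            first = min(results, key=lambda r: r.query)
            pred = first.category.value
        else:
            first = None
            pred = "none"
        confusion.loc[truth.category.value, pred] += 1
        if pred == truth.category.value:
            n_correct += 1
        if truth.direction is not None:
            n_dir_total += 1
            if (
                first is not None
                and first.is_hgt
                and og in tree_index
            ):
                # direction needs the prepared (rooted+collapsed) form the
                # walk ran on; first.stop.node belongs to that form already
                direction = infer_direction(first, tree_index[og])
                if direction == truth.direction:
                    n_dir_correct += 1
    n_trees = len(truth_by_og)
    sensitivity = {}
    precision = {}
    for cat in confusion.index:
        row = confusion.loc[cat].sum()
        col = confusion[cat].sum() if cat in confusion.columns else 0
        diag = confusion.loc[cat, cat] if cat in confusion.columns else 0
        sensitivity[cat] = diag / row if row else float("nan")
        precision[cat] = diag / col if col else float("nan")
    return RecoverySummary(
        confusion=confusion,
        sensitivity=sensitivity,
        precision=precision,
        category_accuracy=n_correct / n_trees,
        direction_accuracy=(
            n_dir_correct / n_dir_total if (trees is not None and n_dir_total) else None
        ),
        n_trees=n_trees,
        seed=seed,
    )
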