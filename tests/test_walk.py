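"""Rooting, collapsing, the nested-clade trace and the stopping criteria."""

import numpy as np
import pytest

from hgtscan.walk import (
    Category,
    CladeCounts,
    WalkParams,
    classify_counts,
    classify_tree,
    collapse_low_support,
    nested_clades,
    root_tree,
    walk_query,
)
from conftest import build_annotated
from oracles import oracle_walk, random_instance


def counts(n_sister=0, outgroup=None, n_query=1, n_ingroup=0):
    og = outgroup or {}
    return CladeCounts(
        node=None,
        n_leaves=n_query + n_ingroup + n_sister + sum(og.values()),
        n_query=n_query,
        n_ingroup=n_ingroup,
        n_sister=n_sister,
        n_outgroup_by_lineage=og,
    )


class TestRooting:
    def test_farthest_leaf_picks_longest_path(self):
        # path lengths from q: a=2, b=3, c=4 -> root lands on c's edge
        ann = build_annotated(
            "(((q:1,a:1):1,b:1):1,c:1);",
            {"q": "query", "a": "sister", "b": "sister", "c": "sister"},
        )
        rooted = root_tree(ann, "farthest_leaf")
        root_children_leafsets = [
            frozenset(c.leaf_names()) for c in rooted.tree.root.children
        ]
        assert frozenset({"c"}) in root_children_leafsets

    def test_midpoint_splits_two_leaf_tree_evenly(self):
        ann = build_annotated("(A:1,B:1);", {"A": "query", "B": "sister"})
        rooted = root_tree(ann, "midpoint")
        lengths = sorted(c.length for c in rooted.tree.root.children)
        assert lengths == [pytest.approx(1.0), pytest.approx(1.0)]

    def test_rerooting_preserves_bipartition_supports(self):
        ann = build_annotated(
            "(((q:1,a:2)0.9:1,(b:1,c:1)0.7:3)0.95:1,(d:1,e:4)0.8:1);",
            {
                "q": "query",
                "a": "sister",
                "b": "sister",
                "c": "sister",
                "d": "outgroup:L1",
                "e": "outgroup:L1",
            },
        )
        before = ann.tree.bipartitions()
        rooted = root_tree(ann, "farthest_leaf")
        after = rooted.tree.bipartitions()
        for key, sup in before.items():
            if key in after and sup is not None:
                assert after[key] == pytest.approx(sup)

    def test_as_is_refuses_unrooted(self):
        ann = build_annotated(
            "(a:1,b:1,c:1);", {"a": "query", "b": "sister", "c": "sister"}
        )
        with pytest.raises(ValueError, match="unrooted|strategy"):
            root_tree(ann, "as_is")


class TestCollapse:
    ROLES = {"A": "query", "B": "sister", "C": "sister"}

    def test_low_support_contracts_to_star(self):
        ann = build_annotated("((A:1,B:1)0.5:1,C:1);", self.ROLES)
        collapsed = collapse_low_support(ann, WalkParams())
        assert len(collapsed.tree.root.children) == 3

    def test_threshold_is_strict(self):
        ann = build_annotated("((A:1,B:1)0.85:1,C:1);", self.ROLES)
        collapsed = collapse_low_support(ann, WalkParams())
        assert len(collapsed.tree.root.children) == 3  # 0.85 is NOT > 0.85
        ann2 = build_annotated("((A:1,B:1)0.95:1,C:1);", self.ROLES)
        collapsed2 = collapse_low_support(ann2, WalkParams())
        assert len(collapsed2.tree.root.children) == 2

    def test_absent_support_is_kept(self):
        ann = build_annotated("((A:1,B:1):1,C:1);", self.ROLES)
        collapsed = collapse_low_support(ann, WalkParams())
        assert len(collapsed.tree.root.children) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        ann, _ = random_instance(rng)
        once = collapse_low_support(ann, WalkParams())
        twice = collapse_low_support(once, WalkParams())
        from hgtscan.tree_io import write_gene_tree

        assert write_gene_tree(once.tree) == write_gene_tree(twice.tree)


class TestNestedClades:
    def test_trace_counts_by_hand(self):
        ann = build_annotated(
            "(((q,s1)1.0,(o1,o2,o3)1.0)1.0,(s2,s3)1.0);",
            {
                "q": "query",
                "s1": "sister",
                "s2": "sister",
                "s3": "sister",
                "o1": "outgroup:L1",
                "o2": "outgroup:L1",
                "o3": "outgroup:L1",
            },
        )
        trace = nested_clades(ann, "q")
        got = [(c.n_sister, dict(c.n_outgroup_by_lineage)) for c in trace]
        assert got == [(1, {}), (1, {"L1": 3}), (3, {"L1": 3})]

    def test_star_tree_single_entry(self):
        ann = build_annotated(
            "(q:1,a:1,b:1);", {"q": "query", "a": "sister", "b": "ingroup"}
        )
        trace = nested_clades(ann, "q")
        assert len(trace) == 1
        assert trace[0].n_leaves == 3

    def test_missing_query_raises(self):
        ann = build_annotated("(q:1,a:1,b:1);",
                              {"q": "query", "a": "sister", "b": "sister"})
        with pytest.raises(KeyError):
            nested_clades(ann, "nope")

    @pytest.mark.parametrize("seed", range(10))
    def test_counts_non_decreasing_along_trace(self, seed):
        rng = np.random.default_rng(100 + seed)
        ann, query = random_instance(rng)
        trace = nested_clades(ann, query)
        for a, b in zip(trace, trace[1:]):
            assert b.n_query >= a.n_query
            assert b.n_sister >= a.n_sister
            assert b.n_ingroup >= a.n_ingroup
            for lin, n in a.n_outgroup_by_lineage.items():
                assert b.n_outgroup_by_lineage.get(lin, 0) >= n


class TestClassifyCounts:
    def test_ancestral_at_five_sisters(self):
        assert classify_counts([counts(n_sister=5)], WalkParams()) == (
            Category.ANCESTRAL,
            0,
        )

    def test_ancestral_hgt_needs_sister_and_lineage_minimum(self):
        trace = [counts(n_sister=1), counts(n_sister=1, outgroup={"Stramenopila": 3})]
        assert classify_counts(trace, WalkParams()) == (Category.ANCESTRAL_HGT, 1)

    def test_multi_hgt_on_two_lineages(self):
        trace = [counts(outgroup={"Stramenopila": 3, "Alveolata": 3})]
        assert classify_counts(trace, WalkParams()) == (Category.MULTI_HGT, 0)

    def test_single_hgt_requires_pure_composition(self):
        trace = [counts(outgroup={"Stramenopila": 4})]
        assert classify_counts(trace, WalkParams()) == (Category.SINGLE_HGT, 0)
        # one stray second-lineage leaf breaks purity under the default rule
        trace = [counts(outgroup={"Stramenopila": 4, "Alveolata": 1})]
        assert classify_counts(trace, WalkParams())[0] is Category.MULTI_HGT
        # ... but passes under the 90%-majority rule
        params = WalkParams(single_lineage_rule="majority")
        trace = [counts(outgroup={"Stramenopila": 19, "Alveolata": 1})]
        assert classify_counts(trace, params)[0] is Category.SINGLE_HGT

    def test_ancestral_takes_precedence_over_hgt(self):
        trace = [counts(n_sister=5, outgroup={"Opisthokonta": 3})]
        assert classify_counts(trace, WalkParams()) == (Category.ANCESTRAL, 0)

    def test_ingroup_only_vs_undetermined(self):
        trace = [counts(n_query=2, n_ingroup=3)]
        assert classify_counts(trace, WalkParams()) == (Category.INGROUP_ONLY, None)
        trace = [counts(n_sister=2, outgroup={"Bacteria": 1})]
        assert classify_counts(trace, WalkParams()) == (Category.UNDETERMINED, None)

    def test_non_cumulative_trace_rejected(self):
        trace = [counts(n_sister=3), counts(n_sister=1)]
        with pytest.raises(ValueError, match="cumulative"):
            classify_counts(trace, WalkParams())


class TestWalkQuery:
    def test_ancient_transfer_called_at_second_clade(self, ancient_hgt_tree):
        result = walk_query(ancient_hgt_tree, "q")
        assert result.category is Category.ANCESTRAL_HGT
        assert result.donor_lineages == {"Stramenopila"}
        assert result.stop.n_leaves == 5

    def test_relabeled_sister_turns_call_single(self):
        ann = build_annotated(
            "(((q:1,s1:1)1.0:1,(o1:1,o2:1,o3:1)1.0:1)1.0:1,(x1:1,x2:1)1.0:1);",
            {
                "q": "query",
                "s1": "outgroup:Stramenopila",
                "o1": "outgroup:Stramenopila",
                "o2": "outgroup:Stramenopila",
                "o3": "outgroup:Stramenopila",
                "x1": "outgroup:Alveolata",
                "x2": "outgroup:Alveolata",
            },
        )
        result = walk_query(ann, "q")
        assert result.category is Category.SINGLE_HGT
        assert result.donor_lineages == {"Stramenopila"}

    def test_collapsed_tree_decides_at_root_star(self):
        ann = build_annotated(
            "(((q:1,s1:1)0.5:1,(o1:1,o2:1,o3:1)0.5:1)0.5:1,(x1:1,x2:1)0.5:1);",
            {
                "q": "query",
                "s1": "sister",
                "o1": "outgroup:Stramenopila",
                "o2": "outgroup:Stramenopila",
                "o3": "outgroup:Stramenopila",
                "x1": "outgroup:Alveolata",
                "x2": "outgroup:Alveolata",
            },
        )
        result = walk_query(ann, "q", WalkParams(rooting_strategy="as_is"))
        # everything collapses; the root clade has 1 sister + 3 Stramenopila
        assert result.category is Category.ANCESTRAL_HGT
        assert len(result.trace) == 1

    def test_child_order_rotation_invariance(self):
        roles = {
            "q": "query",
            "s1": "sister",
            "o1": "outgroup:Stramenopila",
            "o2": "outgroup:Stramenopila",
            "o3": "outgroup:Stramenopila",
        }
        a = build_annotated("((q:1,s1:1)0.9:1,(o1:1,(o2:1,o3:1)0.9:1)0.9:1);", roles)
        b = build_annotated("(((o3:1,o2:1)0.9:1,o1:1)0.9:1,(s1:1,q:1)0.9:1);", roles)
        ra, rb = walk_query(a, "q"), walk_query(b, "q")
        assert ra.category == rb.category
        assert ra.donor_lineages == rb.donor_lineages
        assert frozenset(ra.stop.leaf_names()) == frozenset(rb.stop.leaf_names())

    def test_threshold_zero_gives_full_depth_trace(self):
        ann = build_annotated(
            "(((q:1,s1:1)0.9:1,s2:1)0.9:1,s3:1);",
            {"q": "query", "s1": "sister", "s2": "sister", "s3": "sister"},
        )
        params = WalkParams(support_threshold=0.0, min_sisters=99,
                            rooting_strategy="as_is")
        result = walk_query(ann, "q", params)
        # fully resolved: trace length equals the query's node depth
        assert len(result.trace) == 3

    def test_lower_threshold_refines_trace(self):
        ann = build_annotated(
            "(((q:1,s1:1)0.6:1,s2:1)0.9:1,(s3:1,s4:1)0.6:1);",
            {f"s{i}": "sister" for i in range(1, 5)} | {"q": "query"},
        )
        loose = walk_query(ann, "q", WalkParams(support_threshold=0.5,
                                                min_sisters=99,
                                                rooting_strategy="as_is"))
        tight = walk_query(ann, "q", WalkParams(support_threshold=0.85,
                                                min_sisters=99,
                                                rooting_strategy="as_is"))
        loose_sets = {frozenset(c.leaf_names()) for c in loose.trace}
        tight_sets = {frozenset(c.leaf_names()) for c in tight.trace}
        assert tight_sets <= loose_sets


class TestClassifyTree:
    def test_two_queries_share_stopping_clade(self):
        ann = build_annotated(
            "(((q1:1,q2:1)1.0:1,(o1:1,o2:1,o3:1)1.0:1)1.0:1,x1:1);",
            {
                "q1": "query",
                "q2": "query",
                "o1": "outgroup:Bacteria",
                "o2": "outgroup:Bacteria",
                "o3": "outgroup:Bacteria",
                "x1": "outgroup:Alveolata",
            },
        )
        results = classify_tree(ann, WalkParams(rooting_strategy="as_is"))
        assert [r.query for r in results] == ["q1", "q2"]
        assert results[0].category == results[1].category == Category.SINGLE_HGT
        assert frozenset(results[0].stop.leaf_names()) == frozenset(
            results[1].stop.leaf_names()
        )

    def test_query_free_tree_rejected(self):
        ann = build_annotated(
            "(a:1,b:1,c:1);",
            {"a": "sister", "b": "sister", "c": "sister"},
        )
        with pytest.raises(ValueError, match="no query"):
            classify_tree(ann)


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_walk_matches_bruteforce_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        params = WalkParams(rooting_strategy="as_is")
        for _ in range(300):
            ann, query = random_instance(rng)
            result = walk_query(ann, query, params)
            cat, stop_set, donors = oracle_walk(ann, query, params)
            assert result.category.value == cat
            got_set = (
                frozenset(result.stop.leaf_names()) if result.stop else None
            )
            assert got_set == stop_set
            assert result.donor_lineages == donors
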