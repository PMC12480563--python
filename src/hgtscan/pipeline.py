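"""End-to-end orchestration: trees in, tab-separated reports out.

The pipeline runs annotate → root → collapse → walk → direction →
aggregate → statistics over a directory of newick files and writes four
reports (per-query calls, events, enrichment, category summary) plus a
machine-readable manifest recording parameters, input checksums and
per-category counts.  Trees that fail to parse or annotate are logged,
skipped and counted; re-running on identical inputs yields byte-identical
reports.
"""

from __future__ import annotations

import glob
import hashlib
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import __version__
from .tree_io import (
    AnnotatedGeneTree,
    NewickParseError,
    TaxonomyError,
    TaxonomyMap,
    TreeValidationError,
    annotate_tree,
    contig_lengths_for,
    load_contig_lengths,
    parse_gene_tree,
    read_taxonomy_map,
)
from .walk import Category, WalkParams, WalkResult, classify_tree
from .events import HgtEvent, aggregate_events
from .stats import contig_length_check, lineage_enrichment

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    trees: str  # directory or glob of newick files
    taxonomy: str
    out_dir: str
    params: WalkParams = field(default_factory=WalkParams)
    og_table: Optional[str] = None
    contig_table: Optional[str] = None
    on_missing: str = "error"
    event_key: str = "focal"
    seed: int = 0


@dataclass
class RunArtifacts:
    results: dict[str, list[WalkResult]]
    events: list[HgtEvent]
    trees: list[AnnotatedGeneTree]
    category_counts: dict[str, int]
    n_skipped: int


def _tree_paths(spec: str) -> list[str]:
    if os.path.isdir(spec):
        paths = sorted(
            glob.glob(os.path.join(spec, "*.nwk"))
            + glob.glob(os.path.join(spec, "*.newick"))
            + glob.glob(os.path.join(spec, "*.tre"))
            + glob.glob(os.path.join(spec, "*.tree"))
        )
    else:
        paths = sorted(glob.glob(spec))
    return paths


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunArtifacts:
    os.makedirs(config.out_dir, exist_ok=True)
    taxmap = read_taxonomy_map(config.taxonomy)
    paths = _tree_paths(config.trees)
    if not paths:
        raise FileNotFoundError(f"no tree files under {config.trees!r}")

    annotated: list[AnnotatedGeneTree] = []
    n_skipped = 0
    for path in paths:
        og_id = os.path.splitext(os.path.basename(path))[0]
        try:
            with open(path, encoding="utf-8") as fh:
                text = fh.read()
            tree = parse_gene_tree(text)
            ann = annotate_tree(tree, taxmap, og_id, on_missing=config.on_missing)
            if not ann.has_query():
                raise TreeValidationError("no query leaves")
            annotated.append(ann)
        except (NewickParseError, TreeValidationError, TaxonomyError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            n_skipped += 1
    if not annotated:
        raise RuntimeError("no parseable, annotatable trees with query leaves")

    results: dict[str, list[WalkResult]] = {}
    events: list[HgtEvent] = []
    category_counts: dict[str, int] = {c.value: 0 for c in Category}
    for ann in annotated:
        walks = classify_tree(ann, config.params)
        results[ann.og_id] = walks
        for w in walks:
            category_counts[w.category.value] += 1
        events.extend(aggregate_events(walks, ann, event_key=config.event_key))

    _write_calls(os.path.join(config.out_dir, "calls.tsv"), results)
    _write_events(os.path.join(config.out_dir, "events.tsv"), events)
    _write_enrichment(
        os.path.join(config.out_dir, "enrichment.tsv"),
        events,
        annotated,
        taxmap,
    )
    _write_contig_check(config, results)
    _write_summary(
        os.path.join(config.out_dir, "summary.tsv"), category_counts, events
    )
    _write_manifest(config, paths, annotated, category_counts, events, n_skipped)
    return RunArtifacts(results, events, annotated, category_counts, n_skipped)


def _write_calls(path: str, results: dict[str, list[WalkResult]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "og_id\tquery\tcategory\tstop_clade_size\tn_sister_at_stop\t"
            "donor_lineages\ttrace_depth\n"
        )
        for og in sorted(results):
            for w in results[og]:
                stop_size = w.stop.n_leaves if w.stop else ""
                n_sister = w.stop.n_sister if w.stop else ""
                fh.write(
                    f"{og}\t{w.query}\t{w.category}\t{stop_size}\t{n_sister}\t"
                    f"{','.join(sorted(w.donor_lineages))}\t{len(w.trace)}\n"
                )


def _write_events(path: str, events: Sequence[HgtEvent]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "og_id\tevent_id\tcategory\tn_genes\tgene_ids\tdonor_lineages\t"
            "direction\tingroup_monophyletic\n"
        )
        for ev in sorted(events, key=lambda e: e.event_id):
            fh.write(
                f"{ev.og_id}\t{ev.event_id}\t{ev.category}\t{len(ev.genes)}\t"
                f"{','.join(ev.genes)}\t{','.join(sorted(ev.donor_lineages))}\t"
                f"{ev.direction}\t{str(ev.ingroup_monophyletic).lower()}\n"
            )


def _write_enrichment(
    path: str,
    events: Sequence[HgtEvent],
    trees: Sequence[AnnotatedGeneTree],
    taxmap: TaxonomyMap,
) -> None:
    header = "lineage\tn_trees\tW\tp\tp_adj\tmean_x\tmean_y\n"
    contributing_ogs = {ev.og_id for ev in events}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        if len(contributing_ogs) < 2:
            return
        for res in lineage_enrichment(events, trees, taxmap.lineages):
            fmt = lambda v: "" if v is None else f"{v:.6g}"
            fh.write(
                f"{res.lineage}\t{res.n_trees}\t{fmt(res.statistic)}\t"
                f"{fmt(res.p_value)}\t{fmt(res.p_adjusted)}\t"
                f"{res.mean_clade_share:.6g}\t{res.mean_tree_share:.6g}\n"
            )


def _write_contig_check(
    config: RunConfig, results: dict[str, list[WalkResult]]
) -> None:
    if config.contig_table is None:
        return
    with open(config.contig_table, encoding="utf-8") as fh:
        table = load_contig_lengths(fh.read())
    hgt_genes = [
        w.query for ws in results.values() for w in ws if w.is_hgt
    ]
    anc_genes = [
        w.query
        for ws in results.values()
        for w in ws
        if w.category is Category.ANCESTRAL
    ]
    hgt_lengths = contig_lengths_for(hgt_genes, table)
    anc_lengths = contig_lengths_for(anc_genes, table)
    path = os.path.join(config.out_dir, "contig_check.tsv")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("U\tp_two_sided\tA\tn1\tn2\tinterpretation\n")
        if not hgt_lengths or not anc_lengths:
            return
        rep = contig_length_check(hgt_lengths, anc_lengths)
        fh.write(
            f"{rep['U']:.6g}\t{rep['p_two_sided']:.6g}\t{rep['A']:.6g}\t"
            f"{rep['n1']}\t{rep['n2']}\t{rep['interpretation']}\n"
        )


def _write_summary(
    path: str, category_counts: dict[str, int], events: Sequence[HgtEvent]
) -> None:
    n_hgt_genes = sum(len(ev.genes) for ev in events)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("metric\tvalue\n")
        for cat in sorted(category_counts):
            fh.write(f"n_queries_{cat}\t{category_counts[cat]}\n")
        fh.write(f"n_hgt_events\t{len(events)}\n")
        fh.write(f"n_hgt_genes\t{n_hgt_genes}\n")
        fh.write(
            "n_hgt_events_acceptor\t"
            f"{sum(1 for ev in events if ev.direction.value == 'acceptor')}\n"
        )


def _write_manifest(
    config: RunConfig,
    paths: Sequence[str],
    annotated: Sequence[AnnotatedGeneTree],
    category_counts: dict[str, int],
    events: Sequence[HgtEvent],
    n_skipped: int,
) -> None:
    lines = {
        "hgtscan_version": __version__,
        "n_tree_files": str(len(paths)),
        "n_trees_processed": str(len(annotated)),
        "n_trees_skipped": str(n_skipped),
        "n_queries_processed": str(sum(category_counts.values())),
        "n_hgt_events": str(len(events)),
        "taxonomy_md5": _md5(config.taxonomy),
        "trees_md5": hashlib.md5(
            "".join(_md5(p) for p in paths).encode()
        ).hexdigest(),
        "support_threshold": str(config.params.support_threshold),
        "min_sisters": str(config.params.min_sisters),
        "min_outgroup_per_lineage": str(config.params.min_outgroup_per_lineage),
        "rooting_strategy": config.params.rooting_strategy,
        "strict_greater": str(config.params.strict_greater).lower(),
        "single_lineage_rule": config.params.single_lineage_rule,
        "event_key": config.event_key,
        "on_missing": config.on_missing,
    }
    for cat, n in sorted(category_counts.items()):
        lines[f"count_{cat}"] = str(n)
    with open(
        os.path.join(config.out_dir, "manifest.txt"), "w", encoding="utf-8"
    ) as fh:
        for key in sorted(lines):
            fh.write(f"{key}={lines[key]}\n")
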