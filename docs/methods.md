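# Methods

## The classifier

`hgtscan` treats HGT detection as a per-query scan over nested, highly
supported clades of a gene tree.  The model's assumptions are:

* **Role partition.**  Every leaf is exactly one of `query` (a focal
  sequence under evaluation), `ingroup` (another focal-lineage
  sequence), `sister` (the focal lineage's closest relatives), or
  `outgroup` with a major-lineage label.  Roles come from database
  provenance upstream and are taken as given.
* **Support semantics.**  Internal-node labels in [0, 1] are per-edge
  (per-bipartition) supports, the dialect of fast approximate-ML tree
  builders.  "Highly supported" is strict: support > 0.85.  Edges
  without a label — leaf edges and the root — carry no support and are
  treated as resolved, never collapsed: absence of evidence about a
  bipartition is not evidence against it.  Labels on a 0–100 scale are
  rescaled to [0, 1] (with a warning) when any label exceeds 1.
* **Vertical signal dominates.**  When a clade simultaneously satisfies
  the sister criterion and a transfer criterion (possible at
  polytomies), the vertical call wins: precedence is
  `ancestral ≻ ancestral_hgt ≻ single/multi_hgt`.
* **Cumulative evaluation.**  Counts are cumulative over each nested
  clade; because clades are nested, "found so far" and "found in the
  current clade" coincide, and traces are component-wise non-decreasing
  (violations are rejected as a programming error).

Default thresholds (`WalkParams`): support cutoff 0.85 (strict), 5
sisters for `ancestral`, 3 outgroup sequences of one lineage for any
transfer call.  `single_hgt` purity is literal by default — *all*
outgroup leaves of the stopping clade share one lineage — with an
optional ≥ 90 % majority rule (`single_lineage_rule="majority"`) for
corpora where stray misannotated leaves are common.

Two categories extend the four call types: `ingroup_only` (the whole
tree is focal, nothing to compare against) and `undetermined` (the walk
exhausts a mixed tree without any criterion firing).  `undetermined`
exists because silently forcing one of the other labels onto such walks
would fabricate calls; downstream counts treat it as "no call".

## Rooting

The walk needs a rooted tree but the input trees are typically
unrooted.  No rooting convention is canonical for this procedure, so
two deterministic strategies are shipped and the choice is explicit:

* `farthest_leaf` (default): root on the terminal edge of the leaf with
  the greatest path length from the lexicographically first query leaf,
  ties broken by leaf name.  This maximizes the walk length from the
  query and is stable under child reordering.
* `midpoint`: root at the midpoint of the longest leaf-to-leaf path.
* `as_is`: keep the input rooting (refused for basal polytomies).

Re-rooting preserves supports on the bipartitions they describe: when an
edge flips orientation its support moves with it, and the two half-edges
of a suppressed old root are merged as the single unrooted edge they
are.  Deep queries can receive different calls under different rootings
— that is a property of the procedure, not a bug — so the strategy is
recorded in the run manifest.

## Direction and events

The ingroup-monophyly test roots the stopping clade at its own ancestral
node and asks whether the focal+sister leaves inside it form one clade
(equivalently: their MRCA within the clade subtree contains no outgroup
leaf).  Monophyly is evidence the focal lineage *received* the gene
(`acceptor`); interspersed focal leaves leave the direction
`unresolved`, since an unrooted topology cannot distinguish donor from
acceptor there.  The test ignores branch lengths and child order.

Events deduplicate per-query calls within one orthogroup.  The event key
is the stopping clade's focal+sister leaf set — not the full leaf set —
so queries whose clades differ only in outgroup resolution still merge
(`event_key="full"` switches to full-leaf-set keying).  An event is
`acceptor` only when every member walk is; donors are unioned.  Events
are never merged across orthogroups: without sequence-level identity
there is no sound cross-orthogroup key.

## Statistics

The rank tests are in-house primitives with two regimes:

* exact enumeration — all C(n1+n2, n1) group assignments for
  Mann–Whitney (valid under ties), a rank-sum convolution over the 2^m
  sign assignments for the signed-rank test — whenever the pooled (or
  nonzero-pair) size is ≤ 20;
* a tie-corrected normal approximation with continuity correction
  otherwise, matching common implementations to ~1e-9 on tie-free data.

The cutoff of 20 keeps small-instance results exact while corpus-scale
inputs use the approximation.  Zeros are dropped before ranking; ties
get average ranks.  Benjamini–Hochberg adjustment is the standard
step-up `q(i) = min_{j≥i} (m/j)·p(j)` capped at 1.

The enrichment test is read as a *paired* comparison because the
question conditions on each tree's own taxonomic composition: for every
tree contributing ≥ 1 transfer event, x_t = the lineage's share of
non-focal (sister+outgroup) leaves inside the union of that tree's
stopping clades, y_t = the same share over the whole tree, and the
one-sided (greater) signed-rank test runs on d_t = x_t − y_t.  (An
unpaired rank-sum variant would compare across trees and lose that
conditioning.)  Lineages with fewer than two usable trees or all-zero
differences are reported with p absent and excluded from the BH family
rather than given a fabricated p of 1.

The contig-length check takes pre-joined length lists (the gene →
contig → length join is a reader utility) so the statistic itself stays
pure: x = contig lengths of transfer-called genes, y = of
ancestral-called genes, reporting U, two-sided p and A, with
"no-shortening signal" when A ≥ 0.5 or p above the threshold.

## Synthetic data

The generator plants one scenario per tree and records the truth, so
recovery is measurable without any external data:

* topology: random joins (Yule-type) — the simplest seeded process;
  topological realism (birth–death, rate variation) is deliberately not
  modeled because the classifier only consumes the role arrangement;
* branch lengths Exp(1), unitless;
* supports: point mass at 1.0 (clean conditions) or i.i.d. Beta(8, 2)
  per internal edge, which puts ≈ 14 % of edges below the 0.85 cutoff
  and exercises polytomy collapse;
* scenario cores built to satisfy exactly their own criterion and no
  higher-precedence one: `vertical` nests the query among ≥ 5 sisters
  with no outgroup inside the core; `ancient_hgt` wraps (query + 2
  sisters) beside 3 donor leaves; `recent_hgt_single` wraps (query + 1
  ingroup) beside a pure 3-leaf donor clade; `recent_hgt_multi` builds a
  caterpillar of mixed-lineage tuples so all donor lineages reach the
  per-lineage minimum at the same clade and no pure sub-clade fires a
  single-lineage call first;
* one background *anchor* leaf carries a terminal branch longer than the
  sum of all other branches, pinning farthest-leaf (and midpoint)
  rooting outside the core so the planted clade survives re-rooting —
  the synthetic analogue of a real outgroup-rich tree whose deepest
  split lies outside the focal clade;
* label noise re-draws a leaf's role/lineage uniformly from the full
  vocabulary excluding its truth, stressing both the count thresholds
  and the monophyly test;
* default tree size 40 leaves, 1 query, five-lineage outgroup
  vocabulary; corpora assign og ids `OG0000001…` and derive per-tree
  seeds from one master seed, so a corpus is byte-reproducible.

What passing recovery tests shows: the classifier implements its own
criteria correctly and degrades gracefully under label noise.  What it
does **not** show: performance on real gene trees, where alignment
error, long-branch attraction, incomplete taxon sampling and paralogy
violate the planted-clade idealization.  The generator makes no attempt
to emulate those failure modes; real-data validation is what the
contig-length and enrichment statistics are for.

Recovery scoring uses the first (lexicographically smallest) query per
tree as the tree's prediction; under heavy noise a tree can lose all
query labels, which is scored as a wrong prediction rather than dropped.

## Numerical and determinism choices

* Missing branch lengths count 0 in path-length computations; rooting
  ties break lexicographically by leaf name.
* Collapse is idempotent and runs before any counting; the supported
  clade set of the collapsed tree equals the set of supported clades of
  the input, which is what the brute-force oracle in the test suite
  enumerates independently.
* Floating-point tolerances: 1e-12 for rooting-distance ties, 1e-9 for
  exact-test tail comparisons; newick output prints supports to 6
  significant digits and lengths to 10.
* Nothing in the classifier is stochastic; identical inputs and
  parameters give identical outputs, and pipeline reports contain no
  timestamps so re-runs are byte-identical.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at sizes chosen to make
every property measurable in seconds on one core: 50,000 (suite) /
20,000 (script) sampled ≤ 8-leaf trees for oracle agreement, a 200-tree
clean corpus (5 scenarios × 40) for recovery, 10 seeds × 4 noise levels
for degradation, and 200 permutation replicates for the enrichment
null.  These sizes are the package's own validation design; all scale
linearly if larger runs are wanted.

## Known limitations

* Sequences, alignments and support values are never re-examined; a
  wrong tree yields a wrong call ("garbage in").
* The per-lineage minimum (3) counts sequences, not distinct taxa; three
  sequences from one contaminated genome satisfy it.
* Direction inference is topological only; gene-flow into the sisters
  followed by loss in the outgroup can mimic `acceptor`.
* No cross-orthogroup event merging and no ancestral gain/loss
  reconstruction over a species tree.
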