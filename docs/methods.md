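# Methods

This note documents the models, conventions and numerical choices behind
`elin`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Domain model

**Periods.** Six early-life windows: EG (GD0–GW12), MG (GW13–28), LG
(GW29–40), birth (a point event, empty window label), newborn (0–28 days)
and infant (1–23 months). Every statement file is tagged with exactly one
period; networks are built per period and only compared at the end.

**Layers and groundings.** An entity's layer is a pure function of its
database groundings: HGNC → gene/protein, FPLX → protein family, CHEBI →
chemical, GO → GO process, MESH/DOID/UMLS → disease. When a text-mined
entity carries conflicting groundings we resolve by a fixed precedence
(HGNC > FPLX > CHEBI > GO > MESH > DOID > UMLS). The precedence is a design
choice of this package: gene identity is the pipeline's backbone (denoising,
enrichment and profiles all key on gene symbols), so a gene reading wins
whenever one exists. Ungrounded entities fall back to `TEXT:<UPPERCASED
NAME>` ids so surface-case variants merge; an ungrounded name is routed to
the text-mined bioprocess layer when the statement source flags it as one,
to the immune-endpoint layer when it matches one of the four fixed endpoint
names, and otherwise is kept as a gene-like node with `is_human_gene=False`.
That last rule is deliberate: non-human genes (lacZ, env, rpoD, …) from
bacterial/viral immunology papers must remain in the network even though no
human reference or annotation resource will ever connect them directly.

**Genes and proteins are one node.** Text rarely distinguishes a gene from
its protein, so a single GENE_PROTEIN node represents both.

**Graph container.** A `networkx.MultiGraph` with parallel edges keyed by
provenance (LITERATURE, REFERENCE_CONFIRMED, GO/GOSLIM/DISEASE_ENRICHMENT,
ENDPOINT_MAPPING, INFERRED): one node pair may legitimately carry, say, both
a literature edge and an enrichment edge, but never two edges of the same
provenance. Graphs round-trip exactly through GraphML and through paired
nodes/edges TSVs.

## Assembly

Statements collapsing onto the same unordered node pair merge into one
literature edge; evidence counts are **summed** (not maxed) so the total
literature support mass is conserved and reportable. The merged edge keeps a
direction only when every contributing statement type is directional
(Activation, Inhibition, IncreaseAmount, DecreaseAmount) and all agree on
the subject→object orientation; any Complex/Association statement or a
direction conflict demotes the edge to undirected. Downstream stages treat
all edges as associations anyway — the final products are association
networks, and PageRank runs on the symmetrized topology — so the direction
flag is provenance metadata, not an analysis input. Self-statements are
dropped (and counted); a file in which more than half the records fail
validation is rejected outright as malformed rather than silently filtered.

## Denoising

A gene–gene literature edge survives iff its unordered uppercase symbol pair
appears in the reference association table; the match ignores direction,
reference network type and reference weight — it is a presence/absence
test, and surviving edges are re-tagged REFERENCE_CONFIRMED (which also
makes the operation idempotent). Gene–gene edges touching a non-human gene
are always removed: they cannot be confirmed by a human reference. Nodes are
never removed; confirmation percentages are reported as integer percents
with half-up rounding. Edges with at least one non-gene endpoint are out of
scope for this stage.

## Enrichment

Enrichment is a restricted annotation **join**, not an over-representation
test: each (gene, term) row whose gene is already a human gene node in the
period network adds the term node and an undirected edge of weight 1.
Restricting to genes already in the network keeps the period specificity —
a gene not described in that window's literature contributes nothing.
Endpoint mapping runs after all gene→term sources, attaching bioprocess
terms to the four endpoints only when the term made it into the graph, so
every endpoint connection is anchored through at least one gene.
Statistical testing is deferred entirely to the inference stage. An optional
minimum-score cutoff for disease rows exists but defaults to off.

## Overlap inference

For each candidate cross-layer pair (default: every process-layer node
against every disease, and every disease against every endpoint) we collect
**gene profiles** — the gene neighbours of each node, whatever edge
provenance connects them; an endpoint's profile is the union over its mapped
terms. Pairs sharing at least `min_overlap` genes (default 2, so a single
shared pleiotropic gene cannot create an edge) are scored with the
hypergeometric upper tail and BH-adjusted within the layer pair; pairs with
q ≤ α (default 0.05) become INFERRED edges weighted by Jaccard similarity.
The background universe defaults to the number of distinct gene symbols in
the annotation tables *and* the graph's gene layer — the union guards
against a profile (literature neighbours included) exceeding an
annotation-only universe, which would make the test ill-posed. BH is the
right correction here because the candidate-pair count grows as the product
of two layer sizes. The hypergeometric tail comes from
`scipy.stats.hypergeom`; the BH step-up is a ten-line vectorised
implementation verified in the tests against a direct step-up scan, and the
tail against exhaustive enumeration of all draws for small backgrounds.

Note the test is conservative for small, sparse profiles (the discrete null
puts mass below any fixed threshold); its null calibration approaches the
nominal level only when profiles are large relative to 1/α.

## PageRank prioritization

Power iteration on the column-stochastic transition matrix of the
symmetrized adjacency, with uniform teleportation at damping d = 0.85 (the
classical default), convergence at L1 change < 1e-10, and a 1000-iteration
cap that raises (with the residual) rather than returning an unconverged
vector. Parallel provenance edges count once; the walk is unweighted by
default because relationship strength is deliberately not modelled —
`use_weights=True` switches to weight-proportional transitions. Isolated
nodes receive exactly the teleportation floor (1−d)/N: disconnected
non-human genes rank low but never at zero, and can climb once enrichment
re-connects them. Ranking is global, then filtered to the gene layer for the
top-k list (default 50); ties break lexicographically by node id so ranks
are reproducible across platforms. The implementation is checked against a
dense eigendecomposition of the Google matrix and against an independent
library implementation.

## Cross-period comparison

The three gestation top-50 lists merge by union into one gestation set; the
4-set Venn over {gestation, birth, newborn, infant} assigns every gene to
exactly one of 15 regions by membership signature. The **all-period core**
is intentionally stricter than the Venn's full region: it intersects the six
un-merged lists, so a gene must be top-ranked in *every* window, not merely
in some gestation window plus the three later ones.

## Synthetic data generator

The generator emulates the five input resources with planted ground truth:

- **Hubs** (default 10 of 300 genes) appear in statements and in every
  annotation table with `hub_degree_multiplier` (default 8) times the
  baseline probability. Hubs are planted through degree and annotation
  density rather than block structure because that is exactly the signal
  PageRank is meant to reward.
- **Statement mix** per period (default 500 records): 70% gene–gene, 12%
  gene–bioprocess, 8% gene–chemical, 5% gene–family, 5% contaminant
  records. Evidence counts are 1 + Poisson(0.5).
- **Noise and reference coverage.** A `noise_edge_fraction` (default 0.3) of
  gene–gene statements use uniformly random pairs that never enter the
  reference table; `reference_coverage` (default 0.3) of each period's
  distinct gene–gene pairs — sampled from the non-noise pairs — are copied
  into the reference table, which is then padded with twice as many
  background pairs never seen in statements. The default coverage mirrors
  the ~27–32% confirmation range typical of literature networks checked
  against a human association database. Within a period, a pair drawn both
  as noise and as structure counts as structure; across periods, any pair
  that is noise somewhere is excluded from reference sampling everywhere.
- **Contaminants** (default 5, names drawn from non-human genes seen in real
  text-mined immune corpora: lacZ, env, rpoD, dop, cscK, …) appear
  ungrounded in statements and in no annotation table.
- **Annotations**: per (gene, term) Bernoulli draws calibrated to ~2 GO,
  ~1 GO-slim and ~1.5 disease terms per non-hub gene; ~30% of process terms
  map onto one or two immune endpoints.

Everything is driven by one `numpy` generator seeded from the config, and
files are written in sorted order, so identical configs produce
byte-identical bundles. The generator also writes its own bookkeeping
(distinct pairs, confirmable pairs, row counts) which the tests re-derive by
re-parsing the written files.

What the generator does **not** emulate: text-mining misgroundings beyond
the contaminant mechanism, the heavy-tailed term-size distribution of real
GO (terms here are roughly exchangeable), ontology structure (terms are
flat labels; there is no DAG propagation, matching the pipeline's
non-goals), citation bias, or cross-period article overlap. Passing the
planted-hub recovery test therefore shows that the pipeline rewards
degree-plus-annotation centrality as designed — not that top-50 lists from
real corpora would be equally clean, where hub signal competes with
reporting bias and annotation incompleteness.

## Default problem sizes

Unit tests run on hand-built graphs and a reduced bundle (60 genes, 4 hubs,
120 statements/period); the end-to-end and acceptance checks use the full
default bundle (300 genes, 6 periods, 500 statements each), 200 random
graphs of up to 50 nodes for the PageRank oracle sweep, exhaustive
enumeration up to background 12 for the hypergeometric oracle, and 2,500
independently drawn profile pairs (sizes 500–1500, background 5000) for
null calibration — sizes at which the discrete tail is effectively
continuous. The whole suite completes in well under a minute.

## Known limitations

- Matching is symbol-based at denoising/enrichment; identifier remapping
  (aliases, withdrawn symbols) is assumed to have happened upstream.
- The inference test treats profiles as fixed sets; it does not model the
  dependence induced by shared genes across candidate pairs beyond the BH
  correction.
- PageRank is global; layer-restricted or personalized walks are out of
  scope.
- The four immune-health endpoints are a fixed package-level enumeration,
  not user input.
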