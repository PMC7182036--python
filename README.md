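# elin — early-life immune networks

`elin` builds and analyses **heterogeneous multilayer networks of early-life
immunity**. Knowledge about how the human immune system develops during
gestation, birth and infancy is scattered across thousands of papers; after a
text-mining tool has turned that literature into causal statements between
grounded biological entities, `elin` assembles those statements into six
period-specific networks (1st/2nd/3rd trimester of gestation, birth, newborn
0–28 days, infant 1–23 months), cleans and enriches them, and prioritizes the
genes most central to each developmental window. The intended users are
computational immunologists and systems biologists who want a reproducible,
inspectable pipeline from statement files to ranked candidate markers.

## The method

Nodes are typed into eight layers — genes/proteins, protein families,
chemicals, text-mined bioprocesses, GO processes, GO-slim processes, diseases
and four fixed immune-health endpoints (autoimmunity, hypersensitivity,
resistance to neoplasms, resistance to infections). The pipeline is:

1. **Assemble** — parse causal statements (JSON; Activation, Inhibition,
   IncreaseAmount, DecreaseAmount, Complex, Association), canonicalize
   entities by their database groundings (HGNC > FPLX > CHEBI > GO > disease
   namespaces), and merge statements on the same unordered node pair into one
   literature edge with summed evidence.
2. **Denoise** — keep a gene–gene literature edge only if the symbol pair
   occurs in a reference human functional-association table
   (GeneMania-style); removed edges leave their genes behind as disconnected
   nodes.
3. **Enrich** — join gene→GO, gene→GO-slim and gene→disease annotation tables
   onto the genes already in the network, then map bioprocess terms onto the
   four immune-health endpoints.
4. **Infer** — connect nodes in different layers (bioprocess→disease,
   disease→endpoint) when their gene profiles overlap more than chance: for
   profiles of sizes $|A|$, $|B|$ in a background of $N$ genes with overlap
   $k$, the p-value is the hypergeometric tail $P(X \ge k)$,
   Benjamini–Hochberg adjusted across all candidate pairs; significant pairs
   ($q \le \alpha$, default 0.05) become edges weighted by Jaccard similarity
   $|A \cap B| / |A \cup B|$.
5. **Rank** — PageRank over the full symmetrized, unweighted topology
   (damping 0.85): the stationary distribution of a random walk with uniform
   teleportation, so a gene is important when important
   genes/bioprocesses/diseases attach to it. The top-50 genes per period are
   the candidate markers.
6. **Compare** — merge the three gestation lists, partition the 4-set Venn
   over {gestation, birth, newborn, infant}, and intersect the six un-merged
   lists for the all-period core.

A synthetic-data generator produces complete input bundles with planted hub
genes, noise edges and non-human contaminant entities, so the whole pipeline
is testable without any database downloads.

## Worked example

```bash
elin simulate --out-dir fixtures --seed 42
# bundle in fixtures: 6 periods, 300 genes (10 hubs: ELG026, ELG029, ELG061,
#   ELG128, ELG130, ELG192, ELG208, ELG226, ELG255, ELG297)

elin run-all --config config.yaml     # config points at fixtures/, out_dir: outputs
```

`outputs/denoise_report.tsv` shows, per period, how many gene–gene literature
edges the reference table confirmed — by construction around the generator's
30% coverage:

```
period  n_genes n_edges confirmed
EG      284     370     105 (28%)
...
NEWBORN 287     375     110 (29%)
INFANT  276     370     107 (29%)
```

`outputs/NEWBORN_top50.tsv` is the ranked gene list; the planted hubs surface
at the top (scores are PageRank mass, summing to 1 over all nodes):

```
rank  node_id     label   score            layer
1     HGNC:50297  ELG297  0.0113505847007  GENE_PROTEIN
2     HGNC:50192  ELG192  0.0103770966438  GENE_PROTEIN
3     HGNC:50130  ELG130  0.0103105435459  GENE_PROTEIN
```

`outputs/manifest.json` records parameters, input digests and the
cross-period comparison: on this bundle the gestation top-50 lists merge to
86 unique genes and 18 genes are central in every period — including all 10
planted hubs.

Every stage is also available separately (`elin build`, `elin denoise`,
`elin enrich`, `elin infer`, `elin rank`, `elin compare`) and as library
functions (`elin.assemble_network`, `elin.denoise_graph`, …).

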