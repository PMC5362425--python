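# Methods

`netpharm` implements an in-silico target-identification workflow of the
kind used in network pharmacology of multi-herb formulas: a herbal
preparation contains hundreds of chemicals, only some of which are
plausibly active after oral dosing, and the therapeutic hypothesis is that
the active compounds collectively modulate a set of proteins central to a
disease. The pipeline turns that hypothesis into a sequence of explicit,
auditable set and graph computations.

## Pipeline model

1. **ADME screening.** Each compound carries a predicted oral
   bioavailability OB (percent of an oral dose reaching circulation) and a
   drug-likeness index DL (structural similarity to approved drugs, in
   [0, 1]). Both arrive as input columns; computing them from structure is
   out of scope. A compound is kept when OB ≥ 30 % and DL ≥ 0.18 (the
   TCMSP-convention cutoffs, applied inclusively), or — when no DL
   prediction exists — when OB ≥ 35 %, a stricter OB-only fallback.
   Compounds failing both rules can be rescued through an explicit
   whitelist file; rescue is id-based because literature rescue is a
   judgement call, not a computable rule. A record with neither OB nor DL
   is excluded (with a warning) unless whitelisted.

2. **Compound–target network.** Kept compounds are linked to their
   predicted protein targets (an input mapping table) as a bipartite
   graph. Compounds with no mapped target are excluded from the graph but
   reported. Compound and target namespaces are kept disjoint (`cpd:` /
   `tgt:` prefixes in exported graphs). Per-herb target sets are the union
   of targets of kept compounds containing that herb — the only reading
   consistent with heavy target overlap between herbs that share
   constituents.

3. **Disease-target merge.** Disease-associated gene lists from several
   sources are normalized (uppercase + trim; no alias mapping, since
   cross-database identifier reconciliation is not modelled), unioned, and
   deduplicated, with per-symbol source provenance retained.

4. **Seed-expanded PPI networks and intersection.** Each gene set (the
   putative targets and the merged disease targets) is mapped onto a
   background PPI graph and expanded one hop: the node set is the mapped
   seeds plus all their direct interactors, the edge set the induced
   subgraph. One-hop expansion mirrors the default "add neighbours"
   behaviour of interactome-assembly tools; `expansion: none` disables it.
   Seeds missing from the PPI are reported; seeds with no partner are
   dropped from the graph but listed. The two networks are intersected
   node-wise and edge-wise. Because both are induced subgraphs of one
   background PPI, edge intersection equals the induced subgraph on the
   common nodes (a property the tests verify).

5. **Two-stage median-threshold filter.** Stage 1 computes the median
   degree m of the intersected network and keeps nodes with degree
   strictly greater than 2m ("significant" targets), taking the induced
   subgraph. Stage 2 recomputes all six centrality measures *on that
   subgraph* — not inherited from the parent, since the induced core is
   much denser — and keeps nodes strictly exceeding the median of every
   measure simultaneously ("candidate" targets). Strict inequalities mean
   a vertex-transitive graph yields no candidates; the filter is
   hub-seeking by construction. Medians use the standard convention
   (mean of the two middle values for even counts), recorded in the
   threshold output for auditability.

6. **Enrichment.** Candidate targets are tested against a GMT annotation
   collection with the exact upper-tail hypergeometric probability,
   BH-adjusted within each term category (categories are reported
   separately; pooling is a config option). Enriched terms (p_adj ≤ α,
   default 0.05) are linked when the Cohen kappa of their gene memberships
   over the reference set reaches `kappa_min` (default 0.4, the documented
   default of the ClueGO grouping this emulates); connected components of
   the link graph form term groups, each labeled by its lowest-p_adj
   member (ties broken lexicographically).

## Centrality definitions and numerics

Degree (DC), betweenness (BC), closeness (CC), eigenvector (EC) plus two
essential-protein measures: NC, the sum over a node's incident edges of
the edge clustering coefficient ECC(u,v) = z / min(deg u − 1, deg v − 1)
with z the number of triangles on the edge (ECC := 0 when the denominator
is 0), and LAC, the mean degree of a node's neighbours within the
neighbour-induced subgraph.

- BC is **unnormalized** (raw unordered-pair path counts): the median
  thresholds of stage 2 are defined on raw values, and normalization
  would change them.
- CC is (n_c − 1)/Σd within the node's component; isolated nodes get 0.
- EC is computed independently per connected component and unit-normalized
  (Euclidean) within the component; isolated nodes get 0. The iteration
  runs on A + I rather than A: the shift leaves eigenvectors unchanged but
  makes the principal eigenvalue strictly dominant, which plain power
  iteration lacks on bipartite components (spectrum symmetric about 0).
  Start vector all-ones, convergence tolerance 1e−12, cap 10⁵ iterations,
  sign fixed nonnegative — fully deterministic.
- Disconnected inputs are legal everywhere; per-component conventions are
  the ones stated above.

Betweenness and closeness are delegated to networkx (Brandes algorithm;
`normalized=False`, `wf_improved=False` match the definitions above); EC,
NC and LAC are implemented here. The test suite checks all six against an
independent brute-force oracle (explicit shortest-path enumeration, dense
eigendecomposition, triple-loop triangle counts) on 200+ random graphs at
|error| ≤ 1e−8, plus closed forms on stars, paths, cycles and complete
graphs.

## Enrichment numerics

The hypergeometric tail comes from `scipy.stats.hypergeom.sf(k−1, N, K, n)`
and is verified against exact rational-arithmetic enumeration for every
configuration with N ≤ 25 at 1e−12. The enrichment universe defaults to
(genes present in the GMT) ∩ (nodes of the intersected network) — the
vocabulary-aware choice; it is configurable because over-representation
results depend on it and no universally right universe exists. BH
adjustment uses statsmodels. Query genes outside the universe are dropped
with a logged count; terms with no universe genes are skipped.

## Synthetic data: what it emulates and what it does not

`simulate_bundle` generates the full input bundle from one integer seed:

- **Compound table**: 8 herbs × 20 compounds, cross-herb sharing with
  probability 0.15 per additional herb, OB ~ Uniform(0, 80) %,
  DL ~ Beta(2, 4), 5 % missing DL, and 4 whitelisted rescue compounds
  drawn from the failures. These rates give a kept fraction (~50 %) and a
  screening structure (threshold passes, OB-only passes, rescues) that
  exercise every rule branch.
- **Compound→target map**: out-degrees geometric with mean 11 (matching
  the heavy-tailed "few promiscuous hub compounds" shape of real
  compound-target predictions, where the median compound hits ~11
  targets), targets drawn with degree-proportional weights, ~15 % of kept
  compounds left unmapped.
- **Background PPI**: a 300-node Barabási–Albert graph (m = 3) — PPI
  degree distributions are heavy-tailed — with a 15-node module planted on
  the highest-degree nodes and wired internally at density 0.9. Disease
  proteins concentrate on hubs, and placing the dense module on hubs puts
  the ground truth in the regime the hub-seeking filter assumes, so the
  filter has something well-defined to recover.
- **Disease lists**: five sources with sizes 10/10/60/25/15 (shaped like
  the very unequal sizes of real curated sources), each containing every
  module gene with probability 0.8 plus degree-weighted background genes.
- **Annotations**: three planted terms (≈10 module genes + 1 background
  gene each) plus 30 random background terms, split across the two
  categories.

The manifest records the exact kept-compound set, module and planted term
ids, so tests can assert recovery. Recovery is asserted as Jaccard ≥ 0.6
between candidates and the planted module rather than equality, because
median thresholds interact with background hubs that legitimately pass.

The generator is deliberately statistical, not chemical: it reproduces the
degree structure, overlap structure and missingness of real inputs, but
not real OB/DL marginals, gene identifiers, annotation semantics, or the
literature-curation process behind rescue lists. Passing the recovery
tests therefore shows the pipeline machinery is correct under the stated
statistical assumptions — not that any particular real formula or disease
would yield the same target lists.

## Problem sizes

The standard bundle (seed 42) was sized so that every stage's behaviour
is observable — a ~160-compound screen, a ~280-node intersected network, a
~34-node significant core, ~13 candidates — while the whole pipeline and
its brute-force verification run in seconds; statistically it is a
scaled-down study, not a re-run of a full interactome analysis, where the
same code applies unchanged (the betweenness pass dominates and remains
minutes-scale on interactome-sized graphs).

## Known limitations

- Symbol-level identity is assumed throughout; no alias/accession mapping.
- One-hop expansion is the only implemented interactome-assembly policy
  besides none.
- The enrichment universe choice is the largest analytic degree of
  freedom; both options are explicit config, neither is "the" answer.
- Kappa grouping uses single-linkage connected components, which can
  chain weakly related terms in dense vocabularies.
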