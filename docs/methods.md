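# Methods

## Overview and assumptions

`painmap` models a cross-species candidate-gene analysis: a functional
screen in one species (the "fly" namespace) produces a hit list; orthology
tables project that list into two mammalian namespaces; physical-interaction
edges add first-degree binding partners; hypergeometric tests find gene sets
over-represented in the projected query; significant sets are pooled into
functional classes to form a bipartite systems map; and the map's genes are
compared with independent pain-annotation sources against a random-list
null.

The analysis assumes:

- Gene identifiers are opaque, case-sensitive strings; `(species, id)` is
  the unique gene key. No symbol-alias resolution is attempted.
- Orthology predictions are inputs, not inferences. Merging across
  prediction sources is a set union with per-mapping method provenance —
  union maximizes recall and is the only merge rule that preserves observed
  many-to-many topology without an arbitrary agreement threshold. An
  optional `min_sources` filter restricts to mappings supported by ≥ k
  methods.
- Physical binding is symmetric, so interaction edges are undirected
  regardless of file order; self-loops are biologically meaningless here
  and dropped.
- Partner expansion happens in fly space before projection (the default;
  the enrichment query per mammalian species is the projection of
  hits ∪ partners).
- Node categories follow the precedence **pain > lethal > binding_partner**:
  a screen hit remains a pain node even when it also carries a lethal
  annotation or neighbors another hit. Overlaps trigger an integrity
  warning rather than an error.
- Developmental lethals are displayed, never tested: they are excluded from
  enrichment queries and join the map only when they are members of an
  already-significant set.

## Enrichment

The statistic is the one-sided hypergeometric upper tail
P(X ≥ k | N, K, n), computed via `scipy.stats.hypergeom.sf` (log-gamma
based, stable to N ~ 10⁶). Gene sets are intersected with the background
before testing; query genes outside the background are dropped with a
warning. Only over-representation is tested.

Significance thresholds are per collection: 0.1 for GO-style and
KEGG-pathway-style collections, 0.01 for curated C2-style collections.
These are raw-p thresholds — no multiple-testing correction by default,
matching the analysis style this package reproduces; a Benjamini–Hochberg
mode (`apply_bh=True`) is available and changes only the significance
calls, never the reported p-values.

GO-style results are additionally pruned: terms with more than 500 genes
are removed outright (large terms carry little information), and within
each ancestor–descendant chain of significant terms (transitive closure of
the supplied child→parent table) only the term with maximal overlap k is
retained, ties broken by smaller p and then name. The pruning is greedy in
(−k, p, name) order, which guarantees a term is only removed when a
comparable retained term beats it. Every removal is logged with its reason.

The background universe N is configurable; the pipeline default is the
species' full gene universe. Because the test is one-sided and discrete,
its realized size is below the nominal alpha at typical margins (null
overlap means of 1–3 genes per set); the test suite verifies the empirical
false-positive rate matches the exact attainable discrete size and never
exceeds the nominal level.

## Systems map

Significant sets are pooled into functional classes through an explicit
`set_name → class_label` table — class assignment is curator input, not
clustering, mirroring how such maps are built in practice. Class
membership is the union of query genes captured by the contributing sets
across species. Genes are unified across species by their fly anchor: a
mammalian gene collapses onto the fly gene that has it as an ortholog
target, preferring anchors inside the categorized hit/partner/lethal
universe (then lexicographic minimum, for determinism under many-to-many
topology); genes without a fly anchor keep a species-qualified ID.

The map is bipartite by construction (class ↔ gene edges only); classes
with no members are never created, so every node has degree ≥ 1.

Diagnostics:

- **Hit representation** — per class, the fraction of member genes that are
  direct hits; exactly 50% counts as *not* majority-hit (strict
  inequality).
- **Connectivity without partners** — connected components are counted
  before and after removing all binding-partner gene nodes; connectivity is
  "intact" iff the component count does not grow and no class node becomes
  isolated. In a bipartite map a class with ≥ 1 direct-hit member can never
  be disconnected by partner removal; this is asserted as a property test.

## Overlap validation

Per category (direct hits, binding partners) the report counts matches to
each annotation source, their intersection, and the inclusion–exclusion
union, with percentages rounded **half-up to two decimals**. Half-up is the
only convention consistent with the published percentages this arithmetic
reconstructs (40/166 → 24.10, 33/78 → 42.31); note that under it
23/78 renders as 29.49.

The null draws R (default 100) gene lists uniformly without replacement
from the background, size-matched to the category under test, and computes
each list's union-overlap percent through the same code path as the
observed report. The empirical p-value uses the +1/(R+1) correction, so it
is never zero. The expected per-list overlap is the hypergeometric mean
100·A/N for a union-annotation set of size A, which the tests verify.

## Synthetic data generator

The generator emulates the statistical structure of the study's inputs, not
their content:

| Parameter | Default | Rationale |
|---|---|---|
| fly / mouse / human universe | 14,000 / 15,000 / 15,000 genes | genome-scale RNAi screen convention for the fly; mammalian universes sized to absorb ortholog targets |
| hits / lethals | 580 / 300 | the screen scale the analysis operates at |
| one-to-one / many-to-many / unmapped fractions | 0.6 / 0.1 / 0.3 | ~70% of hits map to a mammalian ortholog, the reported scale; remainder one-to-many |
| interaction mean degree | 0.15 | sparse yeast-2-hybrid coverage: ~80 first-degree partners for 580 hits |
| sets per collection / planted / factor | 200 / 10 / 5 | a detectable but not trivial planted signal |
| set sizes | 30–80 genes | typical pathway-size range |
| annotation base / hit rate (per source) | 0.015 / 0.22 | union background density ≈ 3% (1−0.985²) and union map-gene overlap ≈ 39% (1−0.78²), the scale of the published overlap table |

Mechanisms, chosen so the analytic oracles in the tests are exact:

- **Universe** — fly genes are partitioned into the four topology classes;
  each mapped fly gene maps with the same topology into both mammalian
  namespaces; many-to-many blocks are 2×2. Every mapping edge is attributed
  to ≥ 1 of four simulated prediction sources (one primary chosen uniformly
  plus each other source with probability 0.3), so the per-source tables'
  union realizes the requested topology.
- **Interactions** — Erdős–Rényi with edge probability mean_degree/(n−1):
  the simplest null adequate for testing first-degree expansion; no degree
  heterogeneity is modeled.
- **Planted sets** — a planted set of size K draws its hit-member count as
  Binomial(K, min(1, f·H/N)) and fills both strata uniformly without
  replacement, making E[overlap] exactly K·f·H/N below saturation. A
  plain weighted-without-replacement scheme would make this expectation
  only approximate; the stratified form keeps the oracle closed-form. At
  f = 1 the construction is statistically indistinguishable from uniform
  sampling (verified by KS test).
- **Annotations** — independent Bernoulli per gene and per source, at the
  hit rate for designated map genes and the base rate otherwise. Because
  the planted annotation signal targets the *assembled map's* genes, the
  pipeline generates annotation inputs at the validate stage (after map
  assembly) when simulating; all other inputs are written up front.

What the generator does **not** emulate: real pathway topology or overlap
structure between gene sets, degree-heterogeneous (scale-free) interaction
networks, correlated annotation sources, ascertainment bias in disease
databases, or symbol-level identifier noise. Passing tests therefore show
the pipeline's arithmetic, calibration and power under a clean generative
model — not that any particular biological claim holds on real data.

## Determinism and provenance

One master seed fans out to per-stage child seeds via SHA-256 of
`"<seed>|<stage labels>"` (top 31 bits), so stages can be regenerated
independently and identical configs reproduce byte-identical outputs.
Every output file carries a `# painmap <version> / config <hash> / seed`
header; readers skip `#` lines (strip the header before feeding the GMT
files to third-party tools). The run manifest records per-stage status,
counts and SHA-256 checksums of all outputs; the config hash covers the
scientific parameters and excludes the output directory.

## Problem sizes in the test suite

The statistical checks run at the study conditions above (N = 14,000,
n = 580, 200 sets; 200 calibration replicates, 50 recovery replicates,
100-list nulls × 50 seeds). The end-to-end pipeline fixture in the unit
tests uses a reduced universe (2,000 fly genes, 150 hits) purely to keep
the suite responsive; all numeric tolerances are stated in the tests
themselves (3 SE for analytic expectations, binomial 99% bounds for rates,
10⁻¹² for the enumeration sweep).

## Known limitations

- The hit-representation and connectivity claims of the original analysis
  are reproducible only with the original supplementary class membership,
  which is not redistributed here; they are property-checked on
  constructed fixtures instead.
- The union-merge of orthology sources has no confidence weighting; a
  spurious mapping in any single source propagates (mitigated by
  `min_sources`).
- Enrichment treats gene sets as unstructured; no GSEA-style ranked
  statistics, no inter-set correlation modeling.
- The discrete one-sided test is conservative at small expected overlaps;
  empirical significant fractions sit below nominal alpha by design of the
  statistic, not by error (see Enrichment above).
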