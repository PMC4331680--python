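# Methods

## Network model

A regulatory network is a signed directed multigraph. Node identifiers are
upper-cased gene/compound/miRNA symbols and compared case-insensitively,
because pathway sources mix cases for the same symbol and the crosstalk
computation intersects node sets by name. Edges carry a sign
(+1 activation/expression, −1 inhibition/repression, 0 unknown or
compound-mediated), an interaction class (PPrel, GErel, PCrel, PTM, other)
and an optional mechanism tag. At most one edge exists per ordered
(source, target, sign) triple; an ordered pair with edges of *conflicting*
sign keeps both — sign is part of edge identity — and the pair is flagged
ambiguous. Self-edges are legal and encode auto-regulation. Dense adjacency
views use an explicit boolean presence matrix rather than an "infinity for
non-regulation" sentinel; the semantics are identical and the arithmetic
safer.

## KGML mapping

Only `entry`, `relation` and `subtype` elements are consumed; `reaction`
(metabolic) elements are ignored — the targets are signalling and cancer
maps. Subtype mapping: activation/expression → +1, inhibition/repression
→ −1 (expression/repression force class GErel);
phosphorylation-family subtypes set class PTM and record the mechanism,
keeping the accompanying activation/inhibition sign; a `compound` subtype
yields a sign-0 PCrel edge between the two protein endpoints with the
compound recorded in the mechanism (the protein–protein shortcut is the
analysed edge; a compound becomes a node only when it has relations of its
own). Relations without subtypes, and unknown subtypes, are kept at sign 0
and flagged rather than silently dropped. The first display label of an
entry is its canonical id, the rest become aliases. Group entries are
expanded: each member inherits every relation incident to the group.

## Motif definitions and their edge cases

* **FFL.** The canonical pattern x→y, y→z, x→z, with reverse edges
  neither required nor forbidden; distinct role assignments over the same
  node set are distinct instances. This is the form every named pathway
  example takes (e.g. PI3K/PDPK1/AKT3). An alternative reading —
  a fully bidirectional triangle — is retained behind
  `ffl_style="bidirectional"` for fidelity experiments, since procedural
  descriptions of adjacency-matrix FFL scans sometimes state that variant.
  Coherence compares sign(x→z) with sign(x→y)·sign(y→z); any 0 or
  conflicting constituent sign yields `ambiguous`.
* **Bi-fan.** All four r→t edges present, regulator pair unconnected in
  either direction, regulators disjoint from targets. Target–target edges
  are *not* excluded by default (`bifan_exclude_target_edges` exists
  because the convention is genuinely open). Every 2×2 combination is an
  instance; no biclique maximalisation. On a complete bipartite r×t
  digraph the count is therefore C(r,2)·C(t,2).
* **SIM.** A master whose out-neighbour set (self excluded) has
  ≥ `sim_min_targets` members; the instance carries the full (maximal)
  target set, and no exclusivity is imposed on the targets. "Multiple"
  downstream genes is undefined in the literature this follows; the
  default is 3 (2 makes SIMs near-ubiquitous) and is configurable.
* **ARL/FBL** are independent inventories: an FBL whose member also
  self-loops is still an FBL.
* Instance output is sorted by (type, node tuple), so identical inputs
  give identical inventories.

## CMS merging and topology

Two instances couple when their node sets intersect. Merging is computed
as connected components of the instance-overlap graph — the same fixpoint
as iteratively merging overlapping structures, but order-independent and
near-linear; tests verify equivalence against a union-find oracle under
instance-order permutation. "Meaningfulness" filters are not applied: any
shared node merges. The six-type pair table counts unordered instance
pairs sharing ≥ 1 node, restricted to FBL/FFL/bi-fan combinations, each
pair counted once regardless of how many nodes are shared; ARL and SIM
join merged structures but not this table.

Topology is computed on the undirected simple projection of a structure's
constituent motif edges (self-edges dropped), for the **largest** merged
structure per network (ties broken by structure id): the centrality
definitions used are degree-based and undirected, and the largest
connected cluster is the stated scope of the size parameter. Betweenness
is the unnormalised sum over unordered pairs with endpoints excluded
(delegated to networkx; an independent BFS path-counting oracle guards it
in tests). The bridging coefficient BCO(i) = (1/d(i)) / Σ_{j∈N(i)} 1/d(j)
is implemented here; isolated nodes return 0 with a warning. Closed forms
used as test anchors: on a k-leaf star BCO(centre) = 1/k², BCO(leaf) = k;
a path interior node has BCO = 1/4 and BC = 1. Group medians use the
mean-of-central-pair convention for even counts; γ = β/α is undefined
(reported NA) where α = 0.

The six-network cancer reference table bundled in
`regmotifs.reference` reproduces medians size 13, max degree 5.5,
BRC 0.0376 and DC 0.2415 (printing as 0.242 at three decimals). The
corresponding published STN medians are not internally consistent with
their own per-network values and are therefore not asserted anywhere.

## Overlays and the TMMN

miRNA identifiers are matched case-insensitively with the `hsa-` species
prefix stripped, while the first-seen spelling is preserved for display;
gene role conflicts resolve by precedence OCG > TSG > cancer-related with
a warning. For a motif type T, a miRNA is **inter**-counted when its
targets hit ≥ 2 distinct instances of T and **intra**-counted when it
targets ≥ 2 member genes of one instance; the counts are deliberately
non-exclusive, and the reported total counts miRNAs touching any motif
gene (not any network gene). The TMMN gene layer is the union of the
supplied instances' (or CMS structures') nodes and constituent edges;
miRNAs enter only if they target a gene-layer node, TFs only if they
regulate an included miRNA — so across layers the graph is acyclic by
construction while gene→gene edges may cycle.

## Crosstalk

Motif node sets include all five motif types by default. The Jaccard
denominator is the union cardinality |A|+|B|−|A∩B|; JI of two empty sets
is defined as 0 with a warning. The matrix is group-2 rows × group-1
columns with a first-occurrence argmax.

## Synthetic data

`random_signed_digraph` is a signed Erdős–Rényi digraph (edge probability
p per ordered pair, activation probability `sign_p`, default 0.8 — curated
signalling maps are predominantly activating). `plant_motifs` places each
requested instance on its own fresh node group; with background p = 0 the
finders recover exactly the ground truth (at the SIM threshold the spec
was planted for). Background edges are sampled over all remaining ordered
pairs *except* those that would mutate a planted instance: self-pairs,
pairs inside a planted bi-fan's regulator pair, and out-edges from planted
SIM masters (whose instances are maximal target sets). This makes the
planted inventory a guaranteed subset of the found inventory at any
background density — a property of the generator's construction, used
throughout the recovery tests. The default background density 0.03–0.05
keeps generated networks in the sparse regime typical of curated pathway
maps (mean degree ~1–2). The demonstration collection draws each
network's genes from a shared 60-symbol universe so motif node sets
overlap partially across networks, which is what the crosstalk matrix is
meant to measure. What the generator does **not** emulate: scale-free
degree structure, correlated motif placement, database-specific
identifier noise, or biased sign composition per interaction class —
passing tests show algorithmic correctness on the stated graph model, not
fidelity to any particular curated pathway release.

The exhaustive enumerator in `regmotifs.synthetic` applies each motif
definition literally over all node tuples of the relevant arity; it
shares no code path with the production finders and anchors the
oracle-equivalence tests (random digraphs up to n = 15 across edge
densities 0.05–0.3).

## Pipeline conventions

All CLI outputs are plain TSV/GraphML/SIF written with sorted, stable
ordering and `\n` newlines, so a fixed manifest and configuration
produce byte-identical output trees (tested). Gene-set enrichment and
literature mining depend on external web services; the pipeline instead
exports the per-structure gene lists one would submit to them.

## Known limitations

* No statistical over-representation testing against degree-preserving
  null models (exact enumeration reports what is there, with identities).
* No weighted or probabilistic edges; no motif sizes beyond the five
  types; no dynamical (ODE) analysis of motif behaviour.
* Edge-list TSV round-trips are byte-identical for canonically formatted
  files; the reader is deliberately lenient about sign spelling ("1" vs
  "+1").
* Betweenness on disconnected projections follows the component-wise
  convention of the underlying library (pairs in other components
  contribute nothing).
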