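# regmotifs

Motif analysis for signed directed regulatory networks: exact enumeration of
the five classic network motifs, merging of overlapping instances into
coupled motif structures, topological scoring, TF–miRNA–motif overlay
networks, and Jaccard-index crosstalk between network collections.

## The problem

Curated pathway maps — KEGG cancer pathways, signal transduction networks
(STNs) such as MAPK or PI3K-Akt — are signed digraphs: nodes are genes,
compounds and receptors, edges are activating (+1) or inhibiting (−1)
regulatory relations. Local wiring patterns in these graphs carry function:

* **ARL** — auto-regulation loop, a gene regulating itself;
* **FBL** — feedback loop, two genes regulating each other;
* **FFL** — feed-forward loop, x→y, y→z plus the direct x→z; *coherent*
  when sign(x→z) = sign(x→y)·sign(y→z), *incoherent* otherwise;
* **bi-fan** — two mutually unconnected regulators driving the same two
  targets (a 2×2 directed biclique);
* **SIM** — single-input module, one master regulating ≥ k downstream genes.

Unlike sampling-based motif tools that report only over-representation
statistics, `regmotifs` enumerates every instance *with node identities*,
which is what downstream biology needs. Instances sharing genes are merged
(transitively) into **coupled motif structures (CMS)**, characterised by
size, maximum degree, mean degree centrality DC(i) = d(i)/(N−1) and mean
bridging centrality BRC(i) = BC(i)·BCO(i), where BC is unnormalised
betweenness and BCO(i) = (1/d(i)) / Σ_{j∈N(i)} 1/d(j). Two-group contrasts
use per-parameter medians α, β and their ratio γ = β/α. Overlaying
experimentally validated TF→miRNA and miRNA→target tables produces a
three-layer **TF–miRNA–motif network (TMMN)** with oncogene / tumour
suppressor labels, and the coupling between two network collections is
quantified on their motif gene sets with the Jaccard index
JI(A,B) = |A∩B| / (|A|+|B|−|A∩B|).

## Worked example

```python
from regmotifs import MotifSearchConfig, build_network, find_all_motifs

net = build_network("demo", [
    ("EGF", "EGFR", 1), ("EGF", "ERBB2", 1),
    ("TGFA", "EGFR", 1), ("TGFA", "ERBB2", 1),
    ("PIK3CA", "PDPK1", 1), ("PDPK1", "AKT3", 1), ("PIK3CA", "AKT3", 1),
])
inv = find_all_motifs(net, MotifSearchConfig(sim_min_targets=2))
print(inv.summary_row())
for inst in inv.instances:
    print(inst.motif_type, inst.nodes, inst.coherence)
```

prints

```
(0, 0, 1, 1, 3)
FFL ('PIK3CA', 'PDPK1', 'AKT3') coherent
BIFAN ('EGF', 'TGFA', 'EGFR', 'ERBB2') n/a
SIM ('EGF', 'EGFR', 'ERBB2') n/a
SIM ('PIK3CA', 'AKT3', 'PDPK1') n/a
SIM ('TGFA', 'EGFR', 'ERBB2') n/a
```

— one coherent feed-forward loop (PIK3CA drives AKT3 directly and through
PDPK1, all activating), one bi-fan (EGF and TGFA, unconnected, both drive
EGFR and ERBB2), and at SIM threshold 2 each multi-target regulator also
counts as a single-input module. The `examples/` directory holds one short
script per capability (enumeration, CMS + topology, KGML parsing, TMMN
overlay, crosstalk); each prints its numbers and what they mean.

A thin CLI mirrors the workflow over manifests of KGML/edge-list files:

```bash
regmotifs fixtures demo/            # seeded synthetic collection
regmotifs motifs demo/manifest.tsv -o out/motifs
regmotifs cms demo/manifest.tsv -o out/cms
regmotifs crosstalk demo/manifest.tsv -o out/xt
```

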