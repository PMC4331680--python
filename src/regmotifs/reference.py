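"""Published per-network topology summaries used as regression inputs.

These are the reported size / maximum degree / bridging centrality /
degree centrality values of the largest coupled motif structure in six
KEGG cancer pathway maps (acute myeloid leukemia, glioma, melanoma,
non-small cell lung cancer, prostate cancer, renal cell carcinoma).
They serve as fixed inputs to the two-group median comparison: the
cancer-group medians recomputed from them are a stable, desk-checkable
regression point (size 13, max degree 5.5, BRC 0.0376, DC ~0.242).
"""

from __future__ import annotations

from .topology import TopologyReport

#: largest-CMS topology of six KEGG cancer pathway maps (reported values)
CANCER_CMS_TOPOLOGY: tuple[TopologyReport, ...] = (
    TopologyReport("AML", size=22, max_degree=7, brc=0.310, dc=0.116),
    TopologyReport("Glioma", size=8, max_degree=4, brc=0.0443, dc=0.393),
    TopologyReport("Melanoma", size=4, max_degree=2, brc=0.0678, dc=0.400),
    TopologyReport("NSCLC", size=18, max_degree=6, brc=0.0309, dc=0.150),
    TopologyReport("PC", size=18, max_degree=11, brc=0.0137, dc=0.111),
    TopologyReport("RCC", size=6, max_degree=5, brc=0.0075, dc=0.333),
)
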