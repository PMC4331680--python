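"""Parse a KGML pathway document into a signed regulatory network.

Writes a minimal KGML fixture to a temporary file, parses it back and
prints the signed, classed edge list -- the same call works on real
KEGG pathway XML files supplied by the user.
"""

import tempfile
from pathlib import Path

from regmotifs import parse_kgml

KGML = """<pathway name="path:demo" title="demo pathway">
  <entry id="1" type="gene"><graphics name="EGF"/></entry>
  <entry id="2" type="gene"><graphics name="EGFR, ERBB1"/></entry>
  <entry id="3" type="gene"><graphics name="PIK3CA"/></entry>
  <entry id="4" type="gene"><graphics name="PTEN"/></entry>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="2" entry2="3" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
    <subtype name="phosphorylation" value="+p"/>
  </relation>
  <relation entry1="4" entry2="3" type="GErel">
    <subtype name="repression" value="--|"/>
  </relation>
</pathway>
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo.xml"
    path.write_text(KGML, encoding="utf-8")
    net = parse_kgml(path)

print(f"network {net.name!r}: {len(net)} nodes, {len(net.edges)} edges")
for e in net.edges:
    mech = f" ({e.mechanism})" if e.mechanism else ""
    print(f"  {e.source} -> {e.target}  sign={e.sign:+d} "
          f"class={e.interaction_class}{mech}")
print("EGFR aliases:", net.nodes["EGFR"].aliases)
# activation maps to +1, repression to -1; the phosphorylating relation
# is classed PTM with its mechanism recorded; the second graphics label
# (ERBB1) is kept as an alias of the canonical first symbol.
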