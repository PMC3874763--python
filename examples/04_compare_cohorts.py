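"""Overlay the hypoxia-response sub-networks of two cell lines.

Each cohort's sub-network is the union of shortest paths connecting its
significant differential pairs. Overlaying them classifies metabolites
as cohort-specific or shared — shared nodes mark responses to low
oxygen that are conserved across cell lines.
"""

import networkx as nx

from metcorrnet import compare_networks, export_network

# sub-network of cohort A: glucose/malate axis rewiring
sub_a = nx.Graph()
for a, b in [("glucose", "pyruvate"), ("pyruvate", "malate"),
             ("malate", "2-oxoglutarate"), ("2-oxoglutarate", "glutamate")]:
    sub_a.add_edge(a, b, reactions=set())

# sub-network of cohort B: hydroxyproline hub
sub_b = nx.Graph()
for a, b in [("4-hydroxyproline", "glutamate"), ("glutamate", "2-oxoglutarate"),
             ("2-oxoglutarate", "malate"), ("malate", "aspartate")]:
    sub_b.add_edge(a, b, reactions=set())

comp = compare_networks(sub_a, sub_b, label_a="MDA-MB-231", label_b="HCT116")
counts = comp.node_counts()
print(f"node origin counts: {counts}")
print(f"shared metabolites: {sorted(comp.nodes_with_origin('shared'))}")
print(f"{comp.label_a} only:  {sorted(comp.nodes_with_origin('A_only'))}")
print(f"{comp.label_b} only:  {sorted(comp.nodes_with_origin('B_only'))}")

export_network(comp, "comparison.graphml")
print("\nwrote comparison.graphml (node 'origin' attribute = white/black/grey classes)")
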