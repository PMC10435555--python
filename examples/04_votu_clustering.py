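"""Cluster elements into viral OTUs with similarity thresholds + MCL.

The toy panel's six retroviruses fall below the 95%-identity threshold and
form six singleton vOTUs; adding two near-identical copies of one genome
merges them into a single vOTU.
"""
from ervi import synthetic, votu

panel = synthetic.make_reference_panel(seed=0)
elements = {g.genome_id: g.seq for g in panel.genomes.values()}
elements["toyRV1_copy"] = panel.genomes["toyRV1"].seq

edges = votu.pairwise_similarity(elements)
for edge in edges:
    print(f"edge {edge.element_a} -- {edge.element_b}: "
          f"coverage {edge.coverage:.1f}%, identity {edge.identity:.1f}%")

partition = votu.mcl_cluster(edges, list(elements), inflation=1.4)
print(f"\n{len(partition.clusters)} vOTUs over {len(elements)} elements:")
for i, cluster in enumerate(partition.clusters):
    print(f"  vOTU{i + 1}: {sorted(cluster)}")
print()
print("Edges need >=80% coverage of the shorter sequence at >=95% identity;")
print("Markov clustering (inflation 1.4) then partitions the graph.")
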