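"""Generate a synthetic multi-assembly dataset with known ground truth.

One reference plus two alternate assemblies carrying spiked insertions;
the truth manifest records every spike, N-gap and true SV so downstream
stages can be scored exactly.
"""

from pangnovel import generate_assembly_set

assemblies, graph, manifest = generate_assembly_set(
    seed=1,
    reference_spec={"n_sequences": 1, "length": 200_000},
    alt_specs=[
        {"name": "alt1", "n_insertions": 5, "length_range": (300, 1500)},
        {"name": "alt2", "n_insertions": 5, "length_range": (300, 1500),
         "sharing": [["alt1", "alt2"], ["alt2"]]},  # alternate shared/private
    ],
)

print(f"assemblies: { {n: sum(map(len, s.values())) for n, s in assemblies.items()} }")
print(f"graph: {len(graph.nodes)} nodes, {len(graph.paths)} paths")
print(f"spiked insertions (per carrying assembly): {len(manifest.spiked_insertions)}")
print(f"true SVs in callset truth: {len(manifest.true_svs)}")
shared = [s for s in manifest.spiked_insertions if len(s.sharing) > 1]
print(f"spike records on shared nodes: {len(shared)}")
# Assembly totals exceed the reference by exactly the spiked bases; a
# shared insertion appears once per carrying assembly but sits on a
# single graph node.
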