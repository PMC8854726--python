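"""Shared fixtures: toy graphs and an engineered synthetic dataset.

The engineered dataset has one 1 Mb reference sequence, four alternate
assemblies and 40 spiked insertions: per alternate, four clean spikes
(retainable under every rule; one of alt1's is shared with alt2), one
short, one telomeric, one gap-flanking, one repeat-enriched, and one
pair of 40 bp spikes 5 bp apart whose merged segment falls below the
novel-fraction bound — each engineered to violate exactly one retention
rule.
"""

from __future__ import annotations

import pytest

from pangnovel import PipelineConfig, generate_assembly_set
from pangnovel.graph import GenomeGraph


@pytest.fixture
def toy_graph() -> GenomeGraph:
    """ref: A->B->C; alt1: A->D->C; alt2: A->D->E->C."""
    g = GenomeGraph()
    g.nodes = {
        "A": "ACGTACGTAC",  # 10 bp
        "B": "TTTTT",  # 5 bp
        "C": "GGGGGGGGGG",  # 10 bp
        "D": "CCCCC",  # 5 bp
        "E": "AAAA",  # 4 bp
    }
    g.paths = {
        "ref#chr1": [("A", "+"), ("B", "+"), ("C", "+")],
        "alt1#chr1": [("A", "+"), ("D", "+"), ("C", "+")],
        "alt2#chr1": [("A", "+"), ("D", "+"), ("E", "+"), ("C", "+")],
    }
    for steps in g.paths.values():
        for (a, ao), (b, bo) in zip(steps, steps[1:]):
            g.edges.add((a, ao, b, bo))
    return g


ENGINEERED_SEED = 11
REF_LEN = 1_000_000
GAP = (500_000, 500_200)


def engineered_events() -> dict[str, list[dict]]:
    """Spike specifications keyed by category."""
    alts = [f"alt{i}" for i in range(1, 5)]
    cats: dict[str, list[dict]] = {
        "clean": [], "short": [], "telomeric": [], "gap_flank": [],
        "repetitive": [], "haplotype": [],
    }
    for k, alt in enumerate(alts):
        for j in range(4):
            sharing = ["alt1", "alt2"] if (k == 0 and j == 0) else [alt]
            cats["clean"].append(
                {"alt": alt, "position": 100_000 + k * 1_000 + j * 20_000,
                 "length": 500 + 100 * j, "masked_fraction": 0.3, "sharing": sharing}
            )
        cats["short"].append(
            {"alt": alt, "position": 220_000 + k * 1_000, "length": 40,
             "masked_fraction": 0.0, "sharing": [alt]}
        )
        cats["telomeric"].append(
            {"alt": alt, "position": 5_000 + k * 500, "length": 800,
             "masked_fraction": 0.3, "sharing": [alt]}
        )
        cats["gap_flank"].append(
            {"alt": alt, "position": 500_250 + k * 150, "length": 800,
             "masked_fraction": 0.3, "sharing": [alt]}
        )
        cats["repetitive"].append(
            {"alt": alt, "position": 300_000 + k * 1_000, "length": 1_000,
             "masked_fraction": 0.95, "sharing": [alt]}
        )
        base = 400_000 + k * 1_000
        for pos in (base, base + 5):
            cats["haplotype"].append(
                {"alt": alt, "position": pos, "length": 40,
                 "masked_fraction": 0.0, "sharing": [alt]}
            )
    return cats


def build_engineered_dataset():
    cats = engineered_events()
    alts = [f"alt{i}" for i in range(1, 5)]
    per_alt: dict[str, list[dict]] = {a: [] for a in alts}
    for events in cats.values():
        for ev in events:
            per_alt[ev["alt"]].append(
                {"position": ev["position"], "length": ev["length"],
                 "masked_fraction": ev["masked_fraction"], "sharing": ev["sharing"]}
            )
    alt_specs = [{"name": a, "insertions": per_alt[a]} for a in alts]
    assemblies, graph, manifest = generate_assembly_set(
        seed=ENGINEERED_SEED,
        reference_spec={"lengths": [REF_LEN], "gaps": [[GAP]]},
        alt_specs=alt_specs,
    )
    # the telomere rule's chromosome-scale gate is lowered to suit the
    # 1 Mb fixture sequence; every other threshold is the default
    config = PipelineConfig(reference_name="ref", telomere_min_seq=400_000)
    return assemblies, graph, manifest, config, cats


@pytest.fixture(scope="session")
def engineered_dataset():
    return build_engineered_dataset()
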