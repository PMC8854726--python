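"""Genome graph reading and non-reference sequence extraction.

A genome graph embeds a set of assemblies as named paths over shared
sequence nodes: sequence common to several assemblies lies on shared
nodes, divergent sequence forms alternative nodes.  Non-reference
sequence is, by definition, the bases sitting on nodes that no path of
the designated reference assembly traverses.  This module parses the
GFA-1 dialect used here (S records with sequence, L records with 0M
overlap, P records named ``<assembly>#<sequence-id>``), identifies the
non-reference nodes, screens out nodes containing N, and projects the
surviving nodes onto alternate-assembly coordinates as labelled
segments.

Coordinates are 0-based half-open.  A node counts as "present in the
reference" if any reference path traverses it in either orientation:
what matters for sequence novelty is content, not strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

from .intervals import intervals_overlap

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement preserving soft-masking case."""
    return seq.translate(_COMP)[::-1]


class GFAError(ValueError):
    """Malformed or inconsistent GFA input."""


@dataclass
class GenomeGraph:
    """Sequence graph with named per-assembly paths.

    ``paths`` maps a path name (``assembly#sequence``) to an ordered list
    of (node id, orientation) steps, orientation one of ``+``/``-``.
    """

    nodes: dict[str, str] = field(default_factory=dict)
    edges: set[tuple[str, str, str, str]] = field(default_factory=set)
    paths: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def path_sequence(self, path_name: str) -> str:
        """Reconstruct the assembly sequence spelled by a path."""
        steps = self.paths[path_name]
        parts = []
        for node, orient in steps:
            seq = self.nodes[node]
            parts.append(seq if orient == "+" else revcomp(seq))
        return "".join(parts)

    def assembly_names(self) -> set[str]:
        return {split_path_name(p)[0] for p in self.paths}

    def assembly_paths(self, assembly: str) -> list[str]:
        """Path names belonging to one assembly, sorted by sequence id."""
        prefix = assembly + "#"
        return sorted(p for p in self.paths if p.startswith(prefix))


def split_path_name(name: str) -> tuple[str, str]:
    """Split ``assembly#sequence`` into its two components."""
    if "#" not in name:
        return name, name
    assembly, seq_id = name.split("#", 1)
    return assembly, seq_id


def read_graph(stream: TextIO | Iterable[str]) -> GenomeGraph:
    """Parse GFA-1 text into a :class:`GenomeGraph`.

    Two-pass: S records are collected first so P/L records may appear in
    any order.  A P record citing an undefined node, a duplicate node id,
    or a path revisiting a node (a cycle) raise :class:`GFAError` naming
    the offender.
    """
    lines = [ln.rstrip("\n") for ln in stream]
    graph = GenomeGraph()
    for i, line in enumerate(lines, 1):
        if not line or line[0] != "S":
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise GFAError(f"line {i}: S record needs id and sequence")
        _, node_id, seq = fields[:3]
        if node_id in graph.nodes:
            raise GFAError(f"line {i}: duplicate node id {node_id!r}")
        if not seq or not set(seq) <= set("ACGTNacgtn"):
            raise GFAError(f"line {i}: node {node_id!r} has invalid sequence")
        graph.nodes[node_id] = seq
    for i, line in enumerate(lines, 1):
        if not line:
            continue
        tag = line[0]
        fields = line.split("\t")
        if tag == "L":
            if len(fields) < 5:
                raise GFAError(f"line {i}: truncated L record")
            a, ao, b, bo = fields[1:5]
            for n in (a, b):
                if n not in graph.nodes:
                    raise GFAError(f"line {i}: L record references unknown node {n!r}")
            graph.edges.add((a, ao, b, bo))
        elif tag == "P":
            if len(fields) < 3:
                raise GFAError(f"line {i}: truncated P record")
            name, steps_field = fields[1], fields[2]
            steps: list[tuple[str, str]] = []
            seen: set[str] = set()
            for step in steps_field.split(","):
                node_id, orient = step[:-1], step[-1]
                if orient not in "+-":
                    raise GFAError(f"line {i}: bad path step {step!r}")
                if node_id not in graph.nodes:
                    raise GFAError(
                        f"line {i}: path {name!r} references unknown node {node_id!r}"
                    )
                if node_id in seen:
                    raise GFAError(
                        f"line {i}: path {name!r} revisits node {node_id!r} (cyclic paths unsupported)"
                    )
                seen.add(node_id)
                steps.append((node_id, orient))
            if name in graph.paths:
                raise GFAError(f"line {i}: duplicate path name {name!r}")
            graph.paths[name] = steps
    return graph


def write_graph(graph: GenomeGraph, stream: TextIO) -> None:
    """Write GFA-1 (S then L then P records, 0M overlaps)."""
    stream.write("H\tVN:Z:1.0\n")
    for node_id in sorted(graph.nodes, key=_node_sort_key):
        stream.write(f"S\t{node_id}\t{graph.nodes[node_id]}\n")
    for a, ao, b, bo in sorted(graph.edges):
        stream.write(f"L\t{a}\t{ao}\t{b}\t{bo}\t0M\n")
    for name in sorted(graph.paths):
        steps = ",".join(f"{n}{o}" for n, o in graph.paths[name])
        overlaps = ",".join("0M" for _ in graph.paths[name][1:]) or "*"
        stream.write(f"P\t{name}\t{steps}\t{overlaps}\n")


def _node_sort_key(node_id: str):
    # numeric suffix sort so s2 < s10
    digits = "".join(c for c in node_id if c.isdigit())
    return (node_id.rstrip("0123456789"), int(digits) if digits else -1)


@dataclass(frozen=True)
class NonRefSegment:
    """A run of non-reference nodes projected onto one assembly's coordinates.

    ``sources`` is the set of assemblies whose paths traverse the
    underlying nodes; ``nonref_fraction`` is the fraction of bases in
    [start, end) coming from non-reference nodes (1.0 before merging,
    possibly lower after small reference gaps are bridged).  ``nodes``
    records the underlying node run, the canonical identity of the
    segment across assemblies.
    """

    assembly: str
    seq_id: str
    start: int
    end: int
    sources: frozenset[str]
    nonref_fraction: float = 1.0
    nodes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty segment [{self.start}, {self.end})")
        if not 0.0 <= self.nonref_fraction <= 1.0:
            raise ValueError("nonref_fraction outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


def nonreference_nodes(graph: GenomeGraph, reference_assembly: str) -> set[str]:
    """Node ids traversed by no path of the reference assembly.

    Orientation is ignored: a node the reference walks only in reverse
    still contributes its sequence content and is excluded.
    """
    ref_paths = graph.assembly_paths(reference_assembly)
    if not ref_paths:
        raise ValueError(f"no path found for reference assembly {reference_assembly!r}")
    on_ref = {node for p in ref_paths for node, _ in graph.paths[p]}
    return set(graph.nodes) - on_ref


def screen_n_nodes(node_ids: Iterable[str], graph: GenomeGraph) -> set[str]:
    """Drop nodes whose sequence contains an N (case-insensitive)."""
    out = set()
    for nid in node_ids:
        if nid not in graph.nodes:
            raise KeyError(f"unknown node id {nid!r}")
        if "N" not in graph.nodes[nid].upper():
            out.add(nid)
    return out


def node_source_map(graph: GenomeGraph) -> dict[str, frozenset[str]]:
    """node id -> set of assemblies whose paths traverse it."""
    sources: dict[str, set[str]] = {nid: set() for nid in graph.nodes}
    for name, steps in graph.paths.items():
        assembly, _ = split_path_name(name)
        for node, _ in steps:
            sources[node].add(assembly)
    return {nid: frozenset(s) for nid, s in sources.items()}


def project_segments(
    graph: GenomeGraph, node_ids: set[str], assembly: str
) -> list[NonRefSegment]:
    """Project selected nodes onto one assembly as maximal-run segments.

    Walking each path of the assembly with cumulative offsets, every
    maximal run of consecutive selected nodes becomes one segment on the
    forward strand of the owning sequence; its sources are the union of
    assemblies traversing the run's nodes.
    """
    paths = graph.assembly_paths(assembly)
    if not paths:
        raise ValueError(f"assembly {assembly!r} has no path in the graph")
    src_map = node_source_map(graph)
    segments: list[NonRefSegment] = []
    for name in paths:
        _, seq_id = split_path_name(name)
        offset = 0
        run_start = None
        run_nodes: list[str] = []
        for node, _orient in graph.paths[name] + [(None, "+")]:
            if node is not None and node in node_ids:
                if run_start is None:
                    run_start = offset
                run_nodes.append(node)
            else:
                if run_start is not None:
                    sources = frozenset().union(*(src_map[n] for n in run_nodes))
                    segments.append(
                        NonRefSegment(
                            assembly=assembly,
                            seq_id=seq_id,
                            start=run_start,
                            end=offset,
                            sources=sources,
                            nonref_fraction=1.0,
                            nodes=tuple(run_nodes),
                        )
                    )
                    run_start = None
                    run_nodes = []
            if node is not None:
                offset += len(graph.nodes[node])
    segments.sort(key=lambda s: (s.seq_id, s.start))
    return segments


def exclude_regions(
    segments: Iterable[NonRefSegment],
    exclusions: Mapping[str, Iterable[tuple[int, int]]],
) -> list[NonRefSegment]:
    """Remove whole segments overlapping any exclusion interval by ≥1 bp.

    ``exclusions`` maps sequence id to 0-based half-open intervals
    (candidate misassembled regions); segments are removed entire, never
    truncated.
    """
    out = []
    for seg in segments:
        excl = exclusions.get(seg.seq_id, ())
        if any(intervals_overlap((seg.start, seg.end), (int(s), int(e))) for s, e in excl):
            continue
        out.append(seg)
    return out
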