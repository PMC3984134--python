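"""Haplotype-level analysis: intra-genomic variant inference and networks.

The multicopy rDNA operon carries several sequence variants per genome;
their read proportions should rise and fall together across samples.
Haplotype pairs whose within-type proportions are positively gamma-
correlated (permutation p below alpha) are linked, and connected components
of that graph are putative single-genome variant groups.

Haplotype networks use a mutation distance where every substitution counts
one and every contiguous indel run counts one (an n-base indel is a single
event), and retain all minimum-spanning-tree ties instead of choosing one
arbitrarily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._align import cigar_events
from .quantify import UndefinedGamma, gamma_permutation_p


@dataclass
class IntragenomicGroups:
    """Partition of haplotypes into putative single-genome variant groups."""

    groups: list[set[str]]
    edges: list[tuple[str, str, float, float]]  # (a, b, gamma, p)
    zero_variance: list[str] = field(default_factory=list)

    def group_of(self, haplotype_id: str) -> set[str]:
        for group in self.groups:
            if haplotype_id in group:
                return group
        raise KeyError(haplotype_id)


@dataclass
class HaplotypeNetwork:
    """Minimum-spanning network over haplotypes (all MST ties retained)."""

    graph: nx.Graph  # nodes carry total_reads and members; edges carry distance

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"a": a, "b": b, "distance": data["distance"]}
            for a, b, data in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["a", "b", "distance"])

    def write(self, edges_path, graph_path=None) -> None:
        self.edge_list().to_csv(edges_path, sep="\t", index=False)
        if graph_path is not None:
            nx.write_graphml(self.graph, graph_path)


def pairwise_distance(seq_a: str, seq_b: str) -> int:
    """Mutation count: substitution columns + contiguous indel runs.

    The global alignment is computed on the lexicographically ordered pair:
    equally optimal alignments can differ in how they spread events, so a
    canonical orientation keeps the count symmetric.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if seq_a == seq_b:
        return 0
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    substitutions, indel_runs = cigar_events(seq_a, seq_b)
    return substitutions + indel_runs


def proportion_matrix(type_percents_by_reference: pd.DataFrame) -> pd.DataFrame:
    """Within-type haplotype proportions (rows renormalised to 100)."""
    totals = type_percents_by_reference.sum(axis=1)
    return type_percents_by_reference.div(totals.replace(0, np.nan), axis=0) * 100.0


def infer_intragenomic(
    proportions: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    tolerance_r: float = 0.0,
) -> IntragenomicGroups:
    """Group haplotypes whose proportions co-vary across samples.

    ``proportions`` is a samples x haplotypes table. Every haplotype pair is
    tested with the gamma permutation test (one-sided, positive
    association); an edge is drawn iff gamma > 0 and p < alpha. Connected
    components of the resulting graph are the inferred variant groups.
    Haplotypes with no rankable variation are isolated and flagged.
    """
    if len(proportions) < 3:
        raise ValueError("need >= 3 samples to rank haplotype proportions")
    haplotypes = list(proportions.columns)
    graph = nx.Graph()
    graph.add_nodes_from(haplotypes)
    zero_variance = [
        h for h in haplotypes if np.ptp(proportions[h].fillna(0.0).to_numpy()) == 0
    ]
    edges = []
    for i, a in enumerate(haplotypes):
        for b in haplotypes[i + 1 :]:
            x = proportions[a].fillna(0.0).to_numpy()
            y = proportions[b].fillna(0.0).to_numpy()
            try:
                result = gamma_permutation_p(
                    x, y, tolerance_r=tolerance_r, n_iter=n_perm, seed=seed
                )
            except UndefinedGamma:
                continue
            edges.append((a, b, result.gamma, result.p_value))
            if result.gamma > 0 and result.p_value < alpha:
                graph.add_edge(a, b)
    groups = [set(c) for c in nx.connected_components(graph)]
    groups.sort(key=lambda g: sorted(g)[0])
    return IntragenomicGroups(groups=groups, edges=edges, zero_variance=zero_variance)


def build_network(
    haplotype_sequences: dict[str, str],
    read_totals: dict[str, int] | None = None,
) -> HaplotypeNetwork:
    """Minimum-spanning haplotype network.

    Identical sequences are collapsed into one node (reads summed, member
    ids recorded). Over the collapsed nodes, all pairwise mutation
    distances are computed and the union of all minimum spanning trees is
    kept: an edge survives iff its endpoints are not already connected by
    strictly lighter edges (the cycle criterion), so equally parsimonious
    connections are all shown.
    """
    if not haplotype_sequences:
        raise ValueError("need at least one haplotype")
    read_totals = read_totals or {}

    by_seq: dict[str, list[str]] = {}
    for hap_id in sorted(haplotype_sequences):
        by_seq.setdefault(haplotype_sequences[hap_id], []).append(hap_id)

    graph = nx.Graph()
    node_ids = {}
    for seq, members in by_seq.items():
        node = members[0]
        node_ids[seq] = node
        graph.add_node(
            node,
            total_reads=int(sum(read_totals.get(m, 0) for m in members)),
            members=",".join(members),
        )

    sequences = list(by_seq)
    complete = nx.Graph()
    complete.add_nodes_from(node_ids.values())
    for i, seq_a in enumerate(sequences):
        for seq_b in sequences[i + 1 :]:
            complete.add_edge(
                node_ids[seq_a],
                node_ids[seq_b],
                distance=pairwise_distance(seq_a, seq_b),
            )

    # union of all MSTs: keep edge (u,v,w) iff u,v are disconnected in the
    # subgraph of strictly lighter edges
    for u, v, data in complete.edges(data=True):
        w = data["distance"]
        lighter = nx.Graph(
            (a, b)
            for a, b, d in complete.edges(data=True)
            if d["distance"] < w
        )
        if u in lighter and v in lighter and nx.has_path(lighter, u, v):
            continue
        graph.add_edge(u, v, distance=w)
    return HaplotypeNetwork(graph=graph)


def groups_to_frame(groups: IntragenomicGroups) -> pd.DataFrame:
    rows = [
        {"haplotype_id": hap, "group": i + 1,
         "zero_variance": hap in groups.zero_variance}
        for i, group in enumerate(groups.groups)
        for hap in sorted(group)
    ]
    return pd.DataFrame(rows, columns=["haplotype_id", "group", "zero_variance"])
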