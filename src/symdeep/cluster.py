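"""100 %-identity read clustering and reference selection.

Reads from all samples are pooled and dereplicated at exact identity with
prefix containment (variable-length pyrosequencing reads: a shorter read
that is an exact prefix of a longer one carries no extra information).
Cluster-size histograms drive the reference cut-off: the smallest set of
cluster representatives accounting for (nearly) all reads, with a hard
floor at ``min_cluster_size`` reads per cluster so that singleton and rare
error-derived variants never become mapping references.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from ._align import cigar_events
from .preprocess import CleanRead


@dataclass
class Cluster:
    representative_id: str
    representative_bases: str
    member_read_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.member_read_ids)


@dataclass
class ClusterSizeHistogram:
    """Cumulative cluster-count and read-fraction curves by size class.

    ``clusters_at_least[s]`` is the number of clusters of size >= s and
    ``read_fraction_at_least[s]`` the fraction of all reads contained in
    them; both are non-increasing in s and the read fraction at s=1 is 1.
    """

    sizes: list[int]  # distinct cluster sizes, descending
    clusters_at_least: dict[int, int]
    read_fraction_at_least: dict[int, float]
    total_reads: int

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.clusters_at_least)
        return pd.DataFrame(
            {
                "size_class": rows,
                "clusters_at_least": [self.clusters_at_least[s] for s in rows],
                "read_fraction_at_least": [self.read_fraction_at_least[s] for s in rows],
            }
        )


@dataclass
class ReferenceSet:
    """Selected reference (haplotype) sequences."""

    references: list[tuple[str, str, int]]  # (reference_id, bases, source_cluster_size)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.references]
        if len(set(ids)) != len(ids):
            raise ValueError("reference ids must be unique")
        seqs = [r[1] for r in self.references]
        if len(set(seqs)) != len(seqs):
            raise ValueError("reference sequences must be unique")

    def __len__(self) -> int:
        return len(self.references)

    def ids(self) -> list[str]:
        return [r[0] for r in self.references]

    def cluster_size(self, reference_id: str) -> int:
        for ref_id, _, size in self.references:
            if ref_id == reference_id:
                return size
        raise KeyError(reference_id)

    def write_fasta(self, path) -> None:
        with open(path, "w") as handle:
            for ref_id, bases, size in self.references:
                handle.write(f">{ref_id} cluster_size={size}\n{bases}\n")


class EmptyReferenceSelection(Exception):
    """No cluster meets the minimum size: nothing can serve as a reference."""


def cluster_identical(clean_reads: list[CleanRead]) -> list[Cluster]:
    """Greedy exact-identity clustering with prefix containment.

    Unique sequences are visited longest-first; each founds a cluster unless
    it is an exact prefix of an already-founded representative, in which
    case it joins the earliest-founded such cluster (ties between equally
    early founders cannot occur). The representative is therefore the
    longest member; among identical longest members the lexicographically
    smallest read id is reported.
    """
    if not clean_reads:
        raise ValueError("no reads to cluster")
    by_seq: dict[str, list[str]] = {}
    for read in clean_reads:
        by_seq.setdefault(read.bases, []).append(read.read_id)

    order = sorted(by_seq, key=lambda s: (-len(s), s))
    founders: list[str] = []  # sorted lexicographically, for prefix range queries
    founded_at: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for seq in order:
        # founders having `seq` as a prefix occupy the range [seq, seq+\xff)
        lo = bisect.bisect_left(founders, seq)
        hi = bisect.bisect_right(founders, seq + "\xff")
        candidates = founders[lo:hi]
        if candidates:
            target = min(candidates, key=founded_at.__getitem__)
            members[target].extend(by_seq[seq])
        else:
            bisect.insort(founders, seq)
            founded_at[seq] = len(founded_at)
            members[seq] = list(by_seq[seq])

    clusters = []
    for seq, read_ids in members.items():
        rep_candidates = [rid for rid in by_seq[seq] if rid in set(read_ids)]
        representative_id = min(rep_candidates) if rep_candidates else min(read_ids)
        clusters.append(Cluster(representative_id, seq, read_ids))
    clusters.sort(key=lambda c: (-c.size, c.representative_id))
    return clusters


def size_histogram(clusters: list[Cluster]) -> ClusterSizeHistogram:
    """Cumulative histogram of cluster sizes (counts and read fractions)."""
    if not clusters:
        raise ValueError("no clusters")
    sizes = sorted((c.size for c in clusters), reverse=True)
    total_reads = sum(sizes)
    counts = Counter(sizes)
    distinct = sorted(counts, reverse=True)
    clusters_at_least: dict[int, int] = {}
    read_fraction_at_least: dict[int, float] = {}
    running_clusters = 0
    running_reads = 0
    for s in distinct:
        running_clusters += counts[s]
        running_reads += s * counts[s]
        clusters_at_least[s] = running_clusters
        read_fraction_at_least[s] = running_reads / total_reads
    if 1 not in clusters_at_least:
        clusters_at_least[1] = running_clusters
        read_fraction_at_least[1] = 1.0
    return ClusterSizeHistogram(distinct, clusters_at_least, read_fraction_at_least, total_reads)


def select_references(
    clusters: list[Cluster],
    histogram: ClusterSizeHistogram | None = None,
    min_cluster_size: int = 10,
    asymptote_gain: float = 0.01,
) -> ReferenceSet:
    """Pick cluster representatives as reference sequences.

    Size classes are scanned from largest to smallest; the scan stops at
    the first class whose marginal gain in total-read fraction falls below
    ``asymptote_gain`` — the cumulative read-fraction curve has reached its
    asymptote, and everything smaller is overwhelmingly recurrent
    PCR/sequencing error. When the asymptote triggers, only the admitted
    classes are kept; when it never triggers, every cluster down to
    ``min_cluster_size`` is kept (the fallback for data whose curve keeps
    climbing). In both branches clusters below ``min_cluster_size`` reads
    are never references. If no cluster reaches the floor the selection is
    empty and :class:`EmptyReferenceSelection` is raised.
    """
    if histogram is None:
        histogram = size_histogram(clusters)
    if not any(c.size >= min_cluster_size for c in clusters):
        raise EmptyReferenceSelection(
            f"no cluster has >= {min_cluster_size} reads"
        )
    counts = Counter(c.size for c in clusters)
    distinct = sorted(counts, reverse=True)
    total = histogram.total_reads

    stop_size = distinct[0]
    triggered = False
    for s in distinct[1:]:
        gain = s * counts[s] / total
        if gain < asymptote_gain:
            triggered = True
            break
        stop_size = s

    keep_floor = max(stop_size, min_cluster_size) if triggered else min_cluster_size
    selected = [c for c in clusters if c.size >= keep_floor]
    references = [
        (c.representative_id, c.representative_bases, c.size) for c in selected
    ]
    return ReferenceSet(references)


def screen_homopolymer_references(
    reference_set: ReferenceSet, size_ratio: float = 10.0
) -> tuple[ReferenceSet, list[dict]]:
    """Drop references that look like homopolymer-indel artifacts.

    A reference differing from a >= ``size_ratio``-times-larger reference by
    nothing but a single one-base indel inside a homopolymer run is a
    classic pyrosequencing over/under-call and is removed. Returns the
    screened set and a log of removals.
    """
    refs = sorted(reference_set.references, key=lambda r: -r[2])
    removed: list[dict] = []
    removed_ids: set[str] = set()
    for i, (ref_id, bases, size) in enumerate(refs):
        for larger_id, larger_bases, larger_size in refs[:i]:
            if larger_id in removed_ids or larger_size < size_ratio * size:
                continue
            if _is_single_homopolymer_indel(bases, larger_bases):
                removed.append(
                    {"reference_id": ref_id, "matches": larger_id,
                     "size": size, "larger_size": larger_size}
                )
                removed_ids.add(ref_id)
                break
    kept = [r for r in refs if r[0] not in removed_ids]
    return ReferenceSet(kept), removed


def _is_single_homopolymer_indel(a: str, b: str) -> bool:
    """True if a and b differ by exactly one 1-base indel in a homopolymer."""
    if abs(len(a) - len(b)) != 1:
        return False
    substitutions, indel_runs = cigar_events(a, b)
    if substitutions != 0 or indel_runs != 1:
        return False
    longer, shorter = (a, b) if len(a) > len(b) else (b, a)
    # locate the extra base: first position where the two diverge
    i = 0
    while i < len(shorter) and longer[i] == shorter[i]:
        i += 1
    extra = longer[i]
    neighbours = longer[max(0, i - 1) : i + 2].replace(extra, "", 1)
    return extra in neighbours


def brute_force_containment_partition(reads: list[CleanRead]) -> list[set[str]]:
    """Transitive closure of the pairwise containment relation (test oracle).

    Only practical for tiny inputs; used to cross-check the greedy
    clustering on fixtures without prefix-bridging reads.
    """
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(r.read_id for r in reads)
    for i, a in enumerate(reads):
        for b in reads[i + 1 :]:
            shorter, longer = sorted((a.bases, b.bases), key=len)
            if longer.startswith(shorter):
                graph.add_edge(a.read_id, b.read_id)
    return [set(c) for c in nx.connected_components(graph)]


def write_membership(clusters: list[Cluster], path) -> None:
    rows = [
        {"read_id": read_id, "cluster_id": c.representative_id}
        for c in clusters
        for read_id in c.member_read_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
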