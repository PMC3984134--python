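"""Read-to-reference mapping, type annotation, pruning, and consensus.

Mapping uses semi-global alignment with +1 match / -1 mismatch / -2 gap
scoring; a read is *mapped* only when a unique best-scoring reference
exists and the alignment identity clears ``min_identity`` — any exact score
tie makes the read *ambiguous* and it is discarded from counts, the
maximum-discrimination behaviour that keeps near-identical references
(C1 vs C3) honestly separated.

For speed, candidate references are shortlisted by edit distance with a
provable bound before any scored alignment is computed: for a read of
length n whose best reference lies at edit distance d_min, any alignment
score satisfies score <= n - 2*d while the best reference is guaranteed
score >= n - 3*d_min, so only references with 2*d <= 3*d_min can win or
tie. The shortlist is exact, not heuristic.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from dataclasses import replace as dataclasses_replace

import edlib
import numpy as np
import pandas as pd

from ._align import (
    alignment_identity,
    global_aligner,
    semiglobal_aligner,
    semiglobal_score,
)
from .cluster import ReferenceSet
from .preprocess import CleanRead

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

DEFAULT_MIN_IDENTITY = 90.0
DEFAULT_FLOOR_IDENTITY = 70.0
DEFAULT_HIGH_THRESHOLD = 0.85

MAPPED = "mapped"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class DiagnosticSite:
    """A single discriminating position on a named panel sequence (1-based)."""

    panel_seq_id: str
    position: int
    base_to_type: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.base_to_type)) != len(self.base_to_type):
            raise ValueError("diagnostic bases must be distinct")


@dataclass
class ReferencePanel:
    """Curated per-type annotation sequences plus diagnostic SNP sites."""

    entries: dict[str, str]  # type_name -> bases
    diagnostic_sites: tuple[DiagnosticSite, ...] = ()

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("panel must not be empty")

    @classmethod
    def from_files(cls, fasta_path, sites_path=None) -> "ReferencePanel":
        from Bio import SeqIO

        entries = {
            record.id: str(record.seq) for record in SeqIO.parse(str(fasta_path), "fasta")
        }
        sites: list[DiagnosticSite] = []
        if sites_path is not None:
            frame = pd.read_csv(sites_path, sep="\t", dtype=str)
            for (seq_id, pos), group in frame.groupby(["panel_seq_id", "position_1based"]):
                sites.append(
                    DiagnosticSite(
                        panel_seq_id=seq_id,
                        position=int(pos),
                        base_to_type=dict(zip(group.base, group.type)),
                    )
                )
        return cls(entries=entries, diagnostic_sites=tuple(sites))

    def write(self, fasta_path, sites_path) -> None:
        with open(fasta_path, "w") as handle:
            for type_name, bases in self.entries.items():
                handle.write(f">{type_name}\n{bases}\n")
        rows = [
            {
                "panel_seq_id": site.panel_seq_id,
                "position_1based": site.position,
                "base": base,
                "type": type_name,
            }
            for site in self.diagnostic_sites
            for base, type_name in site.base_to_type.items()
        ]
        pd.DataFrame(rows).to_csv(sites_path, sep="\t", index=False)


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    status: str
    reference_id: str | None = None
    score: float | None = None
    identity: float | None = None


@dataclass(frozen=True)
class TypeAnnotation:
    reference_id: str
    type_name: str | None
    percent_identity: float
    tie_break_used: str = "none"  # none | score | diagnostic_site
    flagged: bool = False


class ReadMapper:
    """Maps reads against a reference library, caching per-sequence work.

    The result cache is keyed by read sequence, so re-mapping after pruning
    (or mapping the same sequence from different samples) costs nothing.
    Use :meth:`with_references` to obtain a mapper restricted to a subset
    of the references that shares this mapper's caches.

    References are grouped into single-linkage families of mutually close
    sequences; per read, whole families are excluded through the triangle
    inequality (d(read, ref) >= d(read, exemplar) - family radius) before
    any member distance is computed. Scored alignments are only run where
    an exact score tie is possible; for unambiguous assignments the
    reported score is that of the minimum-edit alignment of the winning
    reference (the mapping decision itself never depends on it).
    """

    FAMILY_LINK_DISTANCE = 15

    def __init__(
        self,
        references: ReferenceSet | list[tuple[str, str]],
        min_identity: float = DEFAULT_MIN_IDENTITY,
    ):
        if isinstance(references, ReferenceSet):
            entries = [(r[0], r[1]) for r in references.references]
        else:
            entries = list(references)
        if not entries:
            raise ValueError("references must be non-empty")
        self._ref_ids = [e[0] for e in entries]
        self._ref_seqs = [e[1] for e in entries]
        self.min_identity = min_identity
        self._active: frozenset[int] = frozenset(range(len(entries)))
        self._scores: dict[tuple[str, int], float] = {}
        # read sequence -> (candidate indices, assignment); reusable under
        # any restriction that keeps every candidate (see assign)
        self._results: dict[str, tuple[frozenset, ReadAssignment]] = {}
        self._families = self._build_families()
        # sorted reference sequences for exact-prefix lookups: amplicon
        # reads share the reference start, so a truncated error-free read
        # is an exact prefix of its reference
        self._sorted_seqs = sorted(
            (seq, i) for i, seq in enumerate(self._ref_seqs)
        )

    def _build_families(self) -> list[tuple[int, list[int], int]]:
        """Single-linkage families under global edit distance; per family
        the exemplar index, member indices, and radius max d(exemplar, m)."""
        n = len(self._ref_seqs)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        pair_d = {}
        for i in range(n):
            for j in range(i + 1, n):
                d = edlib.align(self._ref_seqs[i], self._ref_seqs[j], mode="NW",
                                task="distance")["editDistance"]
                pair_d[(i, j)] = d
                if d <= self.FAMILY_LINK_DISTANCE:
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        families = []
        for members in groups.values():
            exemplar = members[0]
            radius = 0
            for m in members[1:]:
                key = (min(exemplar, m), max(exemplar, m))
                d = pair_d.get(key)
                if d is None:
                    d = edlib.align(self._ref_seqs[exemplar], self._ref_seqs[m],
                                    mode="NW", task="distance")["editDistance"]
                radius = max(radius, d)
            families.append((exemplar, members, radius))
        return families

    def with_references(self, reference_ids) -> "ReadMapper":
        keep = set(reference_ids)
        clone = object.__new__(ReadMapper)
        clone.__dict__.update(self.__dict__)
        clone._active = frozenset(
            i for i, rid in enumerate(self._ref_ids) if rid in keep
        )
        if not clone._active:
            raise ValueError("no references left after restriction")
        return clone

    @property
    def reference_ids(self) -> list[str]:
        return [self._ref_ids[i] for i in sorted(self._active)]

    def _distance(self, bases: str, ref_index: int) -> int:
        return edlib.align(bases, self._ref_seqs[ref_index], mode="HW",
                           task="distance")["editDistance"]

    def _distances_shortlist(self, bases: str) -> dict[int, int]:
        """HW distances for every active reference that could win or tie.

        Families whose triangle-inequality lower bound exceeds 1.5x the
        current best distance cannot contain the winner (score <= n - 2d
        while the best reference guarantees >= n - 3*d_min) and are skipped
        without touching their members.
        """
        surveyed = []
        d_min_ub = None
        for exemplar, members, radius in self._families:
            if not any(m in self._active for m in members):
                continue
            d_ex = self._distance(bases, exemplar)
            surveyed.append((exemplar, d_ex, members, radius))
            # an achievable distance: the exemplar itself if active, else
            # some active member within `radius` of it
            achievable = d_ex if exemplar in self._active else d_ex + radius
            if d_min_ub is None or achievable < d_min_ub:
                d_min_ub = achievable
        distances: dict[int, int] = {}
        for exemplar, d_ex, members, radius in surveyed:
            if 2 * (d_ex - radius) > 3 * d_min_ub:
                continue
            for m in members:
                if m not in self._active:
                    continue
                distances[m] = (
                    d_ex if m == exemplar else self._distance(bases, m)
                )
        return distances

    def _exact_score(self, bases: str, ref_index: int) -> float:
        key = (bases, ref_index)
        score = self._scores.get(key)
        if score is None:
            score = semiglobal_score(bases, self._ref_seqs[ref_index])
            self._scores[key] = score
        return score

    def _path_score(self, bases: str, ref_index: int) -> float:
        """Score of the minimum-edit semi-global alignment under +1/-1/-2."""
        result = edlib.align(bases, self._ref_seqs[ref_index], mode="HW", task="path")
        matches = mismatches = gap_columns = 0
        for count, op in _CIGAR_RE.findall(result["cigar"]):
            c = int(count)
            if op == "=":
                matches += c
            elif op == "X":
                mismatches += c
            else:
                gap_columns += c
        return float(matches - mismatches - 2 * gap_columns)

    def _prefix_hits(self, bases: str) -> list[int]:
        """Active references having ``bases`` as an exact prefix (distance 0)."""
        import bisect

        lo = bisect.bisect_left(self._sorted_seqs, (bases, -1))
        hits = []
        for seq, i in self._sorted_seqs[lo:]:
            if not seq.startswith(bases):
                break
            if i in self._active:
                hits.append(i)
        return hits

    def assign(self, read_id: str, bases: str) -> ReadAssignment:
        cached = self._results.get(bases)
        if cached is not None:
            candidates, result = cached
            # a restriction keeping every candidate cannot change the
            # outcome: d_min is attained inside the candidate set and the
            # shortlist can only shrink onto the same set
            if candidates <= self._active:
                if result.read_id != read_id:
                    result = dataclasses_replace(result, read_id=read_id)
                return result
        prefix = self._prefix_hits(bases)
        if prefix:
            n = float(len(bases))
            if len(prefix) > 1:
                result = ReadAssignment(read_id, AMBIGUOUS, score=n)
            else:
                result = ReadAssignment(
                    read_id, MAPPED, reference_id=self._ref_ids[prefix[0]],
                    score=n, identity=100.0,
                )
            self._results[bases] = (frozenset(prefix), result)
            return result
        result, candidates = self._assign_uncached(read_id, bases)
        self._results[bases] = (candidates, result)
        return result

    def _assign_uncached(self, read_id: str, bases: str):
        distances = self._distances_shortlist(bases)
        d_min = min(distances.values())
        n = len(bases)
        # only refs with 2d <= 3*d_min can reach the guaranteed best score
        # of n - 3*d_min (see class docstring)
        candidates = [i for i, d in distances.items() if 2 * d <= 3 * d_min]
        candidate_set = frozenset(candidates)
        if len(candidates) == 1:
            winner = candidates[0]
            score = float(n) if d_min == 0 else self._path_score(bases, winner)
        elif d_min == 0:
            # exact match to several references: all score n, a perfect tie
            return ReadAssignment(read_id, AMBIGUOUS, score=float(n)), candidate_set
        else:
            scores = np.array([self._exact_score(bases, i) for i in candidates])
            best = scores.max()
            winners = [c for c, s in zip(candidates, scores) if s == best]
            if len(winners) > 1:
                return (
                    ReadAssignment(read_id, AMBIGUOUS, score=float(best)),
                    candidate_set,
                )
            winner = winners[0]
            score = float(best)
        d_winner = distances[winner]
        identity_floor = 100.0 * (n - d_winner) / (n + d_winner) if n else 0.0
        if identity_floor >= self.min_identity:
            identity = identity_floor
        else:
            identity = alignment_identity(bases, self._ref_seqs[winner])
            if identity < self.min_identity:
                return (
                    ReadAssignment(read_id, UNMAPPED, score=score, identity=identity),
                    candidate_set,
                )
        return (
            ReadAssignment(
                read_id, MAPPED, reference_id=self._ref_ids[winner],
                score=score, identity=identity,
            ),
            candidate_set,
        )

    def map(self, clean_reads: list[CleanRead]) -> list[ReadAssignment]:
        return [self.assign(r.read_id, r.bases) for r in clean_reads]


def map_reads(
    clean_reads: list[CleanRead],
    references: ReferenceSet | list[tuple[str, str]],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    mapper: ReadMapper | None = None,
) -> list[ReadAssignment]:
    """Map reads to references; see :class:`ReadMapper` for semantics."""
    if mapper is None:
        mapper = ReadMapper(references, min_identity)
    return mapper.map(clean_reads)


def mapping_efficiency(assignments: list[ReadAssignment]) -> float:
    """Fraction of reads unambiguously mapped (reported to 2 dp in outputs)."""
    if not assignments:
        raise ValueError("no assignments")
    mapped = sum(1 for a in assignments if a.status == MAPPED)
    return mapped / len(assignments)


# ---------------------------------------------------------------------------
# annotation


def _panel_identity(bases: str, panel_bases: str) -> float:
    return round(alignment_identity(bases, panel_bases), 9)


def _base_at_panel_position(bases: str, panel_bases: str, position_1based: int) -> str | None:
    """Base of ``bases`` aligned opposite the given panel position (or None)."""
    alignment = semiglobal_aligner().align(panel_bases, bases)[0]
    target_idx = position_1based - 1
    for (t_start, t_end), (q_start, q_end) in zip(*alignment.aligned):
        if t_start <= target_idx < t_end:
            return bases[q_start + (target_idx - t_start)]
    return None


def annotate_references(
    references: ReferenceSet | list[tuple[str, str]],
    panel: ReferencePanel,
    floor_identity: float = DEFAULT_FLOOR_IDENTITY,
) -> list[TypeAnnotation]:
    """Assign each reference the panel type of highest percent identity.

    Exact identity ties between near-identical types are resolved by the
    reference's base at a configured diagnostic site (e.g. C at the C1/C3
    SNP -> C1, T -> C3); remaining ties fall back to alignment score, and
    anything still tied is flagged for manual review rather than silently
    broken.
    """
    entries = (
        [(r[0], r[1]) for r in references.references]
        if isinstance(references, ReferenceSet)
        else list(references)
    )
    annotations = []
    for ref_id, bases in entries:
        identities = {
            type_name: _panel_identity(bases, panel_bases)
            for type_name, panel_bases in panel.entries.items()
        }
        best = max(identities.values())
        if best < floor_identity:
            annotations.append(
                TypeAnnotation(ref_id, None, best, tie_break_used="none", flagged=True)
            )
            continue
        tied = sorted(t for t, v in identities.items() if v == best)
        if len(tied) == 1:
            annotations.append(TypeAnnotation(ref_id, tied[0], best))
            continue
        resolved = _resolve_by_diagnostic_site(bases, panel, tied)
        if resolved is not None:
            annotations.append(
                TypeAnnotation(ref_id, resolved, best, tie_break_used="diagnostic_site")
            )
            continue
        scores = {t: semiglobal_score(bases, panel.entries[t]) for t in tied}
        best_score = max(scores.values())
        score_tied = [t for t in tied if scores[t] == best_score]
        if len(score_tied) == 1:
            annotations.append(
                TypeAnnotation(ref_id, score_tied[0], best, tie_break_used="score")
            )
        else:
            annotations.append(
                TypeAnnotation(ref_id, None, best, tie_break_used="score", flagged=True)
            )
    return annotations


def _resolve_by_diagnostic_site(
    bases: str, panel: ReferencePanel, tied: list[str]
) -> str | None:
    for site in panel.diagnostic_sites:
        if not set(site.base_to_type.values()) >= set(tied):
            continue
        panel_bases = panel.entries.get(site.panel_seq_id)
        if panel_bases is None:
            continue
        observed = _base_at_panel_position(bases, panel_bases, site.position)
        if observed is not None and observed in site.base_to_type:
            type_name = site.base_to_type[observed]
            if type_name in tied:
                return type_name
    return None


# ---------------------------------------------------------------------------
# pruning


def prune_references(
    reference_set: ReferenceSet,
    annotations: list[TypeAnnotation],
    counts: pd.DataFrame,
    designs: dict[str, dict[str, float]],
    high_threshold: float = DEFAULT_HIGH_THRESHOLD,
) -> tuple[ReferenceSet, list[dict]]:
    """Drop references missing from known high-abundance samples of their type.

    ``counts`` is a samples x references table of mapped read counts;
    ``designs`` maps sample_id -> {type_name: designed cell fraction}. A
    reference is removed iff it has zero mapped reads in any sample whose
    designed fraction of the reference's type is >= ``high_threshold`` —
    such samples must contain every real haplotype of that type. Types
    without any high-abundance sample are kept with a warning entry.
    """
    type_of = {a.reference_id: a.type_name for a in annotations}
    log: list[dict] = []
    removed: set[str] = set()
    types = {t for t in type_of.values() if t is not None}
    high_samples = {
        t: [s for s, fractions in designs.items() if fractions.get(t, 0.0) >= high_threshold]
        for t in types
    }
    for t in sorted(types):
        if not high_samples[t]:
            log.append({"action": "warning", "type": t,
                        "detail": "no high-abundance sample; references kept"})
    for ref_id, _, _ in reference_set.references:
        t = type_of.get(ref_id)
        if t is None:
            continue
        for sample_id in high_samples.get(t, []):
            count = 0
            if sample_id in counts.index and ref_id in counts.columns:
                count = int(counts.loc[sample_id, ref_id])
            if count == 0:
                removed.add(ref_id)
                log.append({"action": "removed", "reference_id": ref_id,
                            "type": t, "triggering_sample": sample_id})
                break
    kept = [r for r in reference_set.references if r[0] not in removed]
    return ReferenceSet(kept), log


# ---------------------------------------------------------------------------
# consensus


def type_consensus(
    references_of_type: list[tuple[str, str]],
    source_cluster_sizes: dict[str, int] | None = None,
) -> str:
    """Column-majority consensus of one type's reference sequences.

    References are star-aligned against an anchor (the reference from the
    largest source cluster; ties broken toward the longest sequence, then
    the smallest id). Per column the majority base wins; gap-versus-base
    columns are decided by majority presence; exact ties resolve toward the
    anchor. Used for reporting and annotation only — mapping always targets
    the original references, since collapsing them would erase the
    haplotype-level signal.
    """
    if not references_of_type:
        raise ValueError("need at least one reference")
    if len(references_of_type) == 1:
        return references_of_type[0][1]
    sizes = source_cluster_sizes or {}
    anchor_id, anchor = max(
        references_of_type,
        key=lambda r: (sizes.get(r[0], 0), len(r[1]), [-ord(c) for c in r[0]]),
    )
    aligner = global_aligner()
    # column profiles: key (anchor_pos, insert_rank); anchor columns have rank 0
    profiles: defaultdict[tuple[int, int], defaultdict[str, int]] = defaultdict(
        lambda: defaultdict(int)
    )
    n_rows = 0
    for pos in range(len(anchor)):
        profiles[(pos, 0)][anchor[pos]] += 1
    n_rows += 1
    for ref_id, bases in references_of_type:
        if ref_id == anchor_id and bases == anchor:
            continue
        alignment = aligner.align(anchor, bases)[0]
        row_t, row_q = str(alignment[0]), str(alignment[1])
        anchor_pos = -1
        insert_rank = 0
        for t_char, q_char in zip(row_t, row_q):
            if t_char == "-":
                insert_rank += 1
                profiles[(anchor_pos, insert_rank)][q_char] += 1
            else:
                anchor_pos += 1
                insert_rank = 0
                profiles[(anchor_pos, 0)][q_char] += 1
        n_rows += 1

    consensus = []
    for key in sorted(profiles):
        counts = profiles[key]
        pos, rank = key
        present = sum(v for b, v in counts.items() if b != "-")
        absent = n_rows - present  # rows with a gap (incl. rows never inserting here)
        if present < absent or (present == absent and rank > 0):
            continue  # majority (or tied non-anchor insert) says gap
        anchor_base = anchor[pos] if rank == 0 else None
        best = max(counts.values())
        top = sorted(b for b, v in counts.items() if v == best and b != "-")
        if not top:
            continue
        if anchor_base in top:
            consensus.append(anchor_base)
        else:
            consensus.append(top[0])
    return "".join(consensus)


def annotations_to_frame(annotations: list[TypeAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reference_id": a.reference_id,
                "type": a.type_name,
                "percent_identity": a.percent_identity,
                "tie_break": a.tie_break_used,
                "flagged": a.flagged,
            }
            for a in annotations
        ]
    )
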