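"""Shared pairwise-alignment helpers.

Two engines are used throughout the package:

* :mod:`edlib` for fast unit-cost edit distances and extended CIGARs
  (prefiltering read-vs-reference comparisons, mutation counting);
* :class:`Bio.Align.PairwiseAligner` for scored alignments under the
  mapper's +1/-1/-2 scheme, where exact score ties matter.
"""

from __future__ import annotations

import functools
import re

import edlib
from Bio.Align import PairwiseAligner

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP = -2.0


@functools.lru_cache(maxsize=8)
def semiglobal_aligner(
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> PairwiseAligner:
    """Overlap (semi-global) aligner: end gaps on either sequence are free."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


@functools.lru_cache(maxsize=8)
def global_aligner(
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> PairwiseAligner:
    """True global aligner (end gaps penalised)."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def semiglobal_score(query: str, target: str) -> float:
    """Best overlap-alignment score of ``query`` against ``target``."""
    return semiglobal_aligner().score(target, query)


def edit_distance(query: str, target: str, mode: str = "HW") -> int:
    """Unit-cost edit distance; ``HW`` allows free end gaps on the target."""
    return edlib.align(query, target, mode=mode, task="distance")["editDistance"]


def alignment_identity(query: str, target: str) -> float:
    """Percent identity of the best semi-global alignment.

    Identity is matches over (aligned columns + internal gap columns +
    unaligned query bases). Target-side overhangs are free — a read
    covering part of its reference loses nothing — but query bases left
    outside the alignment count against identity, so a short accidental
    match inside an unrelated sequence cannot masquerade as high identity.
    """
    alignment = semiglobal_aligner().align(target, query)[0]
    t_blocks, q_blocks = alignment.aligned
    matches = 0
    aligned_columns = 0
    for (t_start, t_end), (q_start, q_end) in zip(t_blocks, q_blocks):
        aligned_columns += t_end - t_start
        matches += sum(
            a == b for a, b in zip(target[t_start:t_end], query[q_start:q_end])
        )
    internal_gaps = 0
    for i in range(1, len(t_blocks)):
        internal_gaps += t_blocks[i][0] - t_blocks[i - 1][1]
        internal_gaps += q_blocks[i][0] - q_blocks[i - 1][1]
    if len(q_blocks) == 0:
        return 0.0
    query_overhang = q_blocks[0][0] + (len(query) - q_blocks[-1][1])
    denom = aligned_columns + internal_gaps + query_overhang
    if denom == 0:
        return 0.0
    return 100.0 * matches / denom


def cigar_events(query: str, target: str) -> tuple[int, int]:
    """(substitution columns, contiguous indel runs) of a global alignment.

    Each maximal run of insertions or deletions counts once, the mutation
    counting convention under which an n-base indel is a single event.
    """
    result = edlib.align(query, target, mode="NW", task="path")
    substitutions = 0
    indel_runs = 0
    previous = None
    for count, op in _CIGAR_RE.findall(result["cigar"]):
        if op == "X":
            substitutions += int(count)
        elif op in "ID" and previous != op:
            indel_runs += 1
        previous = op if op in "ID" else None
    return substitutions, indel_runs


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
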