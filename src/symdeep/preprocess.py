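"""Read pre-processing: demultiplexing, primer trimming, quality/length filtering.

Raw barcoded amplicon reads are split by barcode, stripped of barcode and
PCR-primer bases, and filtered on read length (< 150 bp discarded, the
strict "less than" rule) and mean Phred-equivalent quality. Counts are
conserved at every stage: every input read ends up in exactly one of
kept / rejected / unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._align import hamming, reverse_complement

DEFAULT_MIN_LENGTH = 150
DEFAULT_MIN_MEAN_QUALITY = 20.0
DEFAULT_BARCODE_MISMATCHES = 1
DEFAULT_PRIMER_MISMATCHES = 2


@dataclass(frozen=True)
class SequencingRead:
    """A raw read with per-base quality scores."""

    read_id: str
    bases: str
    qualities: tuple[int, ...] | bytes

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases and qualities must have equal length")


@dataclass(frozen=True)
class CleanRead:
    """A demultiplexed, barcode- and primer-free read."""

    read_id: str
    sample_id: str
    bases: str
    qualities: tuple[int, ...] | bytes = ()


@dataclass(frozen=True)
class ManifestRow:
    barcode: str
    sample_id: str
    primer_forward: str
    primer_reverse: str


class SampleManifest:
    """Barcode-to-sample mapping with per-sample primers."""

    def __init__(self, rows: list[ManifestRow]):
        if not rows:
            raise ValueError("manifest must not be empty")
        barcodes = [r.barcode for r in rows]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcodes in manifest")
        sample_ids = [r.sample_id for r in rows]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids in manifest")
        self.rows = list(rows)
        self._by_barcode = {r.barcode: r for r in rows}

    @classmethod
    def from_tsv(cls, path) -> "SampleManifest":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        return cls(
            [
                ManifestRow(
                    barcode=row.barcode,
                    sample_id=row.sample_id,
                    primer_forward=row.fwd_primer,
                    primer_reverse=row.rev_primer,
                )
                for row in frame.itertuples()
            ]
        )

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def read_fastq(path) -> list[SequencingRead]:
    # qualities kept as compact Phred byte strings (they behave as integer
    # sequences); the tuple-based constructor used in small fixtures works
    # identically
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as handle:
        return [
            SequencingRead(
                read_id=title.split()[0],
                bases=seq,
                qualities=bytes(ord(c) - 33 for c in qual),
            )
            for title, seq, qual in FastqGeneralIterator(handle)
        ]


def demultiplex(
    reads: list[SequencingRead],
    manifest: SampleManifest,
    max_barcode_mismatches: int = DEFAULT_BARCODE_MISMATCHES,
) -> tuple[dict[str, list[SequencingRead]], list[SequencingRead]]:
    """Assign reads to samples by 5' barcode; barcode bases are stripped.

    A read is assigned only if a unique best-matching barcode lies within
    ``max_barcode_mismatches``; exact-tie or no-match reads land in the
    unassigned bin unchanged.
    """
    by_sample: dict[str, list[SequencingRead]] = {r.sample_id: [] for r in manifest}
    unassigned: list[SequencingRead] = []
    rows = list(manifest)
    exact = {r.barcode: r for r in rows}
    for read in reads:
        row = None
        for length in {len(r.barcode) for r in rows}:
            candidate = exact.get(read.bases[:length])
            if candidate is not None:
                row = candidate
                break
        if row is None and max_barcode_mismatches > 0:
            best, best_d, tie = None, None, False
            for r in rows:
                prefix = read.bases[: len(r.barcode)]
                if len(prefix) < len(r.barcode):
                    continue
                d = hamming(prefix, r.barcode)
                if best_d is None or d < best_d:
                    best, best_d, tie = r, d, False
                elif d == best_d:
                    tie = True
            if best is not None and not tie and best_d <= max_barcode_mismatches:
                row = best
        if row is None:
            unassigned.append(read)
        else:
            n = len(row.barcode)
            by_sample[row.sample_id].append(
                SequencingRead(read.read_id, read.bases[n:], read.qualities[n:])
            )
    return by_sample, unassigned


def trim_primers(
    read: SequencingRead,
    primer_forward: str,
    primer_reverse: str,
    max_mismatches: int = DEFAULT_PRIMER_MISMATCHES,
) -> SequencingRead | None:
    """Strip the leading forward primer and, if present, the trailing
    reverse-complemented reverse primer.

    Returns the trimmed read, or ``None`` (rejection) when no forward primer
    is found within ``max_mismatches`` at the 5' end. The reverse primer is
    optional: 454-style reads frequently terminate before reaching it, in
    which case any partial primer suffix (>= 8 bases, <= 1 mismatch) is also
    removed.
    """
    if not primer_forward or not primer_reverse:
        raise ValueError("primers must be non-empty")
    n_fwd = len(primer_forward)
    if len(read.bases) < n_fwd:
        return None
    if hamming(read.bases[:n_fwd], primer_forward) > max_mismatches:
        return None
    bases = read.bases[n_fwd:]
    qualities = read.qualities[n_fwd:]

    tail = reverse_complement(primer_reverse)
    cut = None
    # full primer: rightmost match wins
    window_start = max(0, len(bases) - len(tail) - 10)
    for start in range(len(bases) - len(tail), window_start - 1, -1):
        if start >= 0 and hamming(bases[start : start + len(tail)], tail) <= max_mismatches:
            cut = start
            break
    if cut is None:
        # truncated read: partial primer prefix at the very end
        for k in range(len(tail) - 1, 7, -1):
            if len(bases) >= k and hamming(bases[-k:], tail[:k]) <= 1:
                cut = len(bases) - k
                break
    if cut is not None:
        bases = bases[:cut]
        qualities = qualities[:cut]
    return SequencingRead(read.read_id, bases, qualities)


@dataclass
class FilterLog:
    """Per-reason rejection counts for the quality/length filter."""

    kept: int = 0
    too_short: int = 0
    low_quality: int = 0

    @property
    def rejected(self) -> int:
        return self.too_short + self.low_quality


def quality_length_filter(
    reads: list[SequencingRead],
    min_length: int = DEFAULT_MIN_LENGTH,
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
) -> tuple[list[SequencingRead], FilterLog]:
    """Keep reads of length >= min_length and mean quality >= min_mean_quality.

    Length is checked first, so a short low-quality read is logged once,
    as a length rejection.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept = []
    log = FilterLog()
    for read in reads:
        if len(read.bases) < min_length:
            log.too_short += 1
        elif read.qualities and sum(read.qualities) / len(read.qualities) < min_mean_quality:
            log.low_quality += 1
        else:
            log.kept += 1
            kept.append(read)
    return kept, log


@dataclass
class PreprocessReport:
    """Stage-by-stage read accounting for one preprocessing run."""

    raw: int = 0
    unassigned: int = 0
    no_forward_primer: int = 0
    too_short: int = 0
    low_quality: int = 0
    cleaned: int = 0
    per_sample: dict[str, int] = field(default_factory=dict)
    per_sample_raw: dict[str, int] = field(default_factory=dict)

    def reconciles(self) -> bool:
        return (
            self.raw
            == self.unassigned
            + self.no_forward_primer
            + self.too_short
            + self.low_quality
            + self.cleaned
        )


def preprocess(
    reads: list[SequencingRead],
    manifest: SampleManifest,
    max_barcode_mismatches: int = DEFAULT_BARCODE_MISMATCHES,
    max_primer_mismatches: int = DEFAULT_PRIMER_MISMATCHES,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
) -> tuple[dict[str, list[CleanRead]], PreprocessReport]:
    """Full pre-processing: demultiplex -> trim -> quality/length filter."""
    report = PreprocessReport(raw=len(reads))
    by_sample, unassigned = demultiplex(reads, manifest, max_barcode_mismatches)
    report.unassigned = len(unassigned)
    primers = {r.sample_id: r for r in manifest}
    clean: dict[str, list[CleanRead]] = {}
    for sample_id, sample_reads in by_sample.items():
        report.per_sample_raw[sample_id] = len(sample_reads)
        row = primers[sample_id]
        trimmed = []
        for read in sample_reads:
            result = trim_primers(
                read, row.primer_forward, row.primer_reverse, max_primer_mismatches
            )
            if result is None:
                report.no_forward_primer += 1
            else:
                trimmed.append(result)
        kept, log = quality_length_filter(trimmed, min_length, min_mean_quality)
        report.too_short += log.too_short
        report.low_quality += log.low_quality
        clean[sample_id] = [
            CleanRead(r.read_id, sample_id, r.bases, r.qualities) for r in kept
        ]
        report.per_sample[sample_id] = len(kept)
    report.cleaned = sum(report.per_sample.values())
    return clean, report


def write_clean_fasta(clean: dict[str, list[CleanRead]], directory) -> None:
    """One FASTA of clean reads per sample."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sample_id, reads in clean.items():
        with open(directory / f"{sample_id}.clean.fasta", "w") as handle:
            for read in reads:
                handle.write(f">{read.read_id}\n{read.bases}\n")
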