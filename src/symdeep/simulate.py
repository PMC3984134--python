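"""Mock-community amplicon simulator.

Generates labelled pyrosequencing-style ITS-2 amplicon reads from a panel of
symbiont type genomes, replicating a cell dilution series of known
composition: four types (A13, D1, C1, C3) mixed at 0.1/1/5/85/97/99.7/100 %
of a combined density of 1e6 cells, with intra-genomic rDNA variants,
per-type rDNA copy numbers, and PCR/454-style errors (substitutions plus
+/-1 indels in homopolymer runs).

Every read carries a truth label (source type and variant), so each
downstream stage of the pipeline can be validated against known composition
without any external data.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace

import numpy as np

from ._align import hamming, reverse_complement

# ITS-2 amplification primers commonly used for Symbiodinium typing.
ITS2_FORWARD_PRIMER = "GTGAATTGCAGAACTCCGTG"
ITS2_REVERSE_PRIMER = "CCTCCGCTTACTTATATGCTT"

#: 1-based position of the single SNP discriminating types C1 and C3
#: (C in C1, T in C3) on the panel sequence of type C1.
C1_C3_DIAGNOSTIC_POSITION = 212

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Cell percentages of (A13, D1, C1, C3) for the 15-sample dilution series:
# each type as dominant over 0.1 %, 1 % and 5 % backgrounds, plus pure
# samples for A13, D1 and C1 (the C3 pure sample is not part of the design).
DILUTION_SERIES_DESIGN: tuple[tuple[float, float, float, float], ...] = (
    (99.7, 0.1, 0.1, 0.1),
    (0.1, 99.7, 0.1, 0.1),
    (0.1, 0.1, 99.7, 0.1),
    (0.1, 0.1, 0.1, 99.7),
    (97.0, 1.0, 1.0, 1.0),
    (1.0, 97.0, 1.0, 1.0),
    (1.0, 1.0, 97.0, 1.0),
    (1.0, 1.0, 1.0, 97.0),
    (85.0, 5.0, 5.0, 5.0),
    (5.0, 85.0, 5.0, 5.0),
    (5.0, 5.0, 85.0, 5.0),
    (5.0, 5.0, 5.0, 85.0),
    (100.0, 0.0, 0.0, 0.0),
    (0.0, 100.0, 0.0, 0.0),
    (0.0, 0.0, 100.0, 0.0),
)

DILUTION_SERIES_PCR_CYCLES = (23, 23, 23, 23, 23, 22, 22, 23, 24, 22, 23, 23, 24, 23, 24)

DILUTION_SERIES_TYPES = ("A13", "D1", "C1", "C3")


@dataclass(frozen=True)
class VariantSequence:
    """One intra-genomic rDNA variant of a type."""

    variant_id: str
    bases: str
    copy_fraction: float

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("variant bases must be non-empty")
        if not 0.0 < self.copy_fraction <= 1.0:
            raise ValueError("copy_fraction must be in (0, 1]")


@dataclass(frozen=True)
class TypeGenome:
    """A symbiont type: its rDNA variants and total copy number per cell."""

    type_name: str
    variants: tuple[VariantSequence, ...]
    copy_number: int = 1000

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("a genome needs at least one variant")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids must be unique")
        total = sum(v.copy_fraction for v in self.variants)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"copy fractions must sum to 1 (got {total})")


@dataclass(frozen=True)
class MixtureDesign:
    """Known cell composition of one mixed sample."""

    sample_id: str
    cell_fractions: dict[str, float]
    total_cells: int = 1_000_000
    read_depth: int = 10_000
    pcr_cycles: int = 23  # metadata only; amplification bias is not modelled

    def __post_init__(self) -> None:
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if any(f < 0 for f in self.cell_fractions.values()):
            raise ValueError("cell fractions must be non-negative")
        total = sum(self.cell_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell fractions must sum to 1 (got {total})")


@dataclass(frozen=True)
class ErrorModel:
    """Sequencing error and read-length model for 454-style reads.

    ``substitution_rate`` is per base; ``homopolymer_indel_rate`` is the
    per-homopolymer-run (length >= 2) probability of a +/-1 length change,
    the dominant pyrosequencing error class. Read lengths are drawn from a
    normal distribution truncated below at ``length_min``.
    """

    substitution_rate: float = 0.002
    homopolymer_indel_rate: float = 0.003
    length_mean: float = 380.0
    length_sd: float = 40.0
    length_min: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.homopolymer_indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.length_min < 1:
            raise ValueError("length_min must be >= 1")

    @classmethod
    def zero_error(cls, seed: int = 0) -> "ErrorModel":
        """Error-free, untruncated reads (for oracle-style tests)."""
        return cls(
            substitution_rate=0.0,
            homopolymer_indel_rate=0.0,
            length_mean=10_000.0,
            length_sd=0.0,
            length_min=1,
            seed=seed,
        )


@dataclass
class SimSample:
    """Simulated reads of one sample plus their truth labels."""

    sample_id: str
    reads: list[tuple[str, str, bytes, str]]  # (read_id, bases, quals, barcode)
    truth: dict[str, tuple[str, str]]  # read_id -> (type_name, variant_id)
    design: MixtureDesign | None = None
    barcode: str = ""

    def __post_init__(self) -> None:
        read_ids = [r[0] for r in self.reads]
        if sorted(read_ids) != sorted(self.truth):
            raise ValueError("truth must cover every read exactly once")


# ---------------------------------------------------------------------------
# panel construction


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate_positions(
    rng: np.random.Generator, seq: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    out = seq.copy()
    for pos in positions:
        choices = _BASES[_BASES != out[pos]]
        out[pos] = rng.choice(choices)
    return out


def _derive_variant(
    rng: np.random.Generator, seq: np.ndarray, n_mutations: int
) -> np.ndarray:
    """Apply ``n_mutations`` events: substitutions and short indel runs."""
    out = seq.copy()
    for _ in range(n_mutations):
        if rng.random() < 0.75:  # substitution
            pos = rng.integers(0, len(out))
            out = _mutate_positions(rng, out, np.array([pos]))
        elif rng.random() < 0.5 and len(out) > 4:  # deletion run (1-3 bp)
            run = int(rng.integers(1, 4))
            pos = int(rng.integers(0, len(out) - run))
            out = np.delete(out, slice(pos, pos + run))
        else:  # insertion run (1-3 bp)
            run = int(rng.integers(1, 4))
            pos = int(rng.integers(0, len(out)))
            out = np.insert(out, pos, _random_sequence(rng, run))
    return out


def _as_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode("ascii")


def build_type_panel(
    n_types: int = 4,
    n_variants_per_type: int | dict[str, int] = 3,
    divergence_between_types: float = 0.10,
    divergence_within_type: float = 0.01,
    copy_numbers: int | dict[str, int] = 1000,
    seed: int = 0,
    sequence_length: int = 350,
    type_names: tuple[str, ...] | None = None,
) -> list[TypeGenome]:
    """Generate a panel of type genomes with controlled divergence.

    Types are derived from a common ancestor by substituting disjoint sets of
    ``divergence_between_types * sequence_length`` positions, so any two
    types differ at >= that many sites. Within a type, variants differ from
    the founding variant by at most ``divergence_within_type *
    sequence_length`` mutation events (substitutions or short indel runs).
    Copy fractions across a genome's variants follow a geometric-ish decay
    (the founding variant is the most abundant copy), normalised to 1.
    """
    if n_types < 1:
        raise ValueError("n_types must be >= 1")
    if sequence_length < 200:
        raise ValueError("sequence_length must be >= 200")
    if not divergence_within_type < divergence_between_types:
        raise ValueError(
            "divergence_within_type must be smaller than divergence_between_types"
        )
    if type_names is None:
        type_names = tuple(f"T{i + 1}" for i in range(n_types))
    if len(type_names) != n_types:
        raise ValueError("type_names length must equal n_types")

    rng = np.random.default_rng(seed)
    ancestor = _random_sequence(rng, sequence_length)
    n_between = max(1, int(round(divergence_between_types * sequence_length)))
    n_within = int(round(divergence_within_type * sequence_length))

    all_positions = rng.permutation(sequence_length)
    if n_types * n_between > sequence_length:
        raise ValueError("divergence_between_types too large for sequence_length")

    genomes: list[TypeGenome] = []
    for i, name in enumerate(type_names):
        positions = all_positions[i * n_between : (i + 1) * n_between]
        founder = _mutate_positions(rng, ancestor, positions)
        n_var = (
            n_variants_per_type[name]
            if isinstance(n_variants_per_type, dict)
            else n_variants_per_type
        )
        if n_var < 1:
            raise ValueError("n_variants_per_type must be >= 1")
        copy_number = (
            copy_numbers[name] if isinstance(copy_numbers, dict) else copy_numbers
        )
        genomes.append(
            _assemble_genome(rng, name, founder, n_var, n_within, copy_number)
        )
    return genomes


def _assemble_genome(
    rng: np.random.Generator,
    name: str,
    founder: np.ndarray,
    n_variants: int,
    max_within_mutations: int,
    copy_number: int,
) -> TypeGenome:
    variants = [founder]
    seen = {_as_str(founder)}
    while len(variants) < n_variants:
        n_mut = int(rng.integers(1, max(2, max_within_mutations + 1)))
        candidate = _derive_variant(rng, founder, n_mut)
        key = _as_str(candidate)
        if key not in seen:
            seen.add(key)
            variants.append(candidate)
    # founding variant dominates the tandem array; minor variants decay
    weights = np.array([2.0 ** -i for i in range(n_variants)])
    fractions = weights / weights.sum()
    # exact sum-to-1 despite float rounding
    fractions[-1] = 1.0 - fractions[:-1].sum()
    letters = "abcdefghijklmnopqrstuvwxyz"
    return TypeGenome(
        type_name=name,
        variants=tuple(
            VariantSequence(f"{name}({letters[i]})", _as_str(v), float(fractions[i]))
            for i, v in enumerate(variants)
        ),
        copy_number=copy_number,
    )


def default_panel(
    seed: int = 0,
    copy_numbers: dict[str, int] | None = None,
    n_variants: dict[str, int] | None = None,
):
    """The four-type study panel (A13, D1, C1, C3) plus its annotation panel.

    C1 and C3 are separated by exactly one substitution, a C/T SNP at
    position :data:`C1_C3_DIAGNOSTIC_POSITION` of the C1 panel sequence
    (C in C1, T in C3); D1 sits ~12 % and A13 ~20 % away from the clade-C
    pair, mirroring the divergence structure of the real types. Variant
    counts default to A13:5, D1:4, C1:3, C3:2 intra-genomic variants.

    Returns ``(genomes, panel)`` where ``panel`` is a
    :class:`symdeep.mapping.ReferencePanel` holding one annotation sequence
    per type and the C1/C3 diagnostic site.
    """
    from .mapping import DiagnosticSite, ReferencePanel

    if copy_numbers is None:
        copy_numbers = {name: 1000 for name in DILUTION_SERIES_TYPES}
    if n_variants is None:
        n_variants = {"A13": 5, "D1": 4, "C1": 3, "C3": 2}

    rng = np.random.default_rng(seed)
    length = 350
    c1 = _random_sequence(rng, length)
    pos0 = C1_C3_DIAGNOSTIC_POSITION - 1
    c1[pos0] = ord("C")
    c3 = c1.copy()
    c3[pos0] = ord("T")

    positions = rng.permutation(np.delete(np.arange(length), pos0))
    d1 = _mutate_positions(rng, c1, positions[:42])  # ~12 % diverged
    a13 = _mutate_positions(rng, c1, positions[42 : 42 + 70])  # ~20 % diverged

    founders = {"A13": a13, "D1": d1, "C1": c1, "C3": c3}
    n_within = 5
    genomes = [
        _assemble_genome(
            rng, name, founders[name], n_variants[name], n_within, copy_numbers[name]
        )
        for name in DILUTION_SERIES_TYPES
    ]
    panel = ReferencePanel(
        entries={g.type_name: g.variants[0].bases for g in genomes},
        diagnostic_sites=(
            DiagnosticSite(
                panel_seq_id="C1",
                position=C1_C3_DIAGNOSTIC_POSITION,
                base_to_type={"C": "C1", "T": "C3"},
            ),
        ),
    )
    return genomes, panel


# ---------------------------------------------------------------------------
# expected composition


def expected_read_fractions(
    design: MixtureDesign, genomes: list[TypeGenome]
) -> dict[str, float]:
    """Copy-number-weighted expected read fraction per type.

    f_t = c_t * n_t / sum_u c_u * n_u, where c is the cell fraction and n
    the per-cell rDNA copy number: a type with 3x the copies of another
    contributes 3x the template molecules per cell.
    """
    by_name = {g.type_name: g for g in genomes}
    missing = set(design.cell_fractions) - set(by_name)
    if missing:
        raise KeyError(f"design types absent from panel: {sorted(missing)}")
    weights = {
        name: frac * by_name[name].copy_number
        for name, frac in design.cell_fractions.items()
    }
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("all template weights are zero")
    return {name: w / total for name, w in weights.items()}


# ---------------------------------------------------------------------------
# read simulation


def barcode_set(n: int, length: int = 8, min_distance: int = 3, seed: int = 7) -> list[str]:
    """Deterministic barcodes with pairwise Hamming distance >= min_distance."""
    rng = np.random.default_rng(seed)
    codes: list[str] = []
    while len(codes) < n:
        candidate = _as_str(_random_sequence(rng, length))
        if all(hamming(candidate, c) >= min_distance for c in codes):
            codes.append(candidate)
    return codes


def _homopolymer_runs(seq: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) of maximal homopolymer runs of length >= 2."""
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            if i - start >= 2:
                runs.append((start, i))
            start = i
    return runs


@functools.lru_cache(maxsize=4096)
def _synthesize_qualities(length: int) -> bytes:
    """Constant high Phred scores with a degraded 3' tail."""
    quals = np.full(length, 38, dtype=np.uint8)
    tail = max(1, length // 10)
    quals[-tail:] = np.linspace(38, 24, tail).astype(np.uint8)
    return quals.tobytes()


def simulate_reads(
    design: MixtureDesign,
    genomes: list[TypeGenome],
    error_model: ErrorModel,
    barcode: str = "",
    forward_primer: str = ITS2_FORWARD_PRIMER,
    reverse_primer: str = ITS2_REVERSE_PRIMER,
) -> SimSample:
    """Draw reads for one sample.

    Each read (i) picks a template (type, variant) with probability
    proportional to cell_fraction x copy_number x copy_fraction, (ii) applies
    per-base substitutions to the biological insert, (iii) applies +/-1
    indels to homopolymer runs, (iv) is assembled as barcode + forward
    primer + insert + reverse-complemented reverse primer and truncated to a
    sampled read length. Barcode and primer bases are copied intact so that
    truth-based demultiplexing checks are exact. Deterministic per seed.
    """
    if not design.cell_fractions:
        raise ValueError("empty design")
    fractions = expected_read_fractions(design, genomes)
    by_name = {g.type_name: g for g in genomes}

    templates: list[tuple[str, str, np.ndarray, list[tuple[int, int]]]] = []
    weights: list[float] = []
    for name, type_fraction in fractions.items():
        genome = by_name[name]
        for variant in genome.variants:
            arr = np.frombuffer(variant.bases.encode("ascii"), dtype=np.uint8)
            templates.append((name, variant.variant_id, arr, _homopolymer_runs(arr)))
            weights.append(type_fraction * variant.copy_fraction)
    weights_arr = np.asarray(weights)
    if weights_arr.sum() <= 0:
        raise ValueError("all template weights are zero")
    probs = weights_arr / weights_arr.sum()

    rng = np.random.default_rng(error_model.seed)
    choices = rng.choice(len(templates), size=design.read_depth, p=probs)
    lengths = np.maximum(
        error_model.length_min,
        np.rint(
            rng.normal(error_model.length_mean, error_model.length_sd, design.read_depth)
        ).astype(int),
    )

    prefix = barcode + forward_primer
    suffix = reverse_complement(reverse_primer)
    reads = []
    truth = {}
    for i, (tmpl_idx, read_len) in enumerate(zip(choices, lengths)):
        name, variant_id, arr, runs = templates[tmpl_idx]
        insert = arr
        if error_model.substitution_rate > 0:
            mask = rng.random(len(insert)) < error_model.substitution_rate
            if mask.any():
                insert = insert.copy()
                for pos in np.nonzero(mask)[0]:
                    insert[pos] = rng.choice(_BASES[_BASES != insert[pos]])
        if error_model.homopolymer_indel_rate > 0 and runs:
            hits = np.nonzero(rng.random(len(runs)) < error_model.homopolymer_indel_rate)[0]
            if hits.size:
                insert = insert.copy() if insert is arr else insert
                # apply right-to-left so run coordinates stay valid
                for run_idx in hits[::-1]:
                    start, end = runs[run_idx]
                    if rng.random() < 0.5 and end - start >= 2:
                        insert = np.delete(insert, start)
                    else:
                        insert = np.insert(insert, start, insert[start])
        bases = prefix + _as_str(insert) + suffix
        bases = bases[: int(read_len)]
        read_id = f"{design.sample_id}_r{i:06d}"
        reads.append((read_id, bases, _synthesize_qualities(len(bases)), barcode))
        truth[read_id] = (name, variant_id)
    return SimSample(
        sample_id=design.sample_id, reads=reads, truth=truth,
        design=design, barcode=barcode,
    )


def dilution_series_designs(
    depth_per_sample: int = 10_000, total_cells: int = 1_000_000
) -> list[MixtureDesign]:
    """The 15 known-composition mixture designs of the dilution series."""
    designs = []
    for row, (percents, cycles) in enumerate(
        zip(DILUTION_SERIES_DESIGN, DILUTION_SERIES_PCR_CYCLES), start=1
    ):
        fractions = {
            name: p / 100.0
            for name, p in zip(DILUTION_SERIES_TYPES, percents)
        }
        designs.append(
            MixtureDesign(
                sample_id=f"S{row:02d}",
                cell_fractions=fractions,
                total_cells=total_cells,
                read_depth=depth_per_sample,
                pcr_cycles=cycles,
            )
        )
    return designs


def make_dilution_series(
    genomes: list[TypeGenome],
    error_model: ErrorModel,
    depth_per_sample: int = 10_000,
) -> list[SimSample]:
    """Simulate the full 15-sample dilution series with per-sample barcodes.

    Sample seeds are derived from the error model's seed so the whole series
    is reproducible from a single integer.
    """
    names = {g.type_name for g in genomes}
    missing = set(DILUTION_SERIES_TYPES) - names
    if missing:
        raise ValueError(f"genomes missing dilution-series types: {sorted(missing)}")
    designs = dilution_series_designs(depth_per_sample)
    barcodes = barcode_set(len(designs))
    samples = []
    for i, design in enumerate(designs):
        model = replace(error_model, seed=(error_model.seed * 100_003 + i) % (2**31 - 1))
        samples.append(simulate_reads(design, genomes, model, barcode=barcodes[i]))
    return samples


# ---------------------------------------------------------------------------
# serialisation


def write_fastq(samples: list[SimSample], path) -> None:
    """Write all samples' reads (barcodes included) to one FASTQ file."""
    with open(path, "w") as handle:
        for sample in samples:
            for read_id, bases, quals, _ in sample.reads:
                qual_string = bytes(q + 33 for q in quals).decode("ascii")
                handle.write(f"@{read_id}\n{bases}\n+\n{qual_string}\n")


def write_truth_table(samples: list[SimSample], path) -> None:
    import pandas as pd

    rows = [
        {
            "read_id": read_id,
            "sample_id": sample.sample_id,
            "type": type_name,
            "variant": variant_id,
        }
        for sample in samples
        for read_id, (type_name, variant_id) in sorted(sample.truth.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_design_table(samples: list[SimSample], path) -> None:
    import pandas as pd

    rows = [
        {
            "sample_id": sample.sample_id,
            "type": name,
            "cell_fraction": fraction,
        }
        for sample in samples
        if sample.design is not None
        for name, fraction in sorted(sample.design.cell_fractions.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_manifest(
    samples: list[SimSample],
    path,
    forward_primer: str = ITS2_FORWARD_PRIMER,
    reverse_primer: str = ITS2_REVERSE_PRIMER,
) -> None:
    import pandas as pd

    rows = [
        {
            "barcode": sample.barcode,
            "sample_id": sample.sample_id,
            "fwd_primer": forward_primer,
            "rev_primer": reverse_primer,
        }
        for sample in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_panel_fasta(genomes: list[TypeGenome], path) -> None:
    with open(path, "w") as handle:
        for genome in genomes:
            for variant in genome.variants:
                handle.write(f">{variant.variant_id} type={genome.type_name}\n")
                handle.write(variant.bases + "\n")
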