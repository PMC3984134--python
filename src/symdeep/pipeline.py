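"""End-to-end pipeline orchestration, configuration and run reporting.

Stages: (optional) simulate -> preprocess -> cluster/select -> map ->
annotate -> prune -> re-map -> quantify -> validate -> haplotypes. Every
stage writes its outputs under the configured output directory, and the
consolidated :class:`RunReport` reconciles read counts across stages
(raw = unassigned + rejected + cleaned; cleaned = mapped + ambiguous +
unmapped) the way a dilution-series accounting table does.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster import (
    cluster_identical,
    screen_homopolymer_references,
    select_references,
    size_histogram,
    write_membership,
)
from .haplotypes import (
    build_network,
    groups_to_frame,
    infer_intragenomic,
    proportion_matrix,
)
from .mapping import (
    AMBIGUOUS,
    MAPPED,
    UNMAPPED,
    ReadMapper,
    ReferencePanel,
    annotate_references,
    annotations_to_frame,
    prune_references,
    type_consensus,
)
from .preprocess import SampleManifest, preprocess, read_fastq, write_clean_fasta
from .quantify import (
    UndefinedGamma,
    assignments_to_counts,
    bootstrap_ci,
    estimate_detection_limit,
    gamma_permutation_p,
    normalize_and_aggregate,
    residual_bias,
)
from .simulate import (
    ErrorModel,
    default_panel,
    make_dilution_series,
    write_design_table,
    write_fastq,
    write_manifest,
    write_panel_fasta,
    write_truth_table,
)

BACKGROUND_MAX_PERCENT = 5.0


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run.

    With ``simulate=True`` the dilution series is generated into
    ``output_dir`` and used as input; otherwise ``reads``, ``manifest``,
    ``panel`` (+ ``panel_sites``) and ``design`` must point to existing
    files. Parameter defaults follow the study design: 150 bp minimum
    length, cluster-size floor 10, 1000 permutations, 1000 bootstrap
    resamples, 85 % high-abundance threshold.
    """

    output_dir: str = "symdeep_out"
    simulate: bool = False
    seed: int = 0
    depth_per_sample: int = 10_000
    copy_numbers: dict[str, int] | None = None

    reads: str | None = None
    manifest: str | None = None
    panel: str | None = None
    panel_sites: str | None = None
    design: str | None = None

    min_length: int = 150
    min_mean_quality: float = 20.0
    max_barcode_mismatches: int = 1
    max_primer_mismatches: int = 2
    min_cluster_size: int = 10
    asymptote_gain: float = 0.01
    min_identity: float = 90.0
    high_threshold: float = 0.85
    alpha: float = 0.05
    n_perm: int = 1000
    n_resamples: int = 1000
    substitution_rate: float = 0.002
    homopolymer_indel_rate: float = 0.003
    use_copy_number_expectation: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("reads", "manifest", "panel", "design"):
                value = getattr(self, name)
                if value is None:
                    raise ConfigError(f"config requires '{name}' unless simulate=true")
                if not Path(value).exists():
                    raise ConfigError(f"{name} path does not exist: {value}")
        if self.min_length < 1 or self.min_cluster_size < 1:
            raise ConfigError("min_length and min_cluster_size must be >= 1")
        if not 0 < self.high_threshold <= 1:
            raise ConfigError("high_threshold must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.n_perm < 1 or self.n_resamples < 1:
            raise ConfigError("n_perm and n_resamples must be >= 1")

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Table-1-style accounting arithmetic (the report layer)


def mapping_efficiency_from_counts(mapped: int, cleaned: int) -> float:
    """Mapped / cleaned, reported to 2 decimals (e.g. 1138/1330 -> 0.86)."""
    if cleaned <= 0:
        raise ValueError("cleaned count must be positive")
    return round(mapped / cleaned, 2)


def quality_retention_percent(cleaned_total: int, raw_total: int) -> float:
    """Percent of raw reads surviving cleaning, 1 dp (80451/115980 -> 69.4)."""
    if raw_total <= 0:
        raise ValueError("raw total must be positive")
    return round(100.0 * cleaned_total / raw_total, 1)


def ambiguous_discard_percent(ambiguous: int, cleaned_total: int) -> float:
    """Percent of cleaned reads discarded for ambiguous mapping, 1 dp."""
    if cleaned_total <= 0:
        raise ValueError("cleaned total must be positive")
    return round(100.0 * ambiguous / cleaned_total, 1)


def reads_after_elimination(mapped_total: int, eliminated: int) -> int:
    """Mapped reads remaining after sample/reference eliminations."""
    if eliminated > mapped_total:
        raise ValueError("cannot eliminate more reads than were mapped")
    return mapped_total - eliminated


@dataclass
class RunReport:
    """Consolidated per-stage accounting and results of one run."""

    version: str
    config_hash: str
    per_sample: list[dict] = field(default_factory=list)
    totals: dict = field(default_factory=dict)
    references_selected: int = 0
    references_screened_out: int = 0
    references_pruned_out: int = 0
    references_final: int = 0
    detection_limit: dict | None = None
    gamma_by_type: dict = field(default_factory=dict)
    gamma_overall: dict | None = None
    haplotype_groups: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def reconciles(self) -> bool:
        for row in self.per_sample:
            if row["cleaned"] != row["mapped"] + row["ambiguous"] + row["unmapped"]:
                return False
        t = self.totals
        return t.get("raw", 0) == (
            t.get("unassigned", 0) + t.get("rejected", 0) + t.get("cleaned", 0)
        )

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=2, sort_keys=True)
            handle.write("\n")

    def summary(self) -> str:
        lines = [
            f"symdeep {self.version} run {self.config_hash}",
            f"references: {self.references_selected} selected, "
            f"{self.references_screened_out} screened out, "
            f"{self.references_pruned_out} pruned, {self.references_final} final",
            "sample\traw\tcleaned\tmapped\tefficiency",
        ]
        for row in self.per_sample:
            lines.append(
                f"{row['sample_id']}\t{row['raw']}\t{row['cleaned']}"
                f"\t{row['mapped']}\t{row['mapping_efficiency']:.2f}"
            )
        if self.detection_limit:
            lines.append(
                f"detection limit cutoff: {self.detection_limit['cutoff']:.3f} %"
            )
        for type_name, result in self.gamma_by_type.items():
            p = result.get("p_value")
            lines.append(
                f"gamma[{type_name}] = {result['gamma']:.2f}"
                + (f" (p = {p:.3f})" if p is not None else "")
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# stage helpers


def load_design_table(path) -> dict[str, dict[str, float]]:
    frame = pd.read_csv(path, sep="\t")
    designs: dict[str, dict[str, float]] = {}
    for row in frame.itertuples():
        designs.setdefault(str(row.sample_id), {})[str(row.type)] = float(
            row.cell_fraction
        )
    return designs


def expected_percent_table(
    designs: dict[str, dict[str, float]],
    copy_numbers: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Expected type percentages per sample (optionally copy-number weighted)."""
    rows = {}
    for sample_id, fractions in designs.items():
        if copy_numbers:
            weights = {t: f * copy_numbers.get(t, 1) for t, f in fractions.items()}
            total = sum(weights.values())
            rows[sample_id] = {t: 100.0 * w / total for t, w in weights.items()}
        else:
            rows[sample_id] = {t: 100.0 * f for t, f in fractions.items()}
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0).sort_index()


def read_clean_fasta(directory) -> dict[str, list]:
    from Bio import SeqIO

    from .preprocess import CleanRead

    clean: dict[str, list] = {}
    for path in sorted(Path(directory).glob("*.clean.fasta")):
        sample_id = path.name.removesuffix(".clean.fasta")
        clean[sample_id] = [
            CleanRead(record.id, sample_id, str(record.seq))
            for record in SeqIO.parse(str(path), "fasta")
        ]
    return clean


def assignments_frame(
    assignments_by_sample: dict[str, list],
) -> pd.DataFrame:
    rows = [
        {
            "sample_id": sample_id,
            "read_id": a.read_id,
            "status": a.status,
            "reference_id": a.reference_id or "",
            "score": a.score if a.score is not None else "",
            "identity": a.identity if a.identity is not None else "",
        }
        for sample_id, assignments in assignments_by_sample.items()
        for a in assignments
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "read_id", "status", "reference_id", "score", "identity"]
    )


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and write all outputs under ``config.output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    report = RunReport(version=__version__, config_hash=config.content_hash())

    # --- inputs (simulated or on disk)
    if config.simulate:
        genomes, panel = default_panel(
            seed=config.seed, copy_numbers=config.copy_numbers
        )
        error_model = ErrorModel(
            substitution_rate=config.substitution_rate,
            homopolymer_indel_rate=config.homopolymer_indel_rate,
            seed=config.seed,
        )
        samples = make_dilution_series(
            genomes, error_model, depth_per_sample=config.depth_per_sample
        )
        write_fastq(samples, out / "reads.fastq")
        write_manifest(samples, out / "manifest.tsv")
        write_truth_table(samples, out / "truth.tsv")
        write_design_table(samples, out / "design.tsv")
        write_panel_fasta(genomes, out / "panel_variants.fasta")
        panel.write(out / "panel.fasta", out / "panel_sites.tsv")
        reads_path = out / "reads.fastq"
        manifest_path = out / "manifest.tsv"
        design_path = out / "design.tsv"
    else:
        panel = ReferencePanel.from_files(config.panel, config.panel_sites)
        reads_path = Path(config.reads)
        manifest_path = Path(config.manifest)
        design_path = Path(config.design)

    # --- preprocess
    raw_reads = read_fastq(reads_path)
    manifest = SampleManifest.from_tsv(manifest_path)
    clean, pre_report = preprocess(
        raw_reads,
        manifest,
        max_barcode_mismatches=config.max_barcode_mismatches,
        max_primer_mismatches=config.max_primer_mismatches,
        min_length=config.min_length,
        min_mean_quality=config.min_mean_quality,
    )
    write_clean_fasta(clean, out / "clean")
    with open(out / "preprocess_report.json", "w") as handle:
        json.dump(dataclasses.asdict(pre_report), handle, indent=2, sort_keys=True)

    # --- cluster and select references
    pooled = [read for reads in clean.values() for read in reads]
    if not pooled:
        raise ConfigError("no reads survived preprocessing")
    clusters = cluster_identical(pooled)
    histogram = size_histogram(clusters)
    histogram.to_frame().to_csv(out / "cluster_histogram.tsv", sep="\t", index=False)
    write_membership(clusters, out / "cluster_membership.tsv")
    selected = select_references(
        clusters,
        histogram,
        min_cluster_size=config.min_cluster_size,
        asymptote_gain=config.asymptote_gain,
    )
    report.references_selected = len(selected)
    screened, screen_log = screen_homopolymer_references(selected)
    report.references_screened_out = len(screen_log)
    pd.DataFrame(screen_log).to_csv(out / "screening_log.tsv", sep="\t", index=False)
    screened.write_fasta(out / "references.fasta")

    # --- map
    mapper = ReadMapper(screened, min_identity=config.min_identity)
    assignments = {sample_id: mapper.map(reads) for sample_id, reads in clean.items()}
    assignments_frame(assignments).to_csv(out / "assignments.tsv", sep="\t", index=False)

    # --- annotate and prune
    annotations = annotate_references(screened, panel)
    annotations_to_frame(annotations).to_csv(out / "annotations.tsv", sep="\t", index=False)
    designs = load_design_table(design_path)
    counts = assignments_to_counts(assignments)
    pruned, prune_log = prune_references(
        screened, annotations, counts, designs, high_threshold=config.high_threshold
    )
    report.references_pruned_out = sum(
        1 for entry in prune_log if entry["action"] == "removed"
    )
    report.warnings.extend(
        entry["detail"] for entry in prune_log if entry["action"] == "warning"
    )
    pd.DataFrame(prune_log).to_csv(out / "pruning_log.tsv", sep="\t", index=False)
    pruned.write_fasta(out / "references_pruned.fasta")
    report.references_final = len(pruned)

    # --- re-map against the pruned library (shares the mapper's caches)
    mapper_pruned = mapper.with_references(pruned.ids())
    assignments = {
        sample_id: mapper_pruned.map(reads) for sample_id, reads in clean.items()
    }
    assignments_frame(assignments).to_csv(
        out / "assignments_pruned.tsv", sep="\t", index=False
    )
    annotations = [a for a in annotations if a.reference_id in set(pruned.ids())]

    # --- per-type consensus (reporting only)
    sizes = {r[0]: r[2] for r in pruned.references}
    with open(out / "consensus.fasta", "w") as handle:
        for type_name in sorted({a.type_name for a in annotations if a.type_name}):
            refs = [
                (r[0], r[1])
                for r in pruned.references
                if any(
                    a.reference_id == r[0] and a.type_name == type_name
                    for a in annotations
                )
            ]
            consensus = type_consensus(refs, sizes)
            handle.write(f">{type_name}_consensus\n{consensus}\n")

    # --- quantify
    counts = assignments_to_counts(assignments)
    abundance = normalize_and_aggregate(counts, annotations)
    counts.to_csv(out / "counts.tsv", sep="\t")
    abundance.reference_percents.to_csv(out / "reference_percents.tsv", sep="\t")
    abundance.type_percents.to_csv(out / "type_percents.tsv", sep="\t")

    # --- accounting
    for sample_id in sorted(clean):
        sample_assignments = assignments[sample_id]
        mapped = sum(1 for a in sample_assignments if a.status == MAPPED)
        ambiguous = sum(1 for a in sample_assignments if a.status == AMBIGUOUS)
        unmapped = sum(1 for a in sample_assignments if a.status == UNMAPPED)
        cleaned = len(sample_assignments)
        report.per_sample.append(
            {
                "sample_id": sample_id,
                "raw": pre_report.per_sample_raw.get(sample_id, cleaned),
                "cleaned": cleaned,
                "mapped": mapped,
                "ambiguous": ambiguous,
                "unmapped": unmapped,
                "mapping_efficiency": (
                    mapping_efficiency_from_counts(mapped, cleaned) if cleaned else 0.0
                ),
            }
        )
    report.totals = {
        "raw": pre_report.raw,
        "unassigned": pre_report.unassigned,
        "rejected": pre_report.no_forward_primer
        + pre_report.too_short
        + pre_report.low_quality,
        "cleaned": pre_report.cleaned,
        "mapped": sum(r["mapped"] for r in report.per_sample),
        "ambiguous": sum(r["ambiguous"] for r in report.per_sample),
        "unmapped": sum(r["unmapped"] for r in report.per_sample),
        "quality_retention_percent": quality_retention_percent(
            pre_report.cleaned, pre_report.raw
        ),
    }
    if report.totals["cleaned"]:
        report.totals["ambiguous_discard_percent"] = ambiguous_discard_percent(
            report.totals["ambiguous"], report.totals["cleaned"]
        )

    # --- validate against the known design
    expected = expected_percent_table(
        designs, config.copy_numbers if config.use_copy_number_expectation else None
    )
    validation = validate_against_design(
        abundance.type_percents,
        expected,
        alpha=config.alpha,
        n_perm=config.n_perm,
        n_resamples=config.n_resamples,
        seed=config.seed,
    )
    report.gamma_by_type = validation["gamma_by_type"]
    report.gamma_overall = validation["gamma_overall"]
    with open(out / "validation.json", "w") as handle:
        json.dump(validation, handle, indent=2, sort_keys=True, default=float)
    _write_background_plot(abundance.type_percents, expected, out, config)
    try:
        limit = estimate_detection_limit(abundance, designs)
        report.detection_limit = {
            "mean_fp": limit.mean_fp,
            "se_fp": limit.se_fp,
            "cutoff": limit.cutoff,
            "n_values": len(limit.fp_values),
            "outliers": limit.outliers,
        }
    except ValueError as err:
        report.warnings.append(f"detection limit not estimated: {err}")

    # --- haplotypes
    # grouping signal: a haplotype's percent of total mapped reads tracks its
    # genome's abundance across the dilution series, so same-genome
    # haplotypes co-vary while different genomes do not
    type_of = {a.reference_id: a.type_name for a in annotations}
    totals_by_ref = counts.sum(axis=0)
    if len(abundance.reference_percents.columns) >= 2 and len(counts) >= 3:
        try:
            groups = infer_intragenomic(
                abundance.reference_percents.fillna(0.0),
                alpha=config.alpha,
                n_perm=config.n_perm,
                seed=config.seed,
            )
            groups_to_frame(groups).to_csv(
                out / "haplotype_groups.tsv", sep="\t", index=False
            )
            report.haplotype_groups = {
                f"group_{i + 1}": sorted(g) for i, g in enumerate(groups.groups)
            }
        except ValueError as err:
            report.warnings.append(f"haplotype grouping skipped: {err}")
    for type_name in sorted({t for t in type_of.values() if t}):
        member_refs = [
            r
            for r, t in type_of.items()
            if t == type_name and r in abundance.reference_percents.columns
        ]
        if len(member_refs) < 2:
            continue
        # within-type read proportions (rows sum to 100 where the type is present)
        proportion_matrix(abundance.reference_percents[member_refs]).to_csv(
            out / f"haplotype_proportions_{type_name}.tsv", sep="\t"
        )
        sequences = {r[0]: r[1] for r in pruned.references if r[0] in member_refs}
        network = build_network(
            sequences, {r: int(totals_by_ref.get(r, 0)) for r in member_refs}
        )
        network.write(
            out / f"haplotype_network_{type_name}.tsv",
            out / f"haplotype_network_{type_name}.graphml",
        )

    report.to_json(out / "report.json")
    with open(out / "summary.txt", "w") as handle:
        handle.write(report.summary() + "\n")
    return report


def _write_background_plot(type_percents, expected, out: Path, config) -> None:
    """Observed-vs-expected scatter with bootstrap CI bars per level."""
    from .quantify import plot_observed_vs_expected

    obs, exp = [], []
    for type_name in expected.columns:
        if type_name not in type_percents.columns:
            continue
        for sample_id in expected.index:
            if sample_id not in type_percents.index:
                continue
            e = float(expected.loc[sample_id, type_name])
            if e > BACKGROUND_MAX_PERCENT:
                continue
            o = type_percents.loc[sample_id, type_name]
            obs.append(0.0 if pd.isna(o) else float(o))
            exp.append(e)
    if not obs:
        return
    ci_by_level = {
        level: bootstrap_ci(
            [o for o, e in zip(obs, exp) if e == level],
            n_resamples=config.n_resamples, seed=config.seed,
        )
        for level in sorted(set(exp))
    }
    plot_observed_vs_expected(obs, exp, out / "observed_vs_expected.png", ci_by_level)


def validate_against_design(
    type_percents: pd.DataFrame,
    expected: pd.DataFrame,
    background_max: float = BACKGROUND_MAX_PERCENT,
    alpha: float = 0.05,
    n_perm: int = 1000,
    n_resamples: int = 1000,
    seed: int = 0,
) -> dict:
    """Gamma correlations, bootstrap CIs and residual bias on background cells.

    A background cell is a (sample, type) pair whose expected percentage is
    at most ``background_max`` (the 0-5 % range). Gamma is computed per
    type and over all background cells pooled, each with a one-sided
    permutation p-value.
    """
    samples = [s for s in expected.index if s in type_percents.index]
    results: dict = {"gamma_by_type": {}, "gamma_overall": None,
                     "bootstrap_by_level": {}, "residuals": None}
    pooled_obs: list[float] = []
    pooled_exp: list[float] = []
    for type_name in expected.columns:
        if type_name not in type_percents.columns:
            continue
        obs, exp = [], []
        for sample_id in samples:
            e = float(expected.loc[sample_id, type_name])
            if e > background_max:
                continue
            o = type_percents.loc[sample_id, type_name]
            obs.append(0.0 if pd.isna(o) else float(o))
            exp.append(e)
        pooled_obs.extend(obs)
        pooled_exp.extend(exp)
        if len(obs) >= 2 and len(set(exp)) > 1:
            try:
                result = gamma_permutation_p(exp, obs, n_iter=n_perm, seed=seed)
                results["gamma_by_type"][type_name] = {
                    "gamma": result.gamma,
                    "p_value": result.p_value,
                    "n_concordant": result.n_concordant,
                    "n_discordant": result.n_discordant,
                    "n_cells": len(obs),
                }
            except UndefinedGamma:
                results["gamma_by_type"][type_name] = {"gamma": None, "p_value": None}
    if pooled_obs:
        try:
            overall = gamma_permutation_p(pooled_exp, pooled_obs, n_iter=n_perm, seed=seed)
            results["gamma_overall"] = {
                "gamma": overall.gamma,
                "p_value": overall.p_value,
                "n_cells": len(pooled_obs),
            }
        except UndefinedGamma:
            pass
        for level in sorted(set(pooled_exp)):
            values = [o for o, e in zip(pooled_obs, pooled_exp) if e == level]
            ci = bootstrap_ci(values, n_resamples=n_resamples, seed=seed)
            results["bootstrap_by_level"][str(level)] = {
                "mean": ci.mean, "lower": ci.lower, "upper": ci.upper,
                "n": len(values),
            }
        if len(set(pooled_exp)) > 1 and len(pooled_obs) >= 3:
            summary = residual_bias(pooled_obs, pooled_exp)
            results["residuals"] = {
                "slope": summary.slope,
                "intercept": summary.intercept,
                "per_level": summary.per_level.to_dict(orient="records"),
            }
    return results
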