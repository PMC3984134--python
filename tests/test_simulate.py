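"""Simulator: panel construction, mixture expectations, read generation."""

import numpy as np
import pytest

from symdeep._align import hamming
from symdeep.simulate import (
    DILUTION_SERIES_TYPES,
    ErrorModel,
    MixtureDesign,
    TypeGenome,
    VariantSequence,
    barcode_set,
    build_type_panel,
    default_panel,
    dilution_series_designs,
    expected_read_fractions,
    make_dilution_series,
    simulate_reads,
    write_fastq,
)


class TestTypes:
    def test_variant_requires_positive_copy_fraction(self):
        with pytest.raises(ValueError):
            VariantSequence("v", "ACGT", 0.0)
        with pytest.raises(ValueError):
            VariantSequence("v", "", 1.0)

    def test_genome_copy_fractions_must_sum_to_one(self):
        good = TypeGenome("X", (VariantSequence("a", "ACGT", 0.5),
                                VariantSequence("b", "ACGA", 0.5)))
        assert good.copy_number == 1000
        with pytest.raises(ValueError):
            TypeGenome("X", (VariantSequence("a", "ACGT", 0.6),
                             VariantSequence("b", "ACGA", 0.5)))
        with pytest.raises(ValueError):
            TypeGenome("X", (VariantSequence("a", "ACGT", 0.5),
                             VariantSequence("a", "ACGA", 0.5)))

    def test_design_fractions_validated(self):
        with pytest.raises(ValueError):
            MixtureDesign("s", {"A": 0.5, "B": 0.4})
        with pytest.raises(ValueError):
            MixtureDesign("s", {"A": 1.2, "B": -0.2})
        with pytest.raises(ValueError):
            MixtureDesign("s", {"A": 1.0}, read_depth=0)


class TestBuildTypePanel:
    def test_single_variant_identity_case(self):
        genomes = build_type_panel(
            n_types=2, n_variants_per_type=1, divergence_within_type=0.0, seed=3
        )
        for genome in genomes:
            assert len(genome.variants) == 1
            assert genome.variants[0].copy_fraction == 1.0

    def test_determinism(self):
        a = build_type_panel(seed=9)
        b = build_type_panel(seed=9)
        assert a == b

    def test_divergence_ordering_rejected(self):
        with pytest.raises(ValueError):
            build_type_panel(divergence_between_types=0.01, divergence_within_type=0.05)
        with pytest.raises(ValueError):
            build_type_panel(n_types=0)

    def test_between_type_divergence_enforced(self):
        genomes = build_type_panel(
            n_types=3, n_variants_per_type=1, divergence_between_types=0.1, seed=2
        )
        length = len(genomes[0].variants[0].bases)
        for i, a in enumerate(genomes):
            for b in genomes[i + 1 :]:
                assert hamming(a.variants[0].bases, b.variants[0].bases) >= 0.1 * length


class TestDefaultPanel:
    def test_c1_c3_single_diagnostic_substitution(self, panel_and_genomes):
        genomes, panel = panel_and_genomes
        c1, c3 = panel.entries["C1"], panel.entries["C3"]
        assert hamming(c1, c3) == 1
        site = panel.diagnostic_sites[0]
        assert c1[site.position - 1] == "C"
        assert c3[site.position - 1] == "T"

    def test_other_type_pairs_diverge_ten_percent(self, panel):
        names = list(panel.entries)
        length = len(panel.entries["C1"])
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if {a, b} == {"C1", "C3"}:
                    continue
                assert hamming(panel.entries[a], panel.entries[b]) >= 0.1 * length

    def test_deterministic(self):
        g1, p1 = default_panel(seed=4)
        g2, p2 = default_panel(seed=4)
        assert g1 == g2
        assert p1.entries == p2.entries


class TestExpectedReadFractions:
    def test_equal_copy_numbers_reproduce_cell_fractions(self, genomes):
        design = MixtureDesign(
            "s", {"A13": 0.997, "D1": 0.001, "C1": 0.001, "C3": 0.001}
        )
        fractions = expected_read_fractions(design, genomes)
        assert fractions == pytest.approx(design.cell_fractions, abs=1e-12)

    def test_copy_number_weighting(self):
        genomes = [
            TypeGenome("A", (VariantSequence("a", "ACGT" * 60, 1.0),), copy_number=1000),
            TypeGenome("B", (VariantSequence("b", "TGCA" * 60, 1.0),), copy_number=3000),
        ]
        design = MixtureDesign("s", {"A": 0.5, "B": 0.5})
        fractions = expected_read_fractions(design, genomes)
        assert fractions["A"] == pytest.approx(0.25)
        assert fractions["B"] == pytest.approx(0.75)

    def test_zero_cell_fraction_gives_zero_reads(self, genomes):
        design = MixtureDesign("s", {"A13": 1.0, "D1": 0.0, "C1": 0.0, "C3": 0.0})
        fractions = expected_read_fractions(design, genomes)
        assert fractions["D1"] == 0.0
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_type_rejected(self, genomes):
        with pytest.raises(KeyError):
            expected_read_fractions(MixtureDesign("s", {"Z9": 1.0}), genomes)


class TestSimulateReads:
    def test_zero_error_reads_match_panel_variants(self, genomes, zero_error):
        design = MixtureDesign("s", {t: 0.25 for t in DILUTION_SERIES_TYPES},
                               read_depth=200)
        sample = simulate_reads(design, genomes, zero_error, barcode="",
                                forward_primer="", reverse_primer="")
        variant_seqs = {
            v.variant_id: v.bases for g in genomes for v in g.variants
        }
        for read_id, bases, quals, _ in sample.reads:
            _, variant_id = sample.truth[read_id]
            assert bases == variant_seqs[variant_id]
            assert len(quals) == len(bases)

    def test_same_seed_identical_sample(self, genomes):
        design = MixtureDesign("s", {t: 0.25 for t in DILUTION_SERIES_TYPES},
                               read_depth=100)
        model = ErrorModel(seed=42)
        a = simulate_reads(design, genomes, model)
        b = simulate_reads(design, genomes, model)
        assert a.reads == b.reads
        assert a.truth == b.truth

    def test_type_counts_within_binomial_error(self, genomes, zero_error):
        # dominant-type mixture at depth 10,000 with equal copy numbers: each
        # type's read count should sit within 3 binomial SDs of expectation
        design = MixtureDesign(
            "s", {"A13": 0.97, "D1": 0.01, "C1": 0.01, "C3": 0.01},
            read_depth=10_000,
        )
        sample = simulate_reads(design, genomes, zero_error)
        counts = {t: 0 for t in DILUTION_SERIES_TYPES}
        for type_name, _ in sample.truth.values():
            counts[type_name] += 1
        for type_name, p in design.cell_fractions.items():
            expected = design.read_depth * p
            sd = np.sqrt(design.read_depth * p * (1 - p))
            assert abs(counts[type_name] - expected) <= 3 * sd

    def test_read_fraction_convergence_at_high_depth(self, genomes, zero_error):
        design = MixtureDesign(
            "s", {"A13": 0.5, "D1": 0.3, "C1": 0.15, "C3": 0.05},
            read_depth=100_000,
        )
        sample = simulate_reads(design, genomes, zero_error)
        expected = expected_read_fractions(design, genomes)
        counts = {t: 0 for t in DILUTION_SERIES_TYPES}
        for type_name, _ in sample.truth.values():
            counts[type_name] += 1
        for type_name, fraction in expected.items():
            assert abs(counts[type_name] / design.read_depth - fraction) < 0.005

    def test_empty_design_rejected(self, genomes, zero_error):
        with pytest.raises(ValueError):
            simulate_reads(MixtureDesign("s", {}), genomes, zero_error)


class TestDilutionSeries:
    def test_designs_match_study_table(self):
        designs = dilution_series_designs()
        assert len(designs) == 15
        assert designs[0].cell_fractions == pytest.approx(
            {"A13": 0.997, "D1": 0.001, "C1": 0.001, "C3": 0.001}
        )
        assert designs[4].cell_fractions == pytest.approx(
            {"A13": 0.97, "D1": 0.01, "C1": 0.01, "C3": 0.01}
        )
        assert designs[12].cell_fractions == pytest.approx(
            {"A13": 1.0, "D1": 0.0, "C1": 0.0, "C3": 0.0}
        )
        for design in designs:
            assert sum(design.cell_fractions.values()) == pytest.approx(1.0)
            assert design.total_cells == 1_000_000

    def test_sample_depth_and_barcodes(self, genomes, zero_error):
        samples = make_dilution_series(genomes, zero_error, depth_per_sample=50)
        assert len(samples) == 15
        barcodes = {s.barcode for s in samples}
        assert len(barcodes) == 15
        for sample in samples:
            assert len(sample.reads) == 50
            assert all(bases.startswith(sample.barcode)
                       for _, bases, _, _ in sample.reads)

    def test_fastq_output_deterministic(self, genomes, tmp_path):
        model = ErrorModel(seed=17)
        for name in ("a.fastq", "b.fastq"):
            samples = make_dilution_series(genomes, model, depth_per_sample=20)
            write_fastq(samples, tmp_path / name)
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()


def test_barcode_set_pairwise_distance():
    codes = barcode_set(15)
    assert len(set(codes)) == 15
    for i, a in enumerate(codes):
        assert len(a) == 8
        for b in codes[i + 1 :]:
            assert hamming(a, b) >= 3
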