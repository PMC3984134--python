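"""Read mapping, annotation, reference pruning and consensus building."""

import numpy as np
import pandas as pd
import pytest

from symdeep.cluster import ReferenceSet
from symdeep.mapping import (
    AMBIGUOUS,
    MAPPED,
    UNMAPPED,
    DiagnosticSite,
    ReadMapper,
    ReferencePanel,
    annotate_references,
    map_reads,
    mapping_efficiency,
    prune_references,
    type_consensus,
)
from symdeep.preprocess import CleanRead
from symdeep.simulate import MixtureDesign, simulate_reads


def _rng_seq(rng, length=300):
    return "".join(rng.choice(list("ACGT"), length))


@pytest.fixture()
def two_refs():
    rng = np.random.default_rng(5)
    a = _rng_seq(rng)
    b = list(a)
    for pos in rng.choice(len(a), 30, replace=False):  # ~10 % diverged
        b[pos] = "ACGT".replace(b[pos], "")[0]
    return [("refA", a), ("refB", "".join(b))]


class TestMapReads:
    def test_identical_read_maps_uniquely(self, two_refs):
        reads = [CleanRead("r1", "s", two_refs[0][1])]
        (assignment,) = map_reads(reads, two_refs)
        assert assignment.status == MAPPED
        assert assignment.reference_id == "refA"
        assert assignment.score == len(two_refs[0][1])

    def test_equidistant_read_is_ambiguous(self):
        refs = [("refA", "ACGTACGTACGT" * 20), ("refB", "ACGTACGTACGT" * 20)]
        refs = [("refA", refs[0][1] + "A"), ("refB", refs[0][1] + "C")]
        # a read that stops before the discriminating base ties both
        reads = [CleanRead("r1", "s", "ACGTACGTACGT" * 20)]
        (assignment,) = map_reads(reads, refs)
        assert assignment.status == AMBIGUOUS

    def test_low_identity_read_unmapped(self, two_refs):
        rng = np.random.default_rng(9)
        reads = [CleanRead("r1", "s", _rng_seq(rng, 250))]
        (assignment,) = map_reads(reads, two_refs, min_identity=90.0)
        assert assignment.status == UNMAPPED

    def test_zero_error_reads_recover_truth_variant(self, genomes, zero_error):
        design = MixtureDesign("s", {t: 0.25 for t in ("A13", "D1", "C1", "C3")},
                               read_depth=400)
        sample = simulate_reads(design, genomes, zero_error, barcode="",
                                forward_primer="", reverse_primer="")
        references = [
            (v.variant_id, v.bases) for g in genomes for v in g.variants
        ]
        reads = [CleanRead(r[0], "s", r[1]) for r in sample.reads]
        assignments = map_reads(reads, references)
        for assignment in assignments:
            assert assignment.status == MAPPED
            assert assignment.reference_id == sample.truth[assignment.read_id][1]

    def test_statuses_partition_reads(self, genomes):
        from symdeep.simulate import ErrorModel

        design = MixtureDesign("s", {t: 0.25 for t in ("A13", "D1", "C1", "C3")},
                               read_depth=300)
        sample = simulate_reads(design, genomes, ErrorModel(seed=8), barcode="")
        references = [(v.variant_id, v.bases) for g in genomes for v in g.variants]
        reads = [CleanRead(r[0], "s", r[1][28:]) for r in sample.reads]
        assignments = map_reads(reads, references)
        statuses = {a.status for a in assignments}
        assert statuses <= {MAPPED, AMBIGUOUS, UNMAPPED}
        assert len(assignments) == len(reads)

    def test_restriction_shares_caches_and_never_raises_ambiguity(
        self, genomes, zero_error
    ):
        design = MixtureDesign("s", {t: 0.25 for t in ("A13", "D1", "C1", "C3")},
                               read_depth=300)
        sample = simulate_reads(design, genomes, zero_error, barcode="",
                                forward_primer="", reverse_primer="")
        references = [(v.variant_id, v.bases) for g in genomes for v in g.variants]
        reads = [CleanRead(r[0], "s", r[1]) for r in sample.reads]
        mapper = ReadMapper(references)
        before = mapper.map(reads)
        keep = [r[0] for r in references if not r[0].startswith("C3")]
        after = mapper.with_references(keep).map(reads)
        ambiguous_before = sum(a.status == AMBIGUOUS for a in before)
        ambiguous_after = sum(a.status == AMBIGUOUS for a in after)
        assert ambiguous_after <= ambiguous_before


class TestMappingEfficiency:
    @pytest.mark.parametrize(
        "mapped,total,expected",
        [(1138, 1330, 0.86), (2186, 2410, 0.91)],
    )
    def test_study_table_values(self, mapped, total, expected):
        from symdeep.mapping import ReadAssignment

        assignments = [
            ReadAssignment(f"m{i}", MAPPED, reference_id="x") for i in range(mapped)
        ] + [
            ReadAssignment(f"a{i}", AMBIGUOUS) for i in range(total - mapped)
        ]
        assert round(mapping_efficiency(assignments), 2) == expected

    def test_all_mapped(self):
        from symdeep.mapping import ReadAssignment

        assignments = [ReadAssignment("r", MAPPED, reference_id="x")]
        assert mapping_efficiency(assignments) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mapping_efficiency([])


class TestAnnotateReferences:
    def test_exact_panel_match(self, panel):
        refs = [("ref1", panel.entries["D1"])]
        (annotation,) = annotate_references(refs, panel)
        assert annotation.type_name == "D1"
        assert annotation.percent_identity == 100.0

    def test_diagnostic_site_breaks_c1_c3_tie(self, panel):
        # panel C1 and C3 differ by exactly the diagnostic SNP, so either
        # sequence ties both entries on identity and the site decides
        for type_name in ("C1", "C3"):
            refs = [("ref", panel.entries[type_name])]
            (annotation,) = annotate_references(refs, panel)
            assert annotation.type_name == type_name

    def test_diverged_reference_recovers_source_type(self, genomes, panel):
        for genome in genomes:
            for variant in genome.variants[1:]:
                (annotation,) = annotate_references(
                    [(variant.variant_id, variant.bases)], panel
                )
                assert annotation.type_name == genome.type_name

    def test_unrelated_sequence_flagged(self, panel):
        rng = np.random.default_rng(3)
        (annotation,) = annotate_references([("junk", _rng_seq(rng))], panel)
        assert annotation.flagged
        assert annotation.type_name is None

    def test_panel_order_invariance(self, genomes, panel):
        refs = [(v.variant_id, v.bases) for g in genomes for v in g.variants]
        forward = annotate_references(refs, panel)
        shuffled = ReferencePanel(
            entries=dict(reversed(list(panel.entries.items()))),
            diagnostic_sites=panel.diagnostic_sites,
        )
        backward = annotate_references(refs, shuffled)
        assert [(a.reference_id, a.type_name) for a in forward] == [
            (a.reference_id, a.type_name) for a in backward
        ]


class TestPruneReferences:
    @pytest.fixture()
    def pruning_fixture(self):
        from symdeep.mapping import TypeAnnotation

        refs = ReferenceSet(
            [("X1", "A" * 200, 100), ("X2", "A" * 199 + "C", 50),
             ("Y1", "G" * 200, 80)]
        )
        annotations = [
            TypeAnnotation("X1", "X", 100.0),
            TypeAnnotation("X2", "X", 99.5),
            TypeAnnotation("Y1", "Y", 100.0),
        ]
        counts = pd.DataFrame(
            {"X1": {"hiX": 500, "hiY": 1}, "X2": {"hiX": 0, "hiY": 0},
             "Y1": {"hiX": 2, "hiY": 700}}
        )
        designs = {"hiX": {"X": 0.97, "Y": 0.03}, "hiY": {"X": 0.0, "Y": 1.0}}
        return refs, annotations, counts, designs

    def test_reference_absent_from_high_sample_removed(self, pruning_fixture):
        refs, annotations, counts, designs = pruning_fixture
        pruned, log = prune_references(refs, annotations, counts, designs)
        assert sorted(pruned.ids()) == ["X1", "Y1"]
        removed = [e for e in log if e["action"] == "removed"]
        assert removed[0]["reference_id"] == "X2"
        assert removed[0]["triggering_sample"] == "hiX"

    def test_reference_present_in_all_high_samples_kept(self, pruning_fixture):
        refs, annotations, counts, designs = pruning_fixture
        pruned, _ = prune_references(refs, annotations, counts, designs)
        assert "X1" in pruned.ids()
        assert "Y1" in pruned.ids()

    def test_type_without_high_sample_warned_and_kept(self, pruning_fixture):
        refs, annotations, counts, _ = pruning_fixture
        designs = {"low": {"X": 0.5, "Y": 0.5}}
        pruned, log = prune_references(refs, annotations, counts, designs)
        assert len(pruned) == 3
        assert any(e["action"] == "warning" for e in log)

    def test_empty_reference_set(self):
        pruned, log = prune_references(
            ReferenceSet([]), [], pd.DataFrame(), {"s": {"X": 1.0}}
        )
        assert len(pruned) == 0


class TestTypeConsensus:
    def test_single_reference_is_its_own_consensus(self):
        assert type_consensus([("a", "ACGTACGT")]) == "ACGTACGT"

    def test_majority_base_wins(self):
        seqs = [("a", "ACGTACGTAA"), ("b", "ACGTACGTAA"), ("c", "ACGTACCTAA")]
        assert type_consensus(seqs) == "ACGTACGTAA"

    def test_matches_column_majority_oracle(self, genomes):
        # substitution-only variants: brute-force per-column majority vote
        d1 = next(g for g in genomes if g.type_name == "D1")
        anchor = d1.variants[0].bases
        same_length = [
            (v.variant_id, v.bases)
            for v in d1.variants
            if len(v.bases) == len(anchor)
        ]
        assert len(same_length) >= 2  # holds for the session panel seed
        sizes = {ref_id: 1000 - i for i, (ref_id, _) in enumerate(same_length)}
        consensus = type_consensus(same_length, sizes)
        expected = []
        for col in range(len(anchor)):
            bases = [seq[col] for _, seq in same_length]
            counts = {b: bases.count(b) for b in set(bases)}
            best = max(counts.values())
            top = [b for b, c in counts.items() if c == best]
            expected.append(anchor[col] if anchor[col] in top else sorted(top)[0])
        assert consensus == "".join(expected)
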