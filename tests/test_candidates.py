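import numpy as np
import pytest

from conftest import random_sequence
from srnascan.candidates import (
    CallerConfig,
    annotate_candidate,
    assign_ids,
    call_candidates,
    external_evidence_for,
    filter_candidates,
    import_external_evidence,
    NcRNACandidate,
    seed_loci,
)
from srnascan.io_formats import (
    AnnotationSet,
    FeatureAnnotation,
    FormatError,
    GenomeSequence,
    ReadAlignment,
    write_candidate_table,
)
from srnascan.rnaseq import LocusExpression, build_coverage
from srnascan.tracks import EvidenceTrack, LocalStructure, local_gc_track


def reads_over(start, end, strand="+", n=10, lib="plus_lib", tag="r"):
    return [
        ReadAlignment("g", start, end, strand, lib, f"{tag}{i}") for i in range(n)
    ]


GENOME = GenomeSequence("g", random_sequence(2000, 0.43, seed=0))


class TestSeedLoci:
    def test_no_signal_no_seeds(self):
        cov = build_coverage([], GENOME)
        assert seed_loci(cov, [], CallerConfig()) == []

    def test_expressed_locus_seeds_covered_region(self):
        cov = build_coverage(reads_over(400, 460), GENOME)
        seeds = seed_loci(cov, [], CallerConfig())
        assert seeds == [(400, 460, "+")]

    def test_nearby_runs_merged_within_gap(self):
        cov = build_coverage(
            reads_over(100, 150) + reads_over(155, 200, tag="s"), GENOME
        )
        seeds = seed_loci(cov, [], CallerConfig(seed_merge_gap=20))
        assert seeds == [(100, 200, "+")]

    def test_structure_hits_become_seeds_and_merge(self):
        cov = build_coverage(reads_over(100, 160), GENOME)
        hit = LocalStructure(140, 210, "+", -20.0, ".", -4.0)
        seeds = seed_loci(cov, [hit], CallerConfig())
        assert seeds == [(100, 210, "+")]


class TestFilterCandidates:
    ANN = AnnotationSet(
        genome_id="g",
        features=[
            FeatureAnnotation("cds1", "CDS", 500, 800, "+"),
            FeatureAnnotation("trna1", "tRNA", 1000, 1076, "+"),
            FeatureAnnotation("rna1", "ncRNA", 1500, 1570, "+"),
        ],
    )

    def test_short_seed_removed(self):
        assert filter_candidates([(10, 34, "+")], self.ANN, CallerConfig()) == []

    def test_single_nt_cds_overlap_removed(self):
        out = filter_candidates([(460, 501, "+")], self.ANN, CallerConfig())
        assert out == []

    def test_either_strand_overlap_blocks(self):
        assert filter_candidates([(600, 700, "-")], self.ANN, CallerConfig()) == []

    def test_trna_overlap_rerouted_when_expressed(self):
        cov = build_coverage(reads_over(1000, 1076, n=5), GENOME)
        out = filter_candidates([(995, 1080, "+")], self.ANN, CallerConfig(), cov)
        assert out == [(995, 1080, "+", "tRNA_locus", "trna1")]

    def test_known_ncrna_kept_with_name(self):
        out = filter_candidates([(1500, 1570, "+")], self.ANN, CallerConfig())
        assert out == [(1500, 1570, "+", "known_ncRNA", "rna1")]

    def test_intergenic_seed_stays_novel(self):
        out = filter_candidates([(100, 200, "+")], self.ANN, CallerConfig())
        assert out == [(100, 200, "+", "novel", "No")]

    def test_t2t_overlap_region_classified(self):
        ann = AnnotationSet(
            genome_id="g",
            features=[
                FeatureAnnotation("a", "CDS", 100, 200, "+"),
                FeatureAnnotation("b", "CDS", 150, 250, "-"),
            ],
        )
        out = filter_candidates([(150, 200, "+")], ann, CallerConfig())
        assert out[0][3] == "t2t"


class TestExternalEvidence:
    def test_import_and_threshold(self, tmp_path):
        p = tmp_path / "ev.tsv"
        p.write_text("101\t160\t0.9996\n201\t260\t0.3\n")
        windows = import_external_evidence(p)
        assert external_evidence_for((100, 160), windows) == pytest.approx(0.9996)
        assert external_evidence_for((200, 260), windows) is None  # below 0.5
        assert external_evidence_for((500, 560), windows) is None  # no overlap

    def test_absent_evidence_renders_no(self):
        assert external_evidence_for((0, 50), None) is None

    def test_probability_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "ev.tsv"
        p.write_text("1\t50\t1.7\n")
        with pytest.raises(FormatError):
            import_external_evidence(p)


class TestAnnotateCandidate:
    def test_conserved_interval_reports_median_count(self):
        gc = local_gc_track(GENOME)
        cons = EvidenceTrack("c", np.full(len(GENOME), 11.0))
        c = annotate_candidate((100, 160, "+"), gc, {"p": cons}, [], cls="novel")
        assert c.cons_p == 11 and c.cons_t == 0

    def test_no_structure_renders_no_cell(self):
        gc = local_gc_track(GENOME)
        c = annotate_candidate((100, 160, "+"), gc, {}, [])
        assert c.structure is None and c.to_row()[8] == "No"

    def test_best_z_structure_selected(self):
        gc = local_gc_track(GENOME)
        hits = [
            LocalStructure(90, 150, "+", -12.0, ".", -3.1),
            LocalStructure(100, 165, "+", -20.0, ".", -5.2),
        ]
        c = annotate_candidate((100, 160, "+"), gc, {}, [], structures=hits)
        assert c.structure.zscore == -5.2
        assert c.structure_energy == pytest.approx(-20.0)


class TestAssignIds:
    def nc(self, start, end, strand, cls="novel", sense=50, anti=0):
        return NcRNACandidate(
            candidate_id="",
            start=start,
            end=end,
            strand=strand,
            expression=LocusExpression(
                start, end, strand, reads_plus_lib=sense, antisense_reads_plus_lib=anti
            ),
            cls=cls,
        )

    def test_numbering_by_genome_position(self):
        cands = [self.nc(9000, 9100, "+"), self.nc(100, 200, "+"), self.nc(5000, 5100, "-")]
        out = assign_ids(cands)
        assert [c.candidate_id for c in out] == ["n1", "n2", "n3"]
        assert out[0].start == 100

    def test_comparable_antisense_pair_shares_id(self):
        a = self.nc(100, 200, "+", sense=61)
        b = self.nc(105, 195, "-", sense=58)
        out = assign_ids([a, b])
        assert out[0].candidate_id == out[1].candidate_id == "n1"

    def test_unbalanced_opposite_strands_get_distinct_ids(self):
        a = self.nc(100, 200, "+", sense=1000)
        b = self.nc(105, 195, "-", sense=5)
        out = assign_ids([a, b])
        assert {out[0].candidate_id, out[1].candidate_id} == {"n1", "n2"}

    def test_t2t_pair_shares_class_id(self):
        a = self.nc(100, 160, "+", cls="t2t")
        b = self.nc(110, 170, "-", cls="t2t")
        out = assign_ids([a, b])
        assert out[0].candidate_id == out[1].candidate_id == "t2t1"

    def test_trna_locus_id_carries_trna_ordinal(self):
        ann = AnnotationSet(
            genome_id="g",
            features=[
                FeatureAnnotation("trnaA", "tRNA", 100, 176, "+"),
                FeatureAnnotation("trnaB", "tRNA", 900, 976, "+"),
            ],
        )
        c = self.nc(900, 980, "+", cls="tRNA_locus")
        c.annotation_overlap = "trnaB"
        out = assign_ids([c], ann)
        assert out[0].candidate_id == "t2;1"


class TestPipeline:
    def _toy_inputs(self):
        ann = AnnotationSet(
            genome_id="g",
            features=[FeatureAnnotation("cds1", "CDS", 1200, 1500, "+")],
        )
        reads = reads_over(300, 370, n=20) + reads_over(300, 370, n=8, lib="minus_lib", tag="m")
        structures = [LocalStructure(305, 365, "+", -25.0, "." * 60, -4.5)]
        return ann, reads, structures

    def test_expressed_intergenic_locus_called(self):
        ann, reads, structures = self._toy_inputs()
        out = call_candidates(GENOME, ann, reads, structures=structures)
        assert len(out) == 1
        c = out[0]
        assert c.cls == "novel" and c.candidate_id == "n1"
        assert c.expression.reads_plus_lib == 20
        assert c.structure is not None

    def test_structure_only_seed_needs_conservation(self):
        ann = AnnotationSet(genome_id="g", features=[])
        structures = [LocalStructure(700, 760, "+", -22.0, "." * 60, -3.6)]
        none_called = call_candidates(GENOME, ann, [], structures=structures)
        assert none_called == []
        # the same seed with strong conservation is kept
        from srnascan.io_formats import MsaBlock, MsaRow

        seg = GENOME.residues[650:850]
        rows = [MsaRow("g", seg, 650, "+", 200)] + [
            MsaRow(f"sp{i}", seg, 650, "+", 200) for i in range(10)
        ]
        blocks = [MsaBlock(rows=rows, reference_species="g")]
        called = call_candidates(
            GENOME, ann, [], maf_blocks={"p": blocks}, structures=structures
        )
        assert len(called) == 1 and called[0].cons_p == 11

    def test_deterministic_output_table(self, tmp_path):
        ann, reads, structures = self._toy_inputs()
        t1, t2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_candidate_table(call_candidates(GENOME, ann, reads, structures=structures), t1)
        write_candidate_table(call_candidates(GENOME, ann, reads, structures=structures), t2)
        assert t1.read_bytes() == t2.read_bytes()
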