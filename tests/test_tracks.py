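from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import hairpin, random_sequence
from oracle_fold import mfe_oracle
from srnascan.io_formats import GenomeSequence, MsaBlock, MsaRow, reverse_complement
from srnascan.tracks import (
    StructureScanConfig,
    conservation_track,
    dinucleotide_shuffle,
    fold_mfe,
    local_gc_track,
    merge_structure_hits,
    scan_local_structures,
    structure_zscore,
)


def dinucs(s):
    return Counter(zip(s, s[1:]))


class TestLocalGc:
    def test_homopolymer_extremes(self):
        assert np.all(local_gc_track(GenomeSequence("g", "G" * 40)).values == 1.0)
        assert np.all(local_gc_track(GenomeSequence("g", "A" * 40)).values == 0.0)

    def test_single_g_centered_window(self):
        g = GenomeSequence("g", "A" * 15 + "G" + "A" * 15)
        track = local_gc_track(g, flank=15)
        assert track.values[15] == pytest.approx(1 / 31)

    def test_edge_windows_clipped(self):
        g = GenomeSequence("g", "G" + "A" * 30)
        # window at position 0 spans only [0, 16): 1 G of 16
        assert local_gc_track(g, flank=15).values[0] == pytest.approx(1 / 16)

    def test_n_excluded_from_both_sides_of_ratio(self):
        g = GenomeSequence("g", "NNGNN")
        assert local_gc_track(g, flank=2).values[2] == pytest.approx(1.0)

    def test_reverse_complement_mirror(self):
        seq = random_sequence(300, 0.43, seed=5)
        fwd = local_gc_track(GenomeSequence("g", seq)).values
        rev = local_gc_track(GenomeSequence("g", reverse_complement(seq))).values
        assert np.allclose(fwd, rev[::-1])

    def test_empty_genome_rejected(self):
        with pytest.raises(Exception):
            local_gc_track(GenomeSequence("g", ""))


class TestDinucleotideShuffle:
    def test_homopolymer_unique_arrangement(self):
        rng = np.random.default_rng(0)
        assert dinucleotide_shuffle("AAAA", rng) == "AAAA"

    @pytest.mark.parametrize("seed", range(5))
    def test_dinucleotide_multiset_conserved(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_sequence(80, 0.5, seed=seed + 100)
        for _ in range(50):
            out = dinucleotide_shuffle(seq, rng)
            assert dinucs(out) == dinucs(seq)
            assert out[0] == seq[0] and out[-1] == seq[-1] and len(out) == len(seq)

    def test_n_rejected(self):
        with pytest.raises(ValueError):
            dinucleotide_shuffle("ACNGT", np.random.default_rng(0))

    @given(st.text(alphabet="ACGT", min_size=2, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conservation_holds_for_arbitrary_sequences(self, seq):
        out = dinucleotide_shuffle(seq, np.random.default_rng(0))
        assert dinucs(out) == dinucs(seq)
        assert out[0] == seq[0] and out[-1] == seq[-1]

    def test_uniform_over_valid_arrangements(self):
        # brute force the valid shuffle set of a 6-mer by permuting interior
        # residues and filtering on the dinucleotide multiset
        from itertools import permutations

        seq = "ACGCAC"
        valid = sorted(
            {
                seq[0] + "".join(mid) + seq[-1]
                for mid in permutations(seq[1:-1])
                if dinucs(seq[0] + "".join(mid) + seq[-1]) == dinucs(seq)
            }
        )
        assert len(valid) > 1
        rng = np.random.default_rng(42)
        draws = Counter(dinucleotide_shuffle(seq, rng) for _ in range(4000))
        assert set(draws) == set(valid)
        from scipy.stats import chisquare

        stat, p = chisquare(list(draws.values()))
        assert p > 0.001


class TestFoldMfe:
    def test_unpairable_sequence_scores_zero(self):
        assert fold_mfe("AAAAAAA", 120) == (0.0, ".......")

    def test_gc_hairpin_stem_and_loop(self):
        mfe, struct = fold_mfe("GGGGAAAACCCC", 120)
        assert mfe < 0
        assert struct == "((((....))))"

    def test_max_span_respected(self):
        seq = "GGGGG" + "A" * 130 + "CCCCC"
        mfe, struct = fold_mfe(seq, 120)
        assert mfe == 0.0 and "(" not in struct

    def test_dot_bracket_balanced_and_hairpin_loops(self):
        for seed in range(10):
            seq = random_sequence(70, 0.5, seed)
            _, struct = fold_mfe(seq, 120)
            stack = []
            pairs = []
            for i, c in enumerate(struct):
                if c == "(":
                    stack.append(i)
                elif c == ")":
                    pairs.append((stack.pop(), i))
            assert not stack
            for i, j in pairs:
                inner = [q for q in pairs if i < q[0] and q[1] < j]
                if not inner:
                    assert j - i - 1 >= 3

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_enumeration_on_15mers(self, seed):
        seq = random_sequence(15, 0.6, seed=seed)
        mfe, _ = fold_mfe(seq, 120)
        assert mfe == pytest.approx(mfe_oracle(seq, 120), abs=1e-9)


class TestStructureZscore:
    def test_homopolymer_zero(self):
        assert structure_zscore("A" * 60, rng=0) == 0.0

    def test_strong_hairpin_below_cutoff(self):
        seq = hairpin(stem=15, loop=4, seed=1)
        z = structure_zscore(seq, rng=3)
        assert z <= -3.0

    def test_matches_independent_recompute(self):
        # straightforward re-implementation: shuffle energies -> (E - mean)/sd
        from srnascan.tracks import fold_energy

        seq = hairpin(stem=10, loop=5, seed=2)
        cfg = StructureScanConfig(n_shuffles=200)
        z = structure_zscore(seq, cfg, rng=11)
        rng = np.random.default_rng(11)
        e_nat = fold_energy(seq, cfg.max_span)
        es = np.array(
            [fold_energy(dinucleotide_shuffle(seq, rng), cfg.max_span) for _ in range(200)]
        )
        expected = (e_nat - es.mean()) / es.std(ddof=1)
        assert z == pytest.approx(expected)

    def test_null_calibration_random_60mers(self):
        # |z| <= 3 nearly always for unselected random sequences
        cfg = StructureScanConfig(n_shuffles=200)
        inside = 0
        n_trials = 200
        for t in range(n_trials):
            seq = random_sequence(60, 0.43, seed=7000 + t)
            if abs(structure_zscore(seq, cfg, rng=t)) <= 3.0:
                inside += 1
        assert inside >= 0.95 * n_trials


class TestScan:
    def _genome_with_hairpin(self, stem, loop, n=2000, seed=9):
        bg = random_sequence(n, 0.43, seed=seed)
        hp = hairpin(stem=stem, loop=loop, seed=seed)
        pos = n // 2
        seq = bg[:pos] + hp + bg[pos + len(hp):]
        return GenomeSequence("g", seq[:n]), pos, pos + len(hp)

    def test_planted_hairpin_found_on_correct_strand(self):
        g, s, e = self._genome_with_hairpin(26, 6)
        hits = scan_local_structures(g, StructureScanConfig(rng_seed=1))
        overlapping = [h for h in hits if h.start < e and s < h.end]
        assert len(overlapping) >= 1
        assert any(h.strand == "+" for h in overlapping)

    def test_short_stable_element_discarded(self):
        # 40 nt hairpin in an unpairable background: trimmed span < 50
        bg = "A" * 1000
        hp = hairpin(stem=18, loop=4, seed=3)  # 40 nt
        g = GenomeSequence("g", bg[:500] + hp + bg[: 500 - len(hp) + 1000][:460])
        hits = scan_local_structures(g, StructureScanConfig(rng_seed=1))
        assert hits == []

    def test_hit_span_bounds(self, default_scan):
        cfg = StructureScanConfig()
        for h in default_scan:
            assert cfg.min_struct_len <= h.span <= cfg.max_span
            assert h.zscore <= cfg.z_cutoff

    def test_strand_symmetry(self):
        g, _, _ = self._genome_with_hairpin(26, 6, n=1500, seed=21)
        cfg = StructureScanConfig(rng_seed=5)
        fwd = scan_local_structures(g, cfg)
        rc = GenomeSequence("g", reverse_complement(g.residues))
        rev = scan_local_structures(rc, cfg)
        n = len(g)
        mirrored = sorted(
            (n - h.end, n - h.start, "+" if h.strand == "-" else "-", round(h.zscore, 6))
            for h in rev
        )
        assert mirrored == sorted(
            (h.start, h.end, h.strand, round(h.zscore, 6)) for h in fwd
        )

    def test_merge_keeps_lowest_z(self):
        from srnascan.tracks import LocalStructure

        a = LocalStructure(10, 80, "+", -20.0, ".", -4.0)
        b = LocalStructure(50, 130, "+", -25.0, ".", -5.5)
        c = LocalStructure(200, 260, "+", -18.0, ".", -3.2)
        d = LocalStructure(50, 130, "-", -25.0, ".", -3.5)
        merged = merge_structure_hits([a, b, c, d])
        assert merged == sorted([b, c, d], key=lambda h: (h.start, h.strand))


class TestConservation:
    def _block(self, rows, ref_start=10):
        msarows = [
            MsaRow(name, text, ref_start, "+", len(text.replace("-", "")))
            for name, text in rows
        ]
        return MsaBlock(rows=msarows, reference_species="ref")

    def test_identical_rows_count_all_species(self):
        block = self._block([("ref", "ACGT")] + [(f"sp{i}", "ACGT") for i in range(10)])
        g = GenomeSequence("g", "A" * 30)
        track = conservation_track([block], g)
        assert list(track.values[10:14]) == [11.0] * 4
        assert track.values[0] == 0.0  # uncovered

    def test_hand_computed_column_counts(self):
        # reference + 3 matching + 2 mismatching rows (5 species absent):
        # identity count = 4 at every column
        rows = [("ref", "ACGT")] + [(f"m{i}", "ACGT") for i in range(3)] + [
            ("x1", "TTTA"),
            ("x2", "GGAC"),
        ]
        g = GenomeSequence("g", "A" * 30)
        track = conservation_track([self._block(rows)], g)
        assert list(track.values[10:14]) == [4.0] * 4

    def test_gap_columns_skip_reference_coordinate(self):
        block = self._block([("ref", "AC-GT"), ("sp1", "ACCGT")])
        g = GenomeSequence("g", "A" * 30)
        track = conservation_track([block], g)
        # 4 reference positions covered, all matching in both species
        assert list(track.values[10:14]) == [2.0] * 4
        assert track.values[14] == 0.0

    def test_overlapping_blocks_max_wins(self):
        high = self._block([("ref", "ACGT"), ("sp1", "ACGT")], ref_start=5)
        low = self._block([("ref", "ACGT"), ("sp1", "TTTT")], ref_start=5)
        g = GenomeSequence("g", "A" * 20)
        track = conservation_track([low, high], g)
        assert list(track.values[5:9]) == [2.0] * 4
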