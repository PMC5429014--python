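"""Codon-aware alignment, block trimming and the coverage filter."""

import numpy as np
import pytest

from c4scan.align import (CodonAlignment, InternalStopError, TrimParams,
                          codon_align, coverage_filter, translate_cds,
                          trim_blocks)
from c4scan.align import _align_profiles, _AA_INDEX, _BLOSUM_ARR
from c4scan.models import CodonModelParams
from c4scan.phylo import Phylogeny
from c4scan.simulate import (grass_species_tree, simulate_codon_alignment)


class TestTranslate:
    def test_basic_codons(self):
        assert translate_cds("ATGGCT") == "MA"

    def test_terminal_stop_dropped(self):
        assert translate_cds("ATGGCTTAA") == "MA"

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            translate_cds("ATGGCTA")

    def test_internal_stop_flagged(self):
        with pytest.raises(InternalStopError):
            translate_cds("ATGGCT" + "TAA" + "GCT" * 7)

    def test_ambiguous_codon_is_x(self):
        assert translate_cds("ATGNNN") == "MX"


class TestCodonAlign:
    def test_identical_sequences_gap_free(self):
        guide = Phylogeny.from_nested((("a", "b"), "c"), 0.1, 0.1)
        seq = "ATGGCTAAAGGG"
        aln = codon_align({t: seq for t in "abc"}, guide)
        assert all(r == seq for r in aln.rows)

    def test_pairwise_score_matches_needleman_wunsch_oracle(self):
        """The profile aligner on two single sequences reproduces an
        independent global affine DP under BLOSUM62, open 10, extend 0.5."""
        a, b = "HEAGAWGHEE", "PAWHEAE"

        def nw_oracle(x, y, open_=10.0, ext=0.5):
            NEG = -1e30
            nx, ny = len(x), len(y)
            M = np.full((nx + 1, ny + 1), NEG)
            X = np.full((nx + 1, ny + 1), NEG)
            Y = np.full((nx + 1, ny + 1), NEG)
            M[0, 0] = 0.0
            for i in range(1, nx + 1):
                X[i, 0] = -open_ - (i - 1) * ext
            for j in range(1, ny + 1):
                Y[0, j] = -open_ - (j - 1) * ext
            for i in range(1, nx + 1):
                for j in range(1, ny + 1):
                    s = _BLOSUM_ARR[_AA_INDEX[x[i - 1]], _AA_INDEX[y[j - 1]]]
                    M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                                  Y[i - 1, j - 1]) + s
                    X[i, j] = max(M[i - 1, j] - open_, X[i - 1, j] - ext,
                                  Y[i - 1, j] - open_)
                    Y[i, j] = max(M[i, j - 1] - open_, Y[i, j - 1] - ext,
                                  X[i, j - 1] - open_)
            return max(M[nx, ny], X[nx, ny], Y[nx, ny])

        _, _, score = _align_profiles([a], [b])
        assert score == pytest.approx(nw_oracle(a, b))

    def test_round_trip_with_indels(self, codon_pi):
        tree = grass_species_tree()
        params = CodonModelParams(pi=codon_pi)
        seqs = simulate_codon_alignment(tree, params, 120, seed=8)
        seqs["Si"] = seqs["Si"][:30] + seqs["Si"][45:]   # 5-codon deletion
        seqs["Os"] = seqs["Os"][:90] + seqs["Os"][96:]   # 2-codon deletion
        aln = codon_align(seqs, tree)
        for t in seqs:
            assert aln.ungapped(t) == seqs[t]
        assert aln.n_codons >= 120 - 5

    def test_determinism(self, codon_pi):
        tree = grass_species_tree()
        seqs = simulate_codon_alignment(
            tree, CodonModelParams(pi=codon_pi), 90, seed=9)
        seqs["Zm"] = seqs["Zm"][:30] + seqs["Zm"][39:]
        a1 = codon_align(seqs, tree)
        a2 = codon_align(dict(seqs), tree)
        assert a1.rows == a2.rows and a1.taxa == a2.taxa

    def test_single_sequence_returned_unchanged(self):
        guide = grass_species_tree()
        aln = codon_align({"Zm": "ATGGCT"}, guide)
        assert aln.taxa == ["Zm"] and aln.rows == ["ATGGCT"]


def _codons_for(protein):
    table = {"M": "ATG", "A": "GCT", "K": "AAA", "G": "GGT", "F": "TTT",
             "L": "CTT", "P": "CCT", "S": "TCT", "T": "ACT", "V": "GTT",
             "W": "TGG", "Y": "TAT", "-": "---"}
    return "".join(table[a] for a in protein)


class TestTrimBlocks:
    def test_fully_conserved_retained_entirely(self):
        rows = [_codons_for("MAKGF" * 8)] * 4
        aln = CodonAlignment(list("abcd"), rows)
        trimmed, colmap = trim_blocks(aln)
        assert trimmed.n_codons == 40
        assert colmap == list(range(40))

    def test_gap_column_removed(self):
        prot = ["MAKGFMAKGFMAKGF", "MA-GFMAKGFMAKGF", "MAKGFMAKGFMAKGF"]
        aln = CodonAlignment(list("abc"), [_codons_for(p) for p in prot])
        trimmed, colmap = trim_blocks(
            aln, TrimParams(min_block_length=3, flank_fraction=0.6))
        assert 2 not in colmap  # the gap column

    def test_toy_low_identity_stretch(self):
        """40 columns with a 9-column nonconserved stretch mid-alignment.

        Hand execution of the stated rules: all four rows agree outside
        columns 16..24 (0-based), where every row differs (conserved
        requires the top residue in strictly more than half of 4 rows,
        i.e. >2 occurrences).  The 9-column nonconserved run exceeds the
        max run of 8, so it is rejected; both flanking blocks (16 and 15
        columns, fully 'highly conserved') are kept.
        """
        base = "MAKGFLPSTV" * 4   # 40 columns
        rows = [list(base) for _ in range(4)]
        subst = ["G", "F", "L", "P"]
        for col in range(16, 25):
            for r in range(4):
                rows[r][col] = subst[(r + col) % 4]
        aln = CodonAlignment(
            list("abcd"), [_codons_for("".join(r)) for r in rows])
        trimmed, colmap = trim_blocks(aln)
        assert colmap == list(range(0, 16)) + list(range(25, 40))

    def test_run_at_max_length_kept_when_flanked(self):
        """An 8-column nonconserved run is within the allowed maximum, so
        the whole alignment stays one block (flanks are conserved)."""
        base = "MAKGFLPSTV" * 4
        rows = [list(base) for _ in range(4)]
        subst = ["G", "F", "L", "P"]
        for col in range(16, 24):
            for r in range(4):
                rows[r][col] = subst[(r + col) % 4]
        aln = CodonAlignment(
            list("abcd"), [_codons_for("".join(r)) for r in rows])
        trimmed, colmap = trim_blocks(aln)
        assert colmap == list(range(40))

    def test_short_blocks_dropped(self):
        rows = [_codons_for("MAKGF")] * 3
        aln = CodonAlignment(list("abc"), rows)
        trimmed, colmap = trim_blocks(aln, TrimParams(min_block_length=10))
        assert trimmed.n_codons == 0

    def test_trimming_is_pure_column_selection(self, codon_pi):
        tree = grass_species_tree()
        seqs = simulate_codon_alignment(
            tree, CodonModelParams(pi=codon_pi), 150, seed=21)
        aln = CodonAlignment(list(seqs), list(seqs.values()))
        trimmed, colmap = trim_blocks(aln)
        assert all(b > a for a, b in zip(colmap, colmap[1:]))
        for k, orig in enumerate(colmap):
            for r in range(len(aln.rows)):
                assert (trimmed.rows[r][3 * k:3 * k + 3]
                        == aln.rows[r][3 * orig:3 * orig + 3])


class TestCoverageFilter:
    @pytest.mark.parametrize("kept,total,expected", [
        (29, 100, False),   # 0.29 -> discard
        (30, 100, True),    # boundary kept
        (0, 100, False),
    ])
    def test_threshold_boundary(self, kept, total, expected):
        taxa = ["a", "b"]
        original = CodonAlignment(taxa, ["ATG" * total] * 2)
        trimmed = CodonAlignment(taxa, ["ATG" * kept] * 2)
        keep, cov = coverage_filter(trimmed, original)
        assert keep is expected
        assert cov == pytest.approx(kept / total)

    def test_zero_length_original_discarded(self):
        empty = CodonAlignment(["a", "b"], ["", ""])
        keep, cov = coverage_filter(empty, empty)
        assert not keep
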