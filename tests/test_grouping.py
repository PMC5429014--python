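"""Ortholog grouping: homeolog merging, best-hit homologs, patterns."""

import numpy as np
import pandas as pd
import pytest

from c4scan.grouping import (HomologIndex, OrthologGroup, best_hit_homolog,
                             classify_pattern, merge_homeologs,
                             read_synteny_table)


def _rows(entries):
    return pd.DataFrame(entries, columns=["group_id", "species", "gene_id"])


class TestMergeHomeologs:
    def test_two_rows_sharing_anchors_merge_maize_genes(self):
        rows = _rows([
            ("g1.a", "Sb", "Sb_1"), ("g1.a", "Si", "Si_1"),
            ("g1.a", "Zm", "Zm_B"),
            ("g1.b", "Sb", "Sb_1"), ("g1.b", "Si", "Si_1"),
            ("g1.b", "Zm", "Zm_A"),
        ])
        merged = merge_homeologs(rows)
        assert len(merged) == 1
        g = merged[0]
        assert g.members["Zm"] == ["Zm_A", "Zm_B"]  # lexicographic order
        assert g.members["Sb"] == ["Sb_1"]

    def test_single_maize_group_unchanged(self):
        rows = _rows([("g1", "Zm", "Zm_A"), ("g1", "Sb", "Sb_1")])
        merged = merge_homeologs(rows)
        assert len(merged) == 1
        assert merged[0].members["Zm"] == ["Zm_A"]

    def test_idempotent(self):
        rows = _rows([
            ("g1.a", "Sb", "Sb_1"), ("g1.a", "Zm", "Zm_A"),
            ("g1.b", "Sb", "Sb_1"), ("g1.b", "Zm", "Zm_B"),
            ("g2", "Sb", "Sb_2"), ("g2", "Zm", "Zm_C"),
        ])
        once = merge_homeologs(rows)
        back = _rows([(g.group_id, sp, gene) for g in once
                      for sp, gene in g.all_genes()])
        twice = merge_homeologs(back)
        assert [(g.group_id, g.members) for g in once] == \
               [(g.group_id, g.members) for g in twice]

    def test_three_maize_members_excluded(self):
        rows = _rows([
            ("g1.a", "Sb", "Sb_1"), ("g1.a", "Zm", "Zm_A"),
            ("g1.b", "Sb", "Sb_1"), ("g1.b", "Zm", "Zm_B"),
            ("g1.c", "Sb", "Sb_1"), ("g1.c", "Zm", "Zm_C"),
        ])
        merged = merge_homeologs(rows)
        assert len(merged) == 1
        assert merged[0].pattern == "excluded"
        assert "3 maize" in merged[0].note

    def test_partition_property(self):
        """Every input (species, gene) lands in exactly one output group."""
        rng = np.random.default_rng(0)
        entries = []
        for i in range(20):
            gid = f"g{i}"
            for sp in ("Sb", "Si", "Os"):
                entries.append((gid, sp, f"{sp}_{i}"))
            entries.append((gid, "Zm", f"Zm_{i}"))
        rows = _rows(entries)
        merged = merge_homeologs(rows)
        out = sorted((sp, g) for grp in merged for sp, g in grp.all_genes())
        inp = sorted((r.species, r.gene_id) for r in rows.itertuples())
        assert out == inp


class TestBestHitHomolog:
    def test_exact_match_wins(self):
        q = "ATGGCTAAAGGGTTTCCC"
        cands = {"x": "ATGTTTAAACCCGGGAAA", "y": q, "z": q[:9] + "AAAAAAAAA"}
        hit = best_hit_homolog(q, cands, min_score=10)
        assert hit is not None
        assert hit[0] == "y"
        assert hit[1] == 2 * len(q)

    def test_empty_candidates_missing(self):
        assert best_hit_homolog("ATG", {}) is None

    def test_below_min_score_missing(self):
        assert best_hit_homolog("ATGATG", {"x": "CCCCCC"},
                                min_score=5) is None

    def test_scores_match_smith_waterman_oracle(self):
        """Seeded random candidates: aligner scores equal an independent
        quadratic-DP local aligner under the stated scoring."""
        rng = np.random.default_rng(42)

        def rand_seq(n):
            return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

        query = rand_seq(300)
        cands = {f"c{i}": rand_seq(300) for i in range(5)}
        # plant a high-identity homolog
        mutated = list(query)
        for pos in rng.choice(300, 30, replace=False):
            mutated[pos] = "ACGT"[rng.integers(0, 4)]
        cands["hom"] = "".join(mutated)

        def sw_oracle(a, b, match=2.0, mis=-3.0, open_=7.0, ext=2.0):
            na, nb = len(a), len(b)
            NEG = -1e30
            M = np.zeros((na + 1, nb + 1))
            X = np.full((na + 1, nb + 1), NEG)
            Y = np.full((na + 1, nb + 1), NEG)
            best = 0.0
            for i in range(1, na + 1):
                for j in range(1, nb + 1):
                    s = match if a[i - 1] == b[j - 1] else mis
                    M[i, j] = max(0.0, M[i - 1, j - 1] + s,
                                  X[i - 1, j - 1] + s, Y[i - 1, j - 1] + s)
                    X[i, j] = max(M[i - 1, j] - open_, X[i - 1, j] - ext)
                    Y[i, j] = max(M[i, j - 1] - open_, Y[i, j - 1] - ext)
                    best = max(best, M[i, j])
            return best

        from c4scan.grouping import _local_aligner
        aligner = _local_aligner()
        for cid, seq in cands.items():
            assert aligner.score(query, seq) == pytest.approx(
                sw_oracle(query, seq)), cid
        hit = best_hit_homolog(query, cands, min_score=50)
        assert hit[0] == "hom"

    def test_index_shortlist_agrees_with_full_scan(self):
        rng = np.random.default_rng(7)

        def rand_seq(n):
            return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

        pool = {f"c{i}": rand_seq(240) for i in range(12)}
        query = pool["c5"][:200] + rand_seq(40)
        idx = HomologIndex(pool)
        assert idx.best(query) == best_hit_homolog(query, pool)


class TestClassifyPattern:
    def _group(self, members):
        return OrthologGroup("g", members={k: list(v)
                                           for k, v in members.items()})

    def test_all_six_is_pattern_i(self):
        g = self._group({sp: [f"{sp}_1"]
                         for sp in ("Zm", "Sb", "Si", "Do", "Os", "Bd")})
        assert classify_pattern(g) == "i"

    def test_two_maize_is_pattern_ii(self):
        g = self._group({"Zm": ["a", "b"], "Sb": ["s"], "Si": ["i"],
                         "Do": ["d"], "Os": ["o"], "Bd": ["bd"]})
        assert classify_pattern(g) == "ii"

    def test_rice_missing_is_pattern_iii(self):
        g = self._group({"Zm": ["a"], "Sb": ["s"], "Si": ["i"],
                         "Do": ["d"], "Bd": ["bd"]})
        assert classify_pattern(g) == "iii"

    def test_brachypodium_missing_is_pattern_iv(self):
        g = self._group({"Zm": ["a"], "Sb": ["s"], "Si": ["i"],
                         "Do": ["d"], "Os": ["o"]})
        assert classify_pattern(g) == "iv"

    def test_sorghum_missing_excluded(self):
        g = self._group({"Zm": ["a"], "Si": ["i"], "Do": ["d"],
                         "Os": ["o"], "Bd": ["bd"]})
        assert classify_pattern(g) == "excluded"

    def test_both_outgroups_missing_excluded(self):
        g = self._group({"Zm": ["a"], "Sb": ["s"], "Si": ["i"],
                         "Do": ["d"]})
        assert classify_pattern(g) == "excluded"

    def test_pure_function_of_counts(self):
        g1 = self._group({sp: [f"{sp}_1"]
                          for sp in ("Zm", "Sb", "Si", "Do", "Os", "Bd")})
        g2 = self._group({sp: [f"{sp}_other"]
                          for sp in ("Zm", "Sb", "Si", "Do", "Os", "Bd")})
        assert classify_pattern(g1) == classify_pattern(g2)


def test_build_groups_excludes_triple_maize_without_raising():
    """Three maize genes for one anchor set exclude the group cleanly."""
    from c4scan.grouping import build_ortholog_groups
    rows = _rows([
        (f"g1.{i}", sp, g)
        for i, zm in enumerate(["Zm_A", "Zm_B", "Zm_C"])
        for sp, g in [("Sb", "Sb_1"), ("Zm", zm)]
    ])
    cds = {"Sb": {"Sb_1": "ATGGCTAAA"},
           "Zm": {f"Zm_{c}": "ATGGCTAAA" for c in "ABC"}}
    groups = build_ortholog_groups(rows, cds)
    assert len(groups) == 1
    assert groups[0].pattern == "excluded"


def test_read_synteny_table_requires_header(tmp_path):
    p = tmp_path / "syn.tsv"
    p.write_text("a\tb\tc\n1\tZm\tg\n")
    with pytest.raises(ValueError, match="columns"):
        read_synteny_table(p)
    p.write_text("group_id\tspecies\tgene_id\ng1\tZm\tZm_1\n")
    df = read_synteny_table(p)
    assert list(df.columns) == ["group_id", "species", "gene_id"]
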