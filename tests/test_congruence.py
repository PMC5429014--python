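"""Quartet distances, topology enumeration and gene-tree congruence."""

from itertools import combinations

import numpy as np
import pytest

from c4scan.align import CodonAlignment
from c4scan.congruence import (congruence_test, enumerate_topologies,
                               infer_gene_tree, quartet_distance,
                               third_position_sites)
from c4scan.fit import GtrGeneTreeModel
from c4scan.models import CodonModelParams, NucModelParams
from c4scan.phylo import Phylogeny
from c4scan.scan import label_foreground
from c4scan.simulate import (DISCORDANT_TOPOLOGY, grass_species_tree,
                             simulate_codon_alignment)


def restriction_quartet_oracle(t1: Phylogeny, t2: Phylogeny) -> int:
    """Independent quartet distance: restrict both trees to each 4-subset
    and compare the split of the first tip (different code path from the
    four-point-condition implementation)."""
    def split_of(tree, quad):
        sub = tree.restrict(quad)
        # find the internal edge partitioning the 4 tips 2|2
        for v in range(sub.n_nodes):
            if v == sub.root:
                continue
            below = sub.tips_below(v)
            if len(below) == 2:
                return frozenset((below, frozenset(quad) - below))
        return None  # star-like (cannot happen for binary input)

    count = 0
    for quad in combinations(sorted(t1.tip_labels), 4):
        if split_of(t1, set(quad)) != split_of(t2, set(quad)):
            count += 1
    return count


def random_tree(labels, rng):
    labels = list(labels)
    rng.shuffle(labels)
    nodes = [(lbl,) for lbl in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))

    def unwrap(n):
        if len(n) == 1 and isinstance(n[0], str):
            return n[0]
        return tuple(unwrap(c) for c in n)

    return Phylogeny.from_nested(unwrap(nodes[0]), 0.1, 0.1)


class TestThirdPositions:
    def test_extracts_third_nucleotides(self):
        aln = CodonAlignment(["a", "b"], ["ATGGCC", "ATAGCA"])
        taxa, rows = third_position_sites(aln)
        assert rows == ["GC", "AA"]
        assert len(rows[0]) == aln.n_codons

    def test_gaps_map_to_gaps(self):
        aln = CodonAlignment(["a"], ["ATG---GCC"])
        _, rows = third_position_sites(aln)
        assert rows == ["G-C"]


class TestEnumeration:
    @pytest.mark.parametrize("n,expected", [(4, 3), (5, 15), (6, 105)])
    def test_topology_counts(self, n, expected):
        labels = [f"t{i}" for i in range(n)]
        tops = enumerate_topologies(labels)
        assert len(tops) == expected
        # all distinct as unrooted topologies
        for i in range(min(10, len(tops))):
            for j in range(i + 1, min(10, len(tops))):
                assert quartet_distance(tops[i], tops[j]) > 0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            enumerate_topologies(["a", "b", "c"])


class TestQuartetDistance:
    def test_worked_five_taxon_example(self):
        t1 = Phylogeny.from_newick("((((A,B),C),D),E);")
        t2 = Phylogeny.from_newick("((((A,B),D),C),E);")
        assert quartet_distance(t1, t2) == 2
        # exactly the quartets {A,C,D,E} and {B,C,D,E} differ
        assert restriction_quartet_oracle(t1, t2) == 2

    def test_identical_trees(self, species_tree):
        assert quartet_distance(species_tree, species_tree) == 0

    def test_symmetry_and_oracle_agreement(self):
        rng = np.random.default_rng(0)
        labels = [f"t{i}" for i in range(6)]
        for _ in range(25):
            t1 = random_tree(labels, rng)
            t2 = random_tree(labels, rng)
            d12 = quartet_distance(t1, t2)
            assert d12 == quartet_distance(t2, t1)
            assert d12 == restriction_quartet_oracle(t1, t2)

    def test_different_tip_sets_rejected(self):
        t1 = Phylogeny.from_newick("((A,B),(C,D));")
        t2 = Phylogeny.from_newick("((A,B),(C,E));")
        with pytest.raises(ValueError):
            quartet_distance(t1, t2)


class TestInferGeneTree:
    def test_recovers_generating_topology(self, codon_pi):
        """500 nt simulated on the 6-taxon species tree with internal
        branches 0.2 is enough signal for exact recovery."""
        gen = label_foreground(grass_species_tree(0.1, 0.2))
        seqs = simulate_codon_alignment(
            gen, CodonModelParams(pi=codon_pi), 170, seed=31)
        taxa = list(seqs)
        rows = [seqs[t] for t in taxa]
        tree, lnl = infer_gene_tree(taxa, rows)
        assert quartet_distance(tree, gen) == 0
        assert lnl < 0

    def test_returned_lnl_at_least_species_topology(self, codon_pi,
                                                    species_tree):
        gen = label_foreground(grass_species_tree(0.1, 0.15,
                                                  DISCORDANT_TOPOLOGY))
        seqs = simulate_codon_alignment(
            gen, CodonModelParams(pi=codon_pi), 150, seed=32)
        taxa = list(seqs)
        rows = [seqs[t] for t in taxa]
        tree, lnl = infer_gene_tree(taxa, rows, ensure=species_tree)
        ref = GtrGeneTreeModel(taxa, rows, species_tree.copy(),
                               params=NucModelParams(alpha=1.0, p_inv=0.1))
        assert lnl >= ref.fit().lnl - 1e-6

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            infer_gene_tree(["a", "b", "c"], ["A", "A", "A"])


class TestCongruenceVerdict:
    def test_concordant_group_passes(self, codon_pi, species_tree):
        gen = label_foreground(grass_species_tree(0.1, 0.2))
        seqs = simulate_codon_alignment(
            gen, CodonModelParams(pi=codon_pi), 300, seed=41)
        aln = CodonAlignment(list(seqs), list(seqs.values()))
        v = congruence_test(aln, species_tree)
        assert v.passed
        assert (v.qdist_all == 0) or (v.qdist_third == 0)

    def test_discordant_group_excluded(self, codon_pi, species_tree):
        gen = label_foreground(grass_species_tree(0.1, 0.2,
                                                  DISCORDANT_TOPOLOGY))
        seqs = simulate_codon_alignment(
            gen, CodonModelParams(pi=codon_pi), 300, seed=42)
        aln = CodonAlignment(list(seqs), list(seqs.values()))
        v = congruence_test(aln, species_tree)
        assert not v.passed
        assert v.qdist_all > 0 and v.qdist_third > 0

    def test_pass_is_a_disjunction(self):
        from c4scan.congruence import CongruenceVerdict
        v = CongruenceVerdict(None, None, qdist_all=3, qdist_third=0,
                              passed=(3 == 0) or (0 == 0))
        assert v.passed

    def test_homeolog_cherry_collapsed(self, codon_pi, species_tree):
        gen = label_foreground(
            grass_species_tree(0.1, 0.2).with_tip_expanded(
                "Zm", ("Zm_h1", "Zm_h2")))
        seqs = simulate_codon_alignment(
            gen, CodonModelParams(pi=codon_pi), 300, seed=43)
        aln = CodonAlignment(list(seqs), list(seqs.values()))
        v = congruence_test(aln, species_tree,
                            homeologs=("Zm_h1", "Zm_h2"))
        assert v.passed
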