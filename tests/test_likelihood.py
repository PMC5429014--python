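"""Pruning likelihoods against exhaustive-marginalization oracles."""

import itertools

import numpy as np
import pytest

from c4scan._codons import N_CODONS, encode_codon_rows
from c4scan.likelihood import (compress_patterns, encode_nuc_rows,
                               prune_loglik)
from c4scan.models import (CodonModelParams, NucModelParams,
                           codon_rate_matrix, discretize_gamma,
                           gtr_rate_matrix, transition_matrix)
from c4scan.phylo import Phylogeny


def exhaustive_codon_loglik(tree: Phylogeny, taxa, rows,
                            params: CodonModelParams) -> float:
    """Oracle: sum the joint likelihood over all internal-node states."""
    Q = codon_rate_matrix(params, params.omega_by_class[0])
    P = {v: transition_matrix(Q, tree.lengths[v])
         for v in range(tree.n_nodes) if v != tree.root}
    states = encode_codon_rows(rows)
    order = {t: i for i, t in enumerate(taxa)}
    internals = [v for v in range(tree.n_nodes) if v >= tree.n_tips]
    total = 0.0
    for col in range(states.shape[1]):
        like = 0.0
        for assign in itertools.product(range(N_CODONS),
                                        repeat=len(internals)):
            node_state = {v: s for v, s in zip(internals, assign)}
            for i, t in enumerate(tree.tip_labels):
                node_state[i] = states[order[t], col]
            term = params.pi[node_state[tree.root]]
            for v in range(tree.n_nodes):
                if v == tree.root:
                    continue
                s_child = node_state[v]
                s_parent = node_state[tree.parent[v]]
                if s_child < 0:  # gap tip: marginalized = sum over states
                    continue
                term *= P[v][s_parent, s_child]
            like += term
        total += np.log(like)
    return total


def exhaustive_nuc_loglik(tree, taxa, rows, params: NucModelParams) -> float:
    """Oracle: brute-force sum over internal states and rate categories."""
    Q = gtr_rate_matrix(params)
    rates = discretize_gamma(params.alpha, params.n_categories)
    states = encode_nuc_rows(rows)
    order = {t: i for i, t in enumerate(taxa)}
    internals = [v for v in range(tree.n_nodes) if v >= tree.n_tips]
    total = 0.0
    for col in range(states.shape[1]):
        site = 0.0
        for rate in rates:
            P = {v: transition_matrix(Q, tree.lengths[v] * rate)
                 for v in range(tree.n_nodes) if v != tree.root}
            like = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                node_state = {v: s for v, s in zip(internals, assign)}
                for i, t in enumerate(tree.tip_labels):
                    node_state[i] = states[order[t], col]
                term = params.pi[node_state[tree.root]]
                for v in range(tree.n_nodes):
                    if v == tree.root:
                        continue
                    if node_state[v] < 0:
                        continue
                    term *= P[v][node_state[tree.parent[v]], node_state[v]]
                like += term
            site += like / params.n_categories
        site *= (1 - params.p_inv)
        col_states = [states[order[t], col] for t in tree.tip_labels]
        obs = [s for s in col_states if s >= 0]
        if params.p_inv > 0:
            if not obs:
                site += params.p_inv
            elif all(s == obs[0] for s in obs):
                site += params.p_inv * params.pi[obs[0]]
        total += np.log(site)
    return total


@pytest.fixture(scope="module")
def four_taxon_tree():
    return Phylogeny.from_newick(
        "((a:0.11,b:0.23):0.08,(c:0.15,d:0.31):0.12);")


class TestCodonPruning:
    def test_matches_exhaustive_marginalization(self, four_taxon_tree,
                                                codon_pi):
        params = CodonModelParams(kappa=2.3, omega_by_class={0: 0.45},
                                  pi=codon_pi)
        taxa = list("abcd")
        rows = ["ATGAAA", "ATGAAG", "ACGAAA", "ATGCAA"]
        got = prune_loglik(four_taxon_tree, taxa, rows, params)
        want = exhaustive_codon_loglik(four_taxon_tree, taxa, rows, params)
        assert abs(got - want) < 1e-8

    def test_gap_codons_marginalize(self, four_taxon_tree, codon_pi):
        params = CodonModelParams(kappa=1.7, omega_by_class={0: 0.8},
                                  pi=codon_pi)
        taxa = list("abcd")
        rows = ["ATG---", "ATGAAG", "ACGAAA", "ATGNNA"]
        got = prune_loglik(four_taxon_tree, taxa, rows, params)
        want = exhaustive_codon_loglik(four_taxon_tree, taxa, rows, params)
        assert abs(got - want) < 1e-8

    def test_rerooting_invariance(self, codon_pi):
        """The pulley principle: reversible models ignore root placement."""
        params = CodonModelParams(kappa=2.0, omega_by_class={0: 0.5},
                                  pi=codon_pi)
        taxa = list("abcd")
        rows = ["ATGAAA", "ATGAAG", "ACGTCA", "ATGCAA"]
        t1 = Phylogeny.from_newick(
            "((a:0.1,b:0.2):0.05,(c:0.15,d:0.3):0.05);")
        # same unrooted tree, rooted on the edge leading to a
        t2 = Phylogeny.from_newick(
            "(a:0.1,(b:0.2,(c:0.15,d:0.3):0.1):0.0);")
        l1 = prune_loglik(t1, taxa, rows, params)
        l2 = prune_loglik(t2, taxa, rows, params)
        assert abs(l1 - l2) < 1e-9

    def test_adding_columns_never_increases_loglik(self, four_taxon_tree,
                                                   codon_pi):
        params = CodonModelParams(kappa=2.0, omega_by_class={0: 0.5},
                                  pi=codon_pi)
        taxa = list("abcd")
        short = ["ATG", "ATG", "ACG", "ATG"]
        long = [r + e for r, e in zip(short, ["AAA", "AAG", "AAA", "CAA"])]
        l_short = prune_loglik(four_taxon_tree, taxa, short, params)
        l_long = prune_loglik(four_taxon_tree, taxa, long, params)
        assert l_long <= l_short

    def test_unknown_taxon_rejected(self, four_taxon_tree, codon_pi):
        params = CodonModelParams(pi=codon_pi)
        with pytest.raises(ValueError, match="absent from tree"):
            prune_loglik(four_taxon_tree, ["a", "b", "zz"],
                         ["ATG", "ATG", "ATG"], params)


class TestNucleotidePruning:
    def test_two_taxon_jc_closed_form(self):
        tree = Phylogeny.from_newick("(a:0.15,b:0.15);")
        lnl = prune_loglik(tree, ["a", "b"], ["A", "A"],
                           NucModelParams(n_categories=1))
        expected = np.log(0.25 * (0.25 + 0.75 * np.exp(-0.4)))
        assert abs(lnl - expected) < 1e-4
        assert abs(lnl - (-1.67033)) < 1e-4

    def test_matches_exhaustive_with_gamma_and_invariant(self,
                                                         four_taxon_tree):
        rng = np.random.default_rng(11)
        params = NucModelParams(
            exchangeabilities=rng.uniform(0.5, 2.0, 6),
            pi=rng.dirichlet(np.ones(4)),
            alpha=0.8, p_inv=0.2, n_categories=3)
        taxa = list("abcd")
        rows = ["ACG", "A-G", "GCG", "ACT"]
        got = prune_loglik(four_taxon_tree, taxa, rows, params)
        want = exhaustive_nuc_loglik(four_taxon_tree, taxa, rows, params)
        assert abs(got - want) < 1e-8


def test_pattern_compression_conserves_counts():
    states = np.array([[0, 1, 0, 2, 0], [3, 1, 3, 2, 3]])
    patterns, weights = compress_patterns(states)
    assert weights.sum() == 5
    assert patterns.shape[1] == 3
    # reconstruct column multiset
    seen = {tuple(patterns[:, k]): w for k, w in enumerate(weights)}
    assert seen[(0, 3)] == 3
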