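"""Phylogenetic likelihoods by Felsenstein pruning.

Two engines share the same traversal logic:

* :class:`CodonLikelihood` — 61-state GY94 branch model, dense numpy
  (61x61 matrix products are BLAS-bound).  Supports cheap single-branch
  objectives via outside/inside partial caching, which is what makes the
  coordinate-wise ML fits fast.
* :func:`nuc_mixture_loglik` — 4-state GTR with a discrete-gamma +
  invariant-sites rate mixture, compiled with numba (the gene-tree search
  evaluates it tens of thousands of times per group).

Gap or ambiguous states contribute a partial likelihood of 1 for every
state, the standard missing-data convention.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
from numba import njit

from ._codons import N_CODONS, encode_codon_rows
from .models import (CodonModelParams, NucModelParams, SpectralQ,
                     codon_rate_matrix, discretize_gamma, gtr_rate_matrix)
from .phylo import Phylogeny

_LOG_FLOOR = 1e-300


def compress_patterns(states: np.ndarray):
    """Collapse identical alignment columns; returns (patterns, weights).

    ``states`` is (n_taxa, n_cols) int; output patterns is (n_taxa, n_pat).
    """
    if states.shape[1] == 0:
        return states, np.zeros(0)
    uniq, counts = np.unique(states.T, axis=0, return_counts=True)
    return uniq.T.copy(), counts.astype(float)


def _states_for_tree(tree: Phylogeny, taxa: Sequence[str],
                     states: np.ndarray) -> np.ndarray:
    """Reorder alignment rows to tree-tip order; absent tips become all-gap."""
    tipset = set(tree.tip_labels)
    for t in taxa:
        if t not in tipset:
            raise ValueError(f"alignment taxon {t!r} absent from tree")
    row = {t: i for i, t in enumerate(taxa)}
    out = np.full((tree.n_tips, states.shape[1]), -1, dtype=np.int64)
    for i, name in enumerate(tree.tip_labels):
        if name in row:
            out[i] = states[row[name]]
    return out


# ===================================================================== #
# codon engine
# ===================================================================== #

class CodonLikelihood:
    """Pruning likelihood of a codon alignment on a class-labeled tree.

    Branch lengths live in ``self.lengths`` (a copy of the tree's); model
    parameters are set with :meth:`set_rates`.  ``edge_objective`` returns a
    function of a single branch length with everything else held fixed,
    using cached inside (down) and outside partials.
    """

    def __init__(self, tree: Phylogeny, taxa: Sequence[str],
                 states: np.ndarray, pi: np.ndarray):
        self.tree = tree
        self.pi = np.asarray(pi, dtype=float)
        tip_states = _states_for_tree(tree, taxa, states)
        self.patterns, self.weights = compress_patterns(tip_states)
        self.n_pat = self.patterns.shape[1]
        self.lengths = tree.lengths.copy()
        self.classes = tree.classes.copy()
        self.post = tree.postorder()
        self.root = tree.root
        self.n_tips = tree.n_tips
        self.n_nodes = tree.n_nodes
        self._spectral: Dict[int, SpectralQ] = {}
        self._P = [None] * self.n_nodes
        self._P_valid = np.zeros(self.n_nodes, dtype=bool)
        self._down = [None] * self.n_nodes
        self._msg = [None] * self.n_nodes
        self._stale = np.ones(self.n_nodes, dtype=bool)
        self._gap_mask = [self.patterns[i] < 0 for i in range(self.n_tips)]
        self._safe_idx = [np.where(self._gap_mask[i], 0, self.patterns[i])
                          for i in range(self.n_tips)]

    # ------------------------------------------------------------------ #
    def set_rates(self, kappa: float, omega_by_class: Dict[int, float],
                  scaled: bool = True):
        params = CodonModelParams(kappa=kappa, omega_by_class=dict(omega_by_class),
                                  pi=self.pi, scaled=scaled)
        self._spectral = {
            cls: SpectralQ(codon_rate_matrix(params, w), self.pi)
            for cls, w in omega_by_class.items()
        }
        self._params = params
        self._P_valid[:] = False
        self._stale[:] = True

    def _effective_class(self, node: int) -> int:
        cls = int(self.classes[node])
        return cls if cls in self._spectral else 0

    def set_omega(self, cls: int, omega: float):
        """Rebuild the rate matrix of one branch class only."""
        params = self._params
        params.omega_by_class[cls] = omega
        self._spectral[cls] = SpectralQ(
            codon_rate_matrix(params, omega), self.pi)
        for v in range(self.n_nodes):
            if v != self.root and self._effective_class(v) == cls:
                self._P_valid[v] = False
                self._stale[v] = True

    def _P_for(self, node: int, t: float | None = None) -> np.ndarray:
        tt = self.lengths[node] if t is None else t
        return self._spectral[self._effective_class(node)].transition_matrix(tt)

    def _tip_msg(self, node: int, P: np.ndarray) -> np.ndarray:
        M = P[:, self._safe_idx[node]].copy()
        M[:, self._gap_mask[node]] = 1.0
        return M

    def _down_pass(self):
        """Refresh inside partials and per-edge messages (post-order),
        recomputing only branches whose P or descendants changed."""
        stale = self._stale
        for node in self.post:
            if node != self.root and not self._P_valid[node]:
                self._P[node] = self._P_for(node)
                self._P_valid[node] = True
                stale[node] = True
            if node < self.n_tips:
                if node != self.root and stale[node]:
                    self._msg[node] = self._tip_msg(node, self._P[node])
                continue
            if not stale[node] and not any(stale[c]
                                           for c in self.tree.children[node]):
                continue
            prod = None
            for c in self.tree.children[node]:
                m = self._msg[c]
                prod = m if prod is None else prod * m
            self._down[node] = prod
            if node != self.root:
                self._msg[node] = self._P[node] @ prod
            stale[node] = True
        stale[:] = False

    def loglik(self) -> float:
        self._down_pass()
        if self.n_pat == 0:
            return 0.0
        L = self.pi @ self._down[self.root]
        return float(self.weights @ np.log(np.maximum(L, _LOG_FLOOR)))

    # ------------------------------------------------------------------ #
    def edge_objective(self, node: int):
        """Return ``f(t) -> lnL`` for the edge above ``node``.

        Valid until any other parameter changes; the caller must call
        ``set_length`` with the chosen value afterwards.
        """
        if node == self.root:
            raise ValueError("the root has no edge")
        self._down_pass()
        # outside partials down to the parent of `node`
        out = {self.root: np.broadcast_to(self.pi[:, None],
                                          (N_CODONS, self.n_pat))}
        path = []
        v = node
        while v != self.root:
            path.append(v)
            v = self.tree.parent[v]
        for v in reversed(path):
            p = self.tree.parent[v]
            S = out[p]
            for sib in self.tree.children[p]:
                if sib != v:
                    S = S * self._msg[sib]
            out[v] = S if v == node else self._P[v].T @ S
        S = np.ascontiguousarray(out[node])
        if node < self.n_tips:
            down = None
        else:
            down = self._down[node]
        spectral = self._spectral.get(int(self.classes[node]),
                                      self._spectral[0])
        weights = self.weights

        def f(t: float) -> float:
            P = spectral.transition_matrix(t)
            if down is None:
                M = P[:, self._safe_idx[node]]
                L = np.einsum("ip,ip->p", S, M)
                gm = self._gap_mask[node]
                if gm.any():
                    L = L.copy()
                    L[gm] = S[:, gm].sum(axis=0)
            else:
                L = np.einsum("ip,ip->p", S, P @ down)
            return float(weights @ np.log(np.maximum(L, _LOG_FLOOR)))

        return f

    def set_length(self, node: int, t: float):
        if t != self.lengths[node]:
            self.lengths[node] = t
            self._P_valid[node] = False
            self._stale[node] = True

    def reset_lengths(self, lengths: np.ndarray):
        self.lengths = np.asarray(lengths, dtype=float).copy()
        self._P_valid[:] = False
        self._stale[:] = True


# ===================================================================== #
# nucleotide engine (numba)
# ===================================================================== #

@njit(cache=False)
def _nuc_kernel(post, parent, child0, child1, n_tips, root, lengths,
                left, eigw, right, pi, rates, cat_w, pinv,
                patterns, weights, const_state):  # pragma: no cover - compiled
    n_nodes = parent.shape[0]
    n_pat = patterns.shape[1]
    n_cat = rates.shape[0]
    site_l = np.zeros(n_pat)
    partial = np.zeros((n_nodes, 4, n_pat))
    P = np.zeros((n_nodes, 4, 4))
    for ic in range(n_cat):
        r = rates[ic]
        # transition matrices for this category
        for idx in range(n_nodes):
            node = post[idx]
            if node == root:
                continue
            t = lengths[node] * r
            for a in range(4):
                for b in range(4):
                    s = 0.0
                    for k in range(4):
                        s += left[a, k] * np.exp(eigw[k] * t) * right[k, b]
                    if s < 0.0:
                        s = 0.0
                    P[node, a, b] = s
        for idx in range(n_nodes):
            node = post[idx]
            if node < n_tips:
                continue
            c0 = child0[node]
            c1 = child1[node]
            for p in range(n_pat):
                for a in range(4):
                    # message from child c0
                    if c0 < n_tips:
                        s0 = patterns[c0, p]
                        m0 = 1.0 if s0 < 0 else P[c0, a, s0]
                    else:
                        m0 = 0.0
                        for b in range(4):
                            m0 += P[c0, a, b] * partial[c0, b, p]
                    if c1 < n_tips:
                        s1 = patterns[c1, p]
                        m1 = 1.0 if s1 < 0 else P[c1, a, s1]
                    else:
                        m1 = 0.0
                        for b in range(4):
                            m1 += P[c1, a, b] * partial[c1, b, p]
                    partial[node, a, p] = m0 * m1
        for p in range(n_pat):
            s = 0.0
            for a in range(4):
                s += pi[a] * partial[root, a, p]
            site_l[p] += cat_w[ic] * s
    lnl = 0.0
    for p in range(n_pat):
        li = (1.0 - pinv) * site_l[p]
        cs = const_state[p]
        if pinv > 0.0:
            if cs >= 0:
                li += pinv * pi[cs]
            elif cs == -1:  # all-gap column
                li += pinv
        if li < 1e-300:
            li = 1e-300
        lnl += weights[p] * np.log(li)
    return lnl


class NucLikelihood:
    """GTR+Gamma+I likelihood of a nucleotide alignment on a tree."""

    def __init__(self, tree: Phylogeny, taxa: Sequence[str],
                 states: np.ndarray, pi: np.ndarray):
        if not tree.is_binary():
            raise ValueError("nucleotide engine requires a binary tree")
        self.tree = tree
        self.pi = np.asarray(pi, dtype=float)
        tip_states = _states_for_tree(tree, taxa, states)
        self.patterns, self.weights = compress_patterns(tip_states)
        self.lengths = tree.lengths.copy()
        self.post = tree.postorder()
        self.root = tree.root
        self.n_tips = tree.n_tips
        child0 = np.full(tree.n_nodes, -1, dtype=np.int64)
        child1 = np.full(tree.n_nodes, -1, dtype=np.int64)
        for v in range(tree.n_nodes):
            if tree.children[v]:
                child0[v], child1[v] = tree.children[v]
        self._child0, self._child1 = child0, child1
        self._const = _constant_states(self.patterns)

    def set_model(self, params: NucModelParams):
        Q = gtr_rate_matrix(params)
        spec = SpectralQ(Q, params.pi)
        self._left = spec.left
        self._eigw = spec.eigenvalues
        self._right = spec.right
        self._rates = discretize_gamma(params.alpha, params.n_categories)
        self._cat_w = np.full(params.n_categories, 1.0 / params.n_categories)
        self._pinv = params.p_inv
        self.pi = params.pi

    def loglik(self) -> float:
        if self.patterns.shape[1] == 0:
            return 0.0
        return float(_nuc_kernel(
            self.post, self.tree.parent, self._child0, self._child1,
            self.n_tips, self.root, self.lengths,
            self._left, self._eigw, self._right, self.pi,
            self._rates, self._cat_w, self._pinv,
            self.patterns, self.weights, self._const))


def _constant_states(patterns: np.ndarray) -> np.ndarray:
    """Per pattern: the shared state if the column is constant (gaps allowed),
    -1 if the column is all-gap, -2 otherwise."""
    n_pat = patterns.shape[1]
    out = np.full(n_pat, -2, dtype=np.int64)
    for p in range(n_pat):
        col = patterns[:, p]
        obs = col[col >= 0]
        if obs.size == 0:
            out[p] = -1
        elif np.all(obs == obs[0]):
            out[p] = obs[0]
    return out


# ===================================================================== #
# public entry point
# ===================================================================== #

NUC_INDEX_MAP = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_nuc_rows(rows) -> np.ndarray:
    out = np.full((len(rows), len(rows[0])), -1, dtype=np.int64)
    for i, seq in enumerate(rows):
        for j, b in enumerate(seq.upper()):
            out[i, j] = NUC_INDEX_MAP.get(b, -1)
    return out


def prune_loglik(tree: Phylogeny, taxa: Sequence[str], rows: Sequence[str],
                 model) -> float:
    """Log-likelihood of aligned sequences on ``tree`` under ``model``.

    ``model`` is either :class:`CodonModelParams` (rows are in-frame codon
    strings; branch classes of the tree select the omega per branch) or
    :class:`NucModelParams` (rows are nucleotide strings; likelihood is the
    gamma+invariant mixture).
    """
    if isinstance(model, CodonModelParams):
        states = encode_codon_rows(rows)
        engine = CodonLikelihood(tree, taxa, states, model.pi)
        engine.set_rates(model.kappa, model.omega_by_class,
                         scaled=model.scaled)
        return engine.loglik()
    if isinstance(model, NucModelParams):
        states = encode_nuc_rows(rows)
        engine = NucLikelihood(tree, taxa, states, model.pi)
        engine.set_model(model)
        return engine.loglik()
    raise TypeError("model must be CodonModelParams or NucModelParams")
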