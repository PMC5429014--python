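"""Gene-tree congruence filtering.

For each QC-passed group two ML gene trees are inferred under GTR+Gamma+I
— one from all nucleotide sites, one from third codon positions only — by
exhaustive enumeration of every unrooted topology (3, 15, 105, 945 for
4-7 taxa), which guarantees the optimum RAxML-style heuristics only
approximate.  Each gene tree is compared with the species phylogeny by
quartet distance; a group is excluded only when *both* trees conflict
(quartet distance > 0 for each).

Maize homeolog pairs must form a cherry in a gene tree (otherwise that tree
fails the test outright) and are collapsed to a single maize tip before the
quartet comparison.

The topology search is staged for speed: every topology gets a coarse
branch-length-only optimization under shared rate parameters estimated once
on the species topology, then the best candidates (always including the
species topology) are refined with free alpha and invariant fraction.  The
refined winner is returned; ties break toward the canonical topology key.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._codons import nucleotide_frequencies
from .align import CodonAlignment
from .fit import GtrGeneTreeModel
from .models import NucModelParams
from .phylo import Phylogeny


def third_position_sites(aln: CodonAlignment) -> Tuple[List[str], List[str]]:
    """Third nucleotide of every codon column; gaps map to gaps."""
    rows = []
    for r in aln.rows:
        rows.append("".join(r[3 * i + 2] for i in range(aln.n_codons)))
    return list(aln.taxa), rows


def all_sites(aln: CodonAlignment) -> Tuple[List[str], List[str]]:
    return list(aln.taxa), list(aln.rows)


# ------------------------------------------------------------------ #
# topology enumeration
# ------------------------------------------------------------------ #

def _rooted_shapes(labels: Sequence[str]):
    """All rooted binary topologies over ``labels`` as nested tuples."""
    if len(labels) == 1:
        yield labels[0]
        return

    def insert(tree, x):
        yield (tree, x)
        if isinstance(tree, tuple):
            a, b = tree
            for va in insert(a, x):
                yield (va, b)
            for vb in insert(b, x):
                yield (a, vb)

    for sub in _rooted_shapes(labels[:-1]):
        yield from insert(sub, labels[-1])


def enumerate_topologies(labels: Sequence[str],
                         branch_length: float = 0.05) -> List[Phylogeny]:
    """Every unrooted binary topology over >= 4 labels.

    Each is represented rooted on the edge to ``labels[0]``: the root's
    first child is that tip with a pinned zero-length edge (its true length
    is carried by the sibling edge), which keeps the parameterization
    identifiable for reversible models.
    """
    labels = list(labels)
    if len(labels) < 4:
        raise ValueError("need at least 4 taxa for a resolved topology")
    out = []
    for shape in _rooted_shapes(labels[1:]):
        tree = Phylogeny.from_nested((labels[0], shape),
                                     tip_length=branch_length,
                                     internal_length=branch_length)
        tree.lengths[tree.tip_index[labels[0]]] = 0.0
        out.append(tree)
    return out


# ------------------------------------------------------------------ #
# quartet distance
# ------------------------------------------------------------------ #

def _topo_distances(tree: Phylogeny) -> Dict[str, Dict[str, int]]:
    """Pairwise path lengths in edges between tips."""
    n = tree.n_nodes
    depth = np.zeros(n, dtype=int)
    for v in tree.preorder():
        if v != tree.root:
            depth[v] = depth[tree.parent[v]] + 1

    def ancestors(v):
        out = []
        while v != -1:
            out.append(v)
            v = tree.parent[v]
        return out

    anc = {t: ancestors(t) for t in range(tree.n_tips)}
    dist: Dict[str, Dict[str, int]] = {}
    for a in range(tree.n_tips):
        for b in range(a + 1, tree.n_tips):
            sa = set(anc[a])
            lca = next(v for v in anc[b] if v in sa)
            d = depth[a] + depth[b] - 2 * depth[lca]
            na, nb = tree.tip_labels[a], tree.tip_labels[b]
            dist.setdefault(na, {})[nb] = int(d)
            dist.setdefault(nb, {})[na] = int(d)
    return dist


def _quartet_split(dist, a, b, c, d) -> int:
    """Induced quartet topology: 0 = ab|cd, 1 = ac|bd, 2 = ad|bc."""
    s0 = dist[a][b] + dist[c][d]
    s1 = dist[a][c] + dist[b][d]
    s2 = dist[a][d] + dist[b][c]
    m = min(s0, s1, s2)
    # in a binary tree exactly one pairing attains the strict minimum
    # unless the quartet is star-like (equal sums), which cannot happen
    # with positive internal path lengths
    if s0 == m and s1 > m and s2 > m:
        return 0
    if s1 == m and s0 > m and s2 > m:
        return 1
    if s2 == m and s0 > m and s1 > m:
        return 2
    return -1  # unresolved (defensive; not reachable for binary trees)


def quartet_distance(t1: Phylogeny, t2: Phylogeny) -> int:
    """Number of 4-tip subsets with different induced quartet topologies.

    Computed by explicit enumeration of all C(n, 4) subsets via the
    four-point condition on topological path lengths.
    """
    tips1, tips2 = set(t1.tip_labels), set(t2.tip_labels)
    if tips1 != tips2:
        raise ValueError("trees must share the same tip set")
    d1 = _topo_distances(t1)
    d2 = _topo_distances(t2)
    count = 0
    for quad in combinations(sorted(tips1), 4):
        if _quartet_split(d1, *quad) != _quartet_split(d2, *quad):
            count += 1
    return count


# ------------------------------------------------------------------ #
# gene-tree inference
# ------------------------------------------------------------------ #

@dataclass
class GeneTreeSearch:
    """Effort knobs for the exhaustive topology search.

    Every unrooted topology is screened with ordinary-least-squares branch
    lengths against the matrix of pairwise Jukes-Cantor distances (the
    minimum-evolution idea behind FastME); the ``refine_top`` best by
    residual, always joined by the reference (species) topology, are then
    fitted by full GTR+Gamma+I maximum likelihood and the max-lnL topology
    is returned.
    """

    refine_top: int = 10
    branch_cycles: int = 2
    branch_xatol: float = 1e-3
    final_cycles: int = 6
    final_branch_xatol: float = 1e-4


def _jc_distance_matrix(taxa, rows) -> np.ndarray:
    from .likelihood import encode_nuc_rows

    states = encode_nuc_rows(rows)
    n = len(taxa)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            sa, sb = states[a], states[b]
            ok = (sa >= 0) & (sb >= 0)
            tot = int(ok.sum())
            p = (float(((sa != sb) & ok).sum()) / tot) if tot else 0.0
            p = min(p, 0.7499)
            d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            D[a, b] = D[b, a] = d
    return D


def _ols_fit(tree: Phylogeny, taxa_index: Dict[str, int],
             D: np.ndarray) -> Tuple[float, np.ndarray]:
    """OLS branch lengths against the distance matrix.

    Returns the residual sum of squares and the fitted (non-negative)
    per-node branch lengths, used both to rank topologies and to
    initialize the ML branch-length fits."""
    n_tips = tree.n_tips
    pairs = list(combinations(range(n_tips), 2))
    edges = [v for v in range(tree.n_nodes) if v != tree.root]
    edge_col = {v: k for k, v in enumerate(edges)}
    A = np.zeros((len(pairs), len(edges)))
    anc = {}
    for t in range(n_tips):
        path = []
        v = t
        while v != tree.root:
            path.append(v)
            v = tree.parent[v]
        anc[t] = path
    for r, (a, b) in enumerate(pairs):
        sa = set(anc[a])
        onpath = sa.symmetric_difference(anc[b])
        for v in onpath:
            A[r, edge_col[v]] = 1.0
    d = np.array([D[taxa_index[tree.tip_labels[a]],
                    taxa_index[tree.tip_labels[b]]] for a, b in pairs])
    x, *_ = np.linalg.lstsq(A, d, rcond=None)
    x = np.maximum(x, 0.0)
    resid = d - A @ x
    lengths = np.zeros(tree.n_nodes)
    for v, k in edge_col.items():
        lengths[v] = max(x[k], 1e-4)
    return float(resid @ resid), lengths


def infer_gene_tree(taxa: Sequence[str], rows: Sequence[str],
                    model: Optional[NucModelParams] = None,
                    ensure: Optional[Phylogeny] = None,
                    search: Optional[GeneTreeSearch] = None
                    ) -> Tuple[Phylogeny, float]:
    """ML gene tree over all unrooted topologies (distance screen + ML).

    Returns ``(tree, lnL)``.  ``ensure`` (typically the species topology)
    is always carried into the ML stage, so the returned lnL is never
    below the species topology's refined lnL.
    """
    taxa = list(taxa)
    if len(taxa) < 4:
        raise ValueError("gene-tree inference needs at least 4 taxa")
    if len(taxa) > 7:
        raise ValueError("exhaustive search supports at most 7 taxa")
    search = search or GeneTreeSearch()
    base = model or NucModelParams(alpha=1.0, p_inv=0.1, n_categories=4)

    topologies = enumerate_topologies(sorted(taxa))
    taxa_index = {t: i for i, t in enumerate(taxa)}
    D = _jc_distance_matrix(taxa, rows)
    scored = []
    for t in topologies:
        rss, lengths = _ols_fit(t, taxa_index, D)
        scored.append((rss, t.topology_key(), t, lengths))
    scored.sort(key=lambda s: (s[0], s[1]))
    shortlist = scored[:search.refine_top]
    if ensure is not None:
        # the rooted key of `ensure` can differ from its tip-rooted twin,
        # so match on quartet distance, not on the key
        if not any(quartet_distance(t, ensure) == 0
                   for _, _, t, _ in shortlist):
            rss, lengths = _ols_fit(ensure, taxa_index, D)
            shortlist.append((rss, ensure.topology_key(), ensure, lengths))

    def full_fit(topo, lengths):
        start = topo.copy()
        start.lengths = _pin_root_tip(start, lengths)
        m = GtrGeneTreeModel(taxa, rows, start, params=base)
        return m.fit(max_cycles=search.final_cycles,
                     branch_xatol=search.final_branch_xatol, tol=1e-4)

    # shared rate parameters from a full fit of the best-screened topology
    ref_fit = full_fit(shortlist[0][2], shortlist[0][3])
    shared = NucModelParams(
        exchangeabilities=base.exchangeabilities.copy(),
        pi=nucleotide_frequencies(rows),
        alpha=ref_fit.params["alpha"], p_inv=ref_fit.params["p_inv"],
        n_categories=base.n_categories)

    # rank the shortlist by branch-length-only ML under the shared rates
    ranked = []
    for _, key, topo, lengths in shortlist:
        start = topo.copy()
        start.lengths = _pin_root_tip(start, lengths)
        m = GtrGeneTreeModel(taxa, rows, start, params=shared)
        fit = m.fit(free_alpha=False, free_pinv=False,
                    max_cycles=search.branch_cycles,
                    branch_xatol=search.branch_xatol, tol=1e-3)
        ranked.append((fit.lnl, key, topo, lengths))
    ranked.sort(key=lambda s: (-s[0], s[1]))

    # full per-topology fits (branch lengths + alpha + p_inv) for the
    # winner and, when supplied, the reference topology
    finalists = [ranked[0]]
    if ensure is not None and quartet_distance(ranked[0][2], ensure) != 0:
        finalists.append(next(
            s for s in ranked if quartet_distance(s[2], ensure) == 0))
    best = None
    for _, key, topo, lengths in finalists:
        fit = full_fit(topo, lengths)
        # higher lnL wins; exact ties break toward the smaller canonical key
        if (best is None or fit.lnl > best[0]
                or (fit.lnl == best[0] and key < best[1])):
            best = (fit.lnl, key, fit.tree)
    return best[2], float(best[0])


def _pin_root_tip(tree: Phylogeny, lengths: np.ndarray) -> np.ndarray:
    """Zero the edge of a tip attached directly to the root, moving its
    OLS length onto the sibling edge (the two are one unrooted edge)."""
    out = np.asarray(lengths, dtype=float).copy()
    kids = tree.children[tree.root]
    tips = [v for v in kids if v < tree.n_tips]
    if len(kids) == 2 and len(tips) == 1:
        sib = kids[0] if kids[1] == tips[0] else kids[1]
        out[sib] += out[tips[0]]
        out[tips[0]] = 0.0
    return out


# ------------------------------------------------------------------ #
# the congruence verdict
# ------------------------------------------------------------------ #

@dataclass
class CongruenceVerdict:
    """Outcome of the two-tree congruence test for one group."""

    tree_all_sites: Optional[Phylogeny]
    tree_third_positions: Optional[Phylogeny]
    qdist_all: Optional[int]
    qdist_third: Optional[int]
    passed: bool
    note: str = ""


def _homeolog_check_and_collapse(tree: Phylogeny,
                                 homeologs: Sequence[str],
                                 collapsed_label: str = "Zm"
                                 ) -> Optional[Phylogeny]:
    """Verify the homeolog pair is a cherry; collapse it to one tip.

    Returns None when the homeologs are not sisters (that gene tree fails
    the congruence test).
    """
    h1, h2 = homeologs
    i1 = tree.tip_index[h1]
    p = tree.parent[i1]
    kids = tree.children[p]
    if len(kids) != 2 or tree.tips_below(p) != frozenset({h1, h2}):
        return None
    rest = [t for t in tree.tip_labels if t != h2]
    collapsed = tree.restrict(rest)
    return collapsed.relabeled({h1: collapsed_label})


def congruence_test(aln: CodonAlignment, species_tree: Phylogeny,
                    homeologs: Optional[Sequence[str]] = None,
                    model: Optional[NucModelParams] = None,
                    search: Optional[GeneTreeSearch] = None
                    ) -> CongruenceVerdict:
    """Two-tree congruence test against the species phylogeny.

    ``species_tree`` must already be restricted to the group's taxa (with
    a single maize tip); ``homeologs`` names the pair of maize homeolog
    rows in the alignment, if any.  Pass requires at least one of the two
    gene trees (all sites / third positions) to have quartet distance 0
    from the species tree.
    """
    ref_tips = set(species_tree.tip_labels)
    qdists = []
    trees = []
    notes = []
    ensure = None
    if homeologs:
        if "Zm" not in ref_tips:
            raise ValueError("homeolog groups need a maize tip in the "
                             "species tree")
        ensure = species_tree.with_tip_expanded("Zm", tuple(homeologs))
    for taxa, rows in (all_sites(aln), third_position_sites(aln)):
        tree, _ = infer_gene_tree(
            taxa, rows, model=model, search=search,
            ensure=ensure if homeologs else species_tree)
        trees.append(tree)
        if homeologs:
            collapsed = _homeolog_check_and_collapse(tree, homeologs)
            if collapsed is None:
                qdists.append(None)
                notes.append("homeologs not sisters")
                continue
            tree = collapsed
        qdists.append(quartet_distance(tree, species_tree))
    passed = any(q == 0 for q in qdists if q is not None)
    return CongruenceVerdict(
        tree_all_sites=trees[0], tree_third_positions=trees[1],
        qdist_all=qdists[0], qdist_third=qdists[1],
        passed=passed, note="; ".join(notes))
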