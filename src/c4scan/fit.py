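"""Maximum-likelihood fitting of the substitution models and the branch LRT.

Model objects are built from data (an alignment plus a class-labeled tree)
and ``fit()`` returns a results object carrying the estimates, the final
log-likelihood, convergence diagnostics and a ``summary()`` table.

Optimization is deterministic coordinate cycling: each branch length gets a
bounded 1-D line search against a cached-partial objective, then the global
rate parameters (kappa and the per-class omegas, or alpha and the
invariant-site proportion for the nucleotide model) are line-searched in
turn, until the cycle improves the log-likelihood by less than ``tol``.
Rate ratios are searched on a log scale; the first omega pass scans three
fixed windows (anchored at 0.1, 0.5 and 2.0) so a fit never commits to the
wrong side of a bimodal omega profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from ._codons import encode_codon_rows, f3x4_frequencies, nucleotide_frequencies
from .likelihood import (CodonLikelihood, NucLikelihood, encode_nuc_rows)
from .models import CodonModelParams, NucModelParams
from .phylo import FOREGROUND, Phylogeny

OMEGA_BOUNDS = (1e-4, 50.0)
KAPPA_BOUNDS = (1e-3, 100.0)
BRANCH_BOUNDS = (0.0, 20.0)
ALPHA_BOUNDS = (0.05, 20.0)
PINV_BOUNDS = (0.0, 0.9)

#: fixed multi-start anchors for the first omega line search
OMEGA_STARTS = (0.1, 0.5, 2.0)


def _maximize(f, lo, hi, xatol):
    """Deterministic bounded 1-D maximization; returns (x, f(x))."""
    res = minimize_scalar(lambda x: -f(x), bounds=(lo, hi),
                          method="bounded", options={"xatol": xatol})
    return float(res.x), float(-res.fun)


def _maximize_log(f, lo, hi, xatol):
    x, v = _maximize(lambda y: f(np.exp(y)), np.log(lo), np.log(hi), xatol)
    return float(np.exp(x)), v


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    lnl: float
    params: dict
    tree: Phylogeny
    iterations: int
    converged: bool

    def summary(self) -> str:
        lines = [
            "Maximum-likelihood fit",
            "----------------------",
            f"log-likelihood  {self.lnl:.6f}",
            f"cycles          {self.iterations}"
            f"{' (converged)' if self.converged else ' (NOT converged)'}",
        ]
        for k, v in self.params.items():
            if isinstance(v, float):
                lines.append(f"{k:<15} {v:.6g}")
            else:
                lines.append(f"{k:<15} {v}")
        lines.append(f"tree            {self.tree.newick(digits=6)}")
        return "\n".join(lines)


@dataclass
class LrtResult:
    """Branch-model likelihood-ratio test.

    ``stat = 2 (lnL1 - lnL0)`` (clamped at zero) is referred to a
    chi-square with one degree of freedom.  ``omega_fg``/``omega_bg`` are
    the alternative-model estimates; both are NaN for degenerate
    (variation-free) alignments, where the test is reported as stat 0, p 1.
    """

    lnl0: float
    lnl1: float
    stat: float
    df: int
    p: float
    omega_fg: float
    omega_bg: float
    kappa: float = np.nan
    omega0: float = np.nan
    degenerate: bool = False


def merge_root_edges(tree: Phylogeny):
    """Collapse the two root-adjacent edges into one unrooted edge.

    Under a reversible model only the *sum* of the two root-child edge
    lengths is identifiable, and in codeml's unrooted branch model they are
    a single edge with a single omega class.  The foreground-classed child
    (or the first child) carries the summed length and the merged class;
    the other is pinned at zero and excluded from optimization.

    Returns ``(canonical tree, pinned node or None)``.
    """
    out = tree.copy()
    kids = out.children[out.root]
    if len(kids) != 2:
        return out, None
    a, b = kids
    carrier = b if (out.classes[b] == FOREGROUND
                    and out.classes[a] != FOREGROUND) else a
    other = b if carrier == a else a
    out.lengths[carrier] = out.lengths[a] + out.lengths[b]
    out.lengths[other] = 0.0
    merged_class = max(out.classes[a], out.classes[b])
    out.classes[carrier] = merged_class
    out.classes[other] = merged_class
    return out, other


def _has_variation(patterns: np.ndarray) -> bool:
    """True if any column holds two different non-gap states."""
    for p in range(patterns.shape[1]):
        col = patterns[:, p]
        obs = col[col >= 0]
        if obs.size > 1 and not np.all(obs == obs[0]):
            return True
    return False


# ===================================================================== #
class CodonBranchModel:
    """GY94 branch model over a codon alignment and a class-labeled tree.

    Parameters
    ----------
    taxa, rows :
        Aligned in-frame codon sequences (rows of equal length, gaps
        allowed) and their names; names must be tips of ``tree``.
    tree :
        Rooted :class:`Phylogeny`; its ``classes`` array assigns each
        branch to background (0) or foreground (1).
    pi :
        61 codon frequencies; by default the empirical F3x4 frequencies of
        the alignment (frequencies are never optimized).
    """

    def __init__(self, taxa: Sequence[str], rows: Sequence[str],
                 tree: Phylogeny, pi: Optional[np.ndarray] = None):
        self.taxa = list(taxa)
        self.rows = list(rows)
        self.tree, self._pinned = merge_root_edges(tree)
        self.pi = f3x4_frequencies(rows) if pi is None else np.asarray(pi)
        self._states = encode_codon_rows(rows)
        self._engine = CodonLikelihood(self.tree, self.taxa, self._states,
                                       self.pi)

    @property
    def has_variation(self) -> bool:
        return _has_variation(self._engine.patterns)

    def loglik(self, kappa: float, omega_by_class: Dict[int, float],
               lengths: Optional[np.ndarray] = None) -> float:
        eng = self._engine
        if lengths is not None:
            eng.reset_lengths(lengths)
        eng.set_rates(kappa, omega_by_class)
        return eng.loglik()

    def fit(self, share_omega: bool = False, *,
            start_kappa: float = 2.0,
            start_omega: Optional[Dict[int, float]] = None,
            start_lengths: Optional[np.ndarray] = None,
            free_branch_lengths: bool = True,
            free_kappa: bool = True,
            free_omega: bool = True,
            multistart_omega: bool = True,
            wide_first_kappa: bool = True,
            tol: float = 1e-6, max_cycles: int = 200) -> FitResult:
        """Coordinate-cycling ML fit; see the module docstring."""
        eng = self._engine
        classes = ({0} if share_omega
                   else {int(c) for i, c in enumerate(self.tree.classes)
                         if i != self.tree.root} or {0})
        if start_omega is None:
            omegas = {c: 0.5 for c in sorted(classes)}
        else:
            omegas = {c: float(start_omega.get(c, 0.5)) for c in sorted(classes)}
        kappa = float(start_kappa)
        eng.reset_lengths(start_lengths if start_lengths is not None
                          else self.tree.lengths)
        eng.set_rates(kappa, omegas)
        lnl = eng.loglik()

        if not self.has_variation:
            # no information: report the initial state unchanged
            return self._result(lnl, kappa, omegas, eng.lengths, 0, True)

        free_any = free_branch_lengths or free_kappa or free_omega
        if not free_any or (tol is None):
            return self._result(lnl, kappa, omegas, eng.lengths, 0, True)

        first_omega_pass = multistart_omega
        cycles = 0
        converged = False
        order = [v for v in eng.post
                 if v != self.tree.root and v != self._pinned]
        for cycle in range(max_cycles):
            cycles = cycle + 1
            prev = lnl
            xatol = 1e-4 if cycle < 2 else 1e-6
            if free_branch_lengths:
                for node in order:
                    fobj = eng.edge_objective(node)
                    cur_t = eng.lengths[node]
                    t, val = _maximize(fobj, *BRANCH_BOUNDS, xatol=xatol)
                    if val >= lnl:
                        eng.set_length(node, t)
                        lnl = val
            if free_kappa:
                def fk(k):
                    eng.set_rates(k, omegas)
                    return eng.loglik()
                lo = max(KAPPA_BOUNDS[0], kappa / 10.0)
                hi = min(KAPPA_BOUNDS[1], kappa * 10.0)
                if cycle == 0 and wide_first_kappa:
                    lo, hi = KAPPA_BOUNDS
                k, val = _maximize_log(fk, lo, hi, xatol=2e-3)
                if val >= lnl:
                    kappa = k
                    lnl = val
            if free_omega:
                eng.set_rates(kappa, omegas)
                for cls in sorted(omegas):
                    def fw(w, _cls=cls):
                        eng.set_omega(_cls, w)
                        return eng.loglik()
                    if first_omega_pass:
                        best = None
                        for anchor in OMEGA_STARTS:
                            lo = max(OMEGA_BOUNDS[0], anchor / 8.0)
                            hi = min(OMEGA_BOUNDS[1], anchor * 8.0)
                            cand = _maximize_log(fw, lo, hi, xatol=2e-3)
                            if best is None or cand[1] > best[1]:
                                best = cand
                        w, val = best
                    else:
                        lo = max(OMEGA_BOUNDS[0], omegas[cls] / 8.0)
                        hi = min(OMEGA_BOUNDS[1], omegas[cls] * 8.0)
                        w, val = _maximize_log(fw, lo, hi, xatol=2e-3)
                    if val >= lnl:
                        omegas[cls] = w
                        lnl = val
                    eng.set_omega(cls, omegas[cls])
                first_omega_pass = False
            eng.set_rates(kappa, omegas)
            if lnl - prev < tol:
                converged = True
                break
        return self._result(lnl, kappa, omegas, eng.lengths, cycles, converged)

    def _result(self, lnl, kappa, omegas, lengths, cycles, converged):
        tree = self.tree.copy()
        tree.lengths = np.asarray(lengths, dtype=float).copy()
        params = {"kappa": kappa}
        for c in sorted(omegas):
            name = "omega_fg" if c == FOREGROUND and len(omegas) > 1 else (
                "omega_bg" if len(omegas) > 1 else "omega")
            params[name] = omegas[c]
        params["omega_by_class"] = dict(omegas)
        return FitResult(lnl=float(lnl), params=params, tree=tree,
                         iterations=cycles, converged=converged)


# ===================================================================== #
class GtrGeneTreeModel:
    """GTR+Gamma+I model of a nucleotide alignment on a fixed topology."""

    def __init__(self, taxa: Sequence[str], rows: Sequence[str],
                 tree: Phylogeny, params: Optional[NucModelParams] = None):
        self.taxa = list(taxa)
        self.rows = list(rows)
        self.tree = tree
        pi = nucleotide_frequencies(rows)
        base = params if params is not None else NucModelParams()
        self.params = NucModelParams(
            exchangeabilities=base.exchangeabilities.copy(), pi=pi,
            alpha=base.alpha, p_inv=base.p_inv,
            n_categories=base.n_categories)
        self._states = encode_nuc_rows(rows)
        self._engine = NucLikelihood(tree, self.taxa, self._states, pi)
        self._fixed_zero = {
            v for v in range(tree.n_nodes)
            if v != tree.root and tree.lengths[v] == 0.0 and v < tree.n_tips
            and tree.parent[v] == tree.root
        }

    def loglik(self) -> float:
        self._engine.set_model(self.params)
        return self._engine.loglik()

    def fit(self, *, free_branch_lengths: bool = True, free_alpha: bool = True,
            free_pinv: bool = True, free_exchangeabilities: bool = False,
            tol: float = 1e-4, max_cycles: int = 20,
            branch_xatol: float = 1e-5) -> FitResult:
        eng = self._engine
        p = self.params
        eng.set_model(p)
        lnl = eng.loglik()
        order = [v for v in eng.post
                 if v != self.tree.root and v not in self._fixed_zero]
        cycles = 0
        converged = False
        for cycle in range(max_cycles):
            cycles = cycle + 1
            prev = lnl
            if free_branch_lengths:
                for node in order:
                    def fb(t, _n=node):
                        eng.lengths[_n] = t
                        return eng.loglik()
                    cur = eng.lengths[node]
                    t, val = _maximize(fb, *BRANCH_BOUNDS, xatol=branch_xatol)
                    if val >= lnl:
                        eng.lengths[node] = t
                        lnl = val
                    else:
                        eng.lengths[node] = cur
            if free_exchangeabilities:
                for k in range(5):  # GT rate is the fixed reference
                    def fe(s, _k=k):
                        p.exchangeabilities[_k] = s
                        eng.set_model(p)
                        return eng.loglik()
                    cur = p.exchangeabilities[k]
                    s, val = _maximize_log(fe, 1e-3, 100.0, xatol=2e-3)
                    p.exchangeabilities[k] = s if val >= lnl else cur
                    lnl = max(lnl, val)
                    eng.set_model(p)
            if free_alpha:
                def fa(a):
                    p.alpha = a
                    eng.set_model(p)
                    return eng.loglik()
                cur = p.alpha
                a, val = _maximize_log(fa, *ALPHA_BOUNDS, xatol=2e-3)
                p.alpha = a if val >= lnl else cur
                lnl = max(lnl, val)
                eng.set_model(p)
            if free_pinv:
                def fp(q):
                    p.p_inv = q
                    eng.set_model(p)
                    return eng.loglik()
                cur = p.p_inv
                q, val = _maximize(fp, *PINV_BOUNDS, xatol=1e-3)
                p.p_inv = q if val >= lnl else cur
                lnl = max(lnl, val)
                eng.set_model(p)
            if lnl - prev < tol:
                converged = True
                break
        tree = self.tree.copy()
        tree.lengths = eng.lengths.copy()
        params = {"alpha": p.alpha, "p_inv": p.p_inv,
                  "exchangeabilities": p.exchangeabilities.copy()}
        return FitResult(lnl=float(lnl), params=params, tree=tree,
                         iterations=cycles, converged=converged)


# ===================================================================== #
def fit_model(tree: Phylogeny, taxa: Sequence[str], rows: Sequence[str],
              model_spec, free: Optional[set] = None, **kwargs) -> FitResult:
    """Generic ML fit dispatching on the model family.

    ``free`` is a subset of ``{"branch_lengths", "kappa", "omega",
    "alpha", "p_inv", "exchangeabilities"}``; an empty set returns the
    initial log-likelihood unchanged.
    """
    if free is None:
        free = {"branch_lengths", "kappa", "omega", "alpha", "p_inv"}
    if isinstance(model_spec, CodonModelParams):
        model = CodonBranchModel(taxa, rows, tree, pi=model_spec.pi)
        share = len(model_spec.omega_by_class) == 1
        return model.fit(
            share_omega=share,
            start_kappa=model_spec.kappa,
            start_omega=model_spec.omega_by_class,
            free_branch_lengths="branch_lengths" in free,
            free_kappa="kappa" in free,
            free_omega="omega" in free,
            **kwargs)
    if isinstance(model_spec, NucModelParams):
        model = GtrGeneTreeModel(taxa, rows, tree, params=model_spec)
        return model.fit(
            free_branch_lengths="branch_lengths" in free,
            free_alpha="alpha" in free,
            free_pinv="p_inv" in free,
            free_exchangeabilities="exchangeabilities" in free,
            **kwargs)
    raise TypeError("model_spec must be CodonModelParams or NucModelParams")


def lrt_branch_model(taxa: Sequence[str], rows: Sequence[str],
                     tree: Phylogeny, tol: float = 1e-6,
                     start_kappa: float = 2.0,
                     start_omega: float = 0.5,
                     informed_start: bool = False) -> LrtResult:
    """Branch-model LRT: one shared omega (H0) vs foreground/background (Ha).

    The tree's branch classes define the foreground set, which must be a
    nonempty strict subset of branches.  Both fits share the empirical F3x4
    codon frequencies of the alignment.  Variation-free alignments are
    reported as stat 0, p 1 with undefined omega estimates.

    ``informed_start`` marks ``start_kappa``/``start_omega`` as coming from
    a fit of the same gene under a nested condition, which narrows the
    first line searches around them (the batch scan uses this; results are
    still deterministic).
    """
    non_root = [v for v in range(tree.n_nodes) if v != tree.root]
    fg = [v for v in non_root if tree.classes[v] == FOREGROUND]
    if not fg:
        raise ValueError("foreground branch set is empty; test undefined")
    if len(fg) == len(non_root):
        raise ValueError("every branch is foreground; test undefined")

    model = CodonBranchModel(taxa, rows, tree)
    if not model.has_variation:
        lnl = model.loglik(2.0, {0: 0.5})
        return LrtResult(lnl0=lnl, lnl1=lnl, stat=0.0, df=1, p=1.0,
                         omega_fg=np.nan, omega_bg=np.nan, degenerate=True)

    r0 = model.fit(share_omega=True, tol=tol,
                   start_kappa=start_kappa, start_omega={0: start_omega},
                   multistart_omega=not informed_start,
                   wide_first_kappa=not informed_start)
    w0 = r0.params["omega_by_class"][0]
    r1 = model.fit(
        share_omega=False,
        start_kappa=r0.params["kappa"],
        start_omega={0: w0, 1: w0},
        start_lengths=r0.tree.lengths,
        multistart_omega=False,
        tol=tol)
    lnl0, lnl1 = r0.lnl, r1.lnl
    stat = 2.0 * (lnl1 - lnl0)
    if stat < -1e-6:
        raise RuntimeError(
            f"alternative fit below null fit (stat={stat:.3g}); "
            "optimizer failure")
    stat = max(stat, 0.0)
    return LrtResult(
        lnl0=lnl0, lnl1=lnl1, stat=stat, df=1,
        p=float(chi2.sf(stat, df=1)),
        omega_fg=r1.params["omega_by_class"][FOREGROUND],
        omega_bg=r1.params["omega_by_class"][0],
        kappa=r1.params["kappa"], omega0=w0)
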