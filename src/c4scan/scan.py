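"""The nine-condition branch-model selection scan.

Condition 1 tests the full phylogeny; conditions 2-7 remove one or two C4
lineages so selection restricted to a subset of C4 origins is not missed;
conditions 8 and 9 remove Dichanthelium and the whole Setaria-Dichanthelium
clade to probe how much detection power that clade contributes.  For every
(group x condition) with at least four remaining taxa, the C4 transition
branches are labeled foreground and the branch-model likelihood-ratio test
of :func:`c4scan.fit.lrt_branch_model` is run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import CodonAlignment
from .fit import LrtResult, lrt_branch_model
from .phylo import BACKGROUND, FOREGROUND, Phylogeny

C4_SPECIES = frozenset({"Zm", "Sb", "Si"})
C3_SPECIES = frozenset({"Do", "Os", "Bd"})

#: condition id -> species removed before testing
CONDITION_REMOVALS: Dict[int, frozenset] = {
    1: frozenset(),
    2: frozenset({"Zm"}),
    3: frozenset({"Sb"}),
    4: frozenset({"Si"}),
    5: frozenset({"Zm", "Sb"}),
    6: frozenset({"Sb", "Si"}),
    7: frozenset({"Zm", "Si"}),
    8: frozenset({"Do"}),
    9: frozenset({"Si", "Do"}),
}

MIN_TAXA = 4


@dataclass(frozen=True)
class Condition:
    """One phylogenetic testing condition."""

    id: int

    @property
    def removed(self) -> frozenset:
        return CONDITION_REMOVALS[self.id]


def species_of(tip_label: str) -> str:
    """Species code of a tip (homeolog suffixes stripped)."""
    return tip_label.split("_")[0]


def label_foreground(tree: Phylogeny, rule: str = "stem_only") -> Phylogeny:
    """Mark the C4 transition branches as foreground on a copy of ``tree``.

    Tips are C4 when their species is Zm, Sb or Si (maize homeolog tips
    inherit maize's tag).  Under the default ``stem_only`` rule the
    foreground is the stem branch of every maximal all-C4 clade —
    the branches on which C3-to-C4 transitions are inferred; ``clade_all``
    additionally marks every branch inside those clades.
    """
    if rule not in ("stem_only", "clade_all"):
        raise ValueError("rule must be 'stem_only' or 'clade_all'")
    out = tree.copy()
    is_c4 = np.zeros(out.n_nodes, dtype=bool)
    for v in out.postorder():
        if v < out.n_tips:
            is_c4[v] = species_of(out.tip_labels[v]) in C4_SPECIES
        else:
            is_c4[v] = all(is_c4[c] for c in out.children[v])
    if is_c4[out.root]:
        raise ValueError("all tips are C4; test undefined")
    if not is_c4.any():
        raise ValueError("no C4 tips; test undefined")
    out.classes[:] = BACKGROUND
    for v in range(out.n_nodes):
        if v == out.root or not is_c4[v]:
            continue
        if not is_c4[out.parent[v]] or rule == "clade_all":
            out.classes[v] = FOREGROUND
    return out


def base_tree_for_taxa(taxa: Iterable[str], species_tree: Phylogeny,
                       cherry_length: float = 0.02) -> Phylogeny:
    """Species tree restricted to a group's taxa, expanding the maize tip
    into a homeolog cherry when the group carries two maize members."""
    taxa = list(taxa)
    homeologs = sorted(t for t in taxa if species_of(t) == "Zm"
                       and t != "Zm")
    plain = [t for t in taxa if t not in homeologs]
    keep = set(plain) | ({"Zm"} if homeologs else set())
    tree = species_tree.restrict(keep)
    if homeologs:
        if len(homeologs) != 2:
            raise ValueError("expected exactly two maize homeolog tips")
        tree = tree.with_tip_expanded("Zm", homeologs,
                                      cherry_length=cherry_length)
    return tree


def enumerate_conditions(taxa: Sequence[str], species_tree: Phylogeny,
                         conditions: Optional[Sequence[int]] = None,
                         foreground_rule: str = "stem_only",
                         min_taxa: int = MIN_TAXA,
                         cherry_length: float = 0.02
                         ) -> List[Tuple[Condition, Optional[Phylogeny], int, str]]:
    """Per condition: the pruned, foreground-labeled testing tree.

    Returns tuples ``(condition, tree_or_None, n_tips, status)`` where
    status is ``tested``, ``skipped_min_taxa`` or ``skipped_qc`` (no
    foreground/background contrast after pruning).  Homeolog tips each
    count as one tip toward the minimum-taxa rule.
    """
    base = base_tree_for_taxa(taxa, species_tree,
                              cherry_length=cherry_length)
    out = []
    for cid in (conditions if conditions is not None
                else sorted(CONDITION_REMOVALS)):
        cond = Condition(cid)
        keep = [t for t in base.tip_labels
                if species_of(t) not in cond.removed]
        n_tips = len(keep)
        if n_tips < min_taxa:
            out.append((cond, None, n_tips, "skipped_min_taxa"))
            continue
        pruned = base.restrict(keep)
        try:
            labeled = label_foreground(pruned, rule=foreground_rule)
        except ValueError:
            out.append((cond, None, n_tips, "skipped_qc"))
            continue
        out.append((cond, labeled, n_tips, "tested"))
    return out


SCAN_COLUMNS = ["group_id", "condition", "n_tips", "lnl0", "lnl1",
                "stat", "p", "omega_fg", "omega_bg", "status"]


def run_scan(alignments: Dict[str, CodonAlignment],
             species_tree: Phylogeny,
             conditions: Optional[Sequence[int]] = None,
             foreground_rule: str = "stem_only",
             min_taxa: int = MIN_TAXA,
             cherry_length: float = 0.02) -> pd.DataFrame:
    """Branch-model LRTs for every applicable (group x condition).

    ``alignments`` maps group id to its QC-passed codon alignment, whose
    taxon names are species codes (maize homeologs ``Zm_h1``/``Zm_h2``).
    Returns one row per (group x condition), ordered by group then
    condition; individual failures become ``failed`` rows, never an abort.
    """
    records = []
    for gid in sorted(alignments):
        aln = alignments[gid]
        plan = enumerate_conditions(
            aln.taxa, species_tree, conditions=conditions,
            foreground_rule=foreground_rule, min_taxa=min_taxa,
            cherry_length=cherry_length)
        warm: Optional[LrtResult] = None
        for cond, tree, n_tips, status in plan:
            row = {"group_id": gid, "condition": cond.id, "n_tips": n_tips,
                   "lnl0": np.nan, "lnl1": np.nan, "stat": np.nan,
                   "p": np.nan, "omega_fg": np.nan, "omega_bg": np.nan,
                   "status": status}
            if status == "tested":
                sub = aln.subset(tree.tip_labels)
                try:
                    if warm is not None and not warm.degenerate:
                        res = lrt_branch_model(
                            sub.taxa, sub.rows, tree,
                            start_kappa=warm.kappa,
                            start_omega=warm.omega0,
                            informed_start=True)
                    else:
                        res = lrt_branch_model(sub.taxa, sub.rows, tree)
                    row.update(lnl0=res.lnl0, lnl1=res.lnl1, stat=res.stat,
                               p=res.p, omega_fg=res.omega_fg,
                               omega_bg=res.omega_bg)
                    if warm is None:
                        warm = res
                except Exception as exc:  # pragma: no cover - defensive
                    row["status"] = f"failed:{type(exc).__name__}"
            records.append(row)
    return pd.DataFrame.from_records(records, columns=SCAN_COLUMNS)
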