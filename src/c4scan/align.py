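"""Codon-aware multiple alignment, conserved-block trimming and coverage QC.

Each ortholog group's CDSs are translated, progressively aligned at the
protein level along the species-tree guide topology (global profile-profile
alignment, BLOSUM62, affine gaps), and back-translated to codons.  The
resulting codon alignment is trimmed to its conserved blocks with a
from-scratch implementation of the Gblocks column/block rules, and groups
whose trimmed alignment keeps less than 30% of the original codon columns
are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from ._codons import GENETIC_CODE
from .phylo import Phylogeny

GAP_CODON = "---"


class InternalStopError(ValueError):
    """CDS contains an in-frame stop before its final codon."""


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS (universal code); terminal stop dropped.

    Ambiguous codons translate to X.  An internal stop raises
    :class:`InternalStopError`; the pipeline excludes such groups.
    """
    s = cds.upper().replace("U", "T")
    if len(s) % 3 != 0:
        raise ValueError(f"CDS length {len(s)} not divisible by 3")
    aas = []
    n = len(s) // 3
    for c in range(n):
        codon = s[3 * c: 3 * c + 3]
        aa = GENETIC_CODE.get(codon, "X")
        if aa == "*":
            if c == n - 1:
                break  # terminal stop dropped
            raise InternalStopError(
                f"internal stop codon at codon {c + 1} of {n}")
        aas.append(aa)
    return "".join(aas)


def strip_terminal_stop(cds: str) -> str:
    s = cds.upper().replace("U", "T")
    if len(s) % 3 == 0 and len(s) >= 3:
        if GENETIC_CODE.get(s[-3:], "X") == "*":
            return s[:-3]
    return s


@dataclass
class CodonAlignment:
    """Gap-padded, in-frame codon matrix over named taxa."""

    taxa: List[str]
    rows: List[str]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(self.rows) != len(self.taxa):
            raise ValueError("row/taxon count mismatch")
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if self.rows and len(self.rows[0]) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def ungapped(self, taxon: str) -> str:
        return self.row(taxon).replace("-", "")

    def subset(self, taxa: Sequence[str]) -> "CodonAlignment":
        keep = [t for t in self.taxa if t in set(taxa)]
        return CodonAlignment(keep, [self.row(t) for t in keep])

    def codon_columns(self, indices: Sequence[int]) -> "CodonAlignment":
        rows = []
        for r in self.rows:
            rows.append("".join(r[3 * i: 3 * i + 3] for i in indices))
        return CodonAlignment(list(self.taxa), rows)

    def protein_rows(self) -> List[str]:
        out = []
        for r in self.rows:
            aas = []
            for i in range(self.n_codons):
                codon = r[3 * i: 3 * i + 3]
                if codon == GAP_CODON:
                    aas.append("-")
                else:
                    aas.append(GENETIC_CODE.get(codon, "X"))
            out.append("".join(aas))
        return out


# ===================================================================== #
# progressive protein-profile alignment
# ===================================================================== #

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHABET = _BLOSUM.alphabet
_AA_INDEX = {a: i for i, a in enumerate(_ALPHABET)}
_BLOSUM_ARR = np.array(_BLOSUM, dtype=float)

GAP_OPEN = 10.0    # cost of the first residue of a gap
GAP_EXTEND = 0.5   # cost of each further residue


@njit(cache=False)
def _gotoh(S, open_, ext):  # pragma: no cover - compiled
    """Global affine-gap DP on a column-score matrix; returns the traceback
    as an array of moves (0 diag, 1 up/gap-in-B, 2 left/gap-in-A) in
    reverse order, plus the alignment score.  Ties prefer diag > up > left
    (explicit pointer matrices keep the traceback exact)."""
    nA, nB = S.shape
    NEG = -1e30
    M = np.full((nA + 1, nB + 1), NEG)
    X = np.full((nA + 1, nB + 1), NEG)  # consumes A (gap in B)
    Y = np.full((nA + 1, nB + 1), NEG)  # consumes B (gap in A)
    tbM = np.zeros((nA + 1, nB + 1), dtype=np.int8)
    tbX = np.zeros((nA + 1, nB + 1), dtype=np.int8)
    tbY = np.zeros((nA + 1, nB + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, nA + 1):
        X[i, 0] = -open_ - (i - 1) * ext
        tbX[i, 0] = 0 if i == 1 else 1
    for j in range(1, nB + 1):
        Y[0, j] = -open_ - (j - 1) * ext
        tbY[0, j] = 0 if j == 1 else 2
    for i in range(1, nA + 1):
        for j in range(1, nB + 1):
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + S[i - 1, j - 1]
            tbM[i, j] = ptr
            best = M[i - 1, j] - open_
            ptr = 0
            if X[i - 1, j] - ext > best:
                best = X[i - 1, j] - ext
                ptr = 1
            if Y[i - 1, j] - open_ > best:
                best = Y[i - 1, j] - open_
                ptr = 2
            X[i, j] = best
            tbX[i, j] = ptr
            best = M[i, j - 1] - open_
            ptr = 0
            if X[i, j - 1] - open_ > best:
                best = X[i, j - 1] - open_
                ptr = 1
            if Y[i, j - 1] - ext > best:
                best = Y[i, j - 1] - ext
                ptr = 2
            Y[i, j] = best
            tbY[i, j] = ptr
    i, j = nA, nB
    if M[i, j] >= X[i, j] and M[i, j] >= Y[i, j]:
        state = 0
        score = M[i, j]
    elif X[i, j] >= Y[i, j]:
        state = 1
        score = X[i, j]
    else:
        state = 2
        score = Y[i, j]
    moves = np.empty(nA + nB, dtype=np.int64)
    k = 0
    while i > 0 or j > 0:
        moves[k] = state
        if state == 0:
            state = tbM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = tbX[i, j]
            i -= 1
        else:
            state = tbY[i, j]
            j -= 1
        k += 1
    return moves[:k], score


def _profile_counts(rows: List[str]) -> np.ndarray:
    """Per-column amino-acid frequency counts over the BLOSUM alphabet."""
    L = len(rows[0])
    counts = np.zeros((L, len(_ALPHABET)))
    for r in rows:
        for i, aa in enumerate(r):
            if aa != "-":
                counts[i, _AA_INDEX.get(aa, _AA_INDEX["X"])] += 1
    return counts


def _align_profiles(rows_a: List[str], rows_b: List[str]
                    ) -> Tuple[List[str], List[str], float]:
    cA = _profile_counts(rows_a)
    cB = _profile_counts(rows_b)
    S = (cA @ _BLOSUM_ARR @ cB.T) / (len(rows_a) * len(rows_b))
    moves, score = _gotoh(S, GAP_OPEN, GAP_EXTEND)
    outA = [[] for _ in rows_a]
    outB = [[] for _ in rows_b]
    i = j = 0
    for m in moves[::-1]:
        if m == 0:
            for r, o in zip(rows_a, outA):
                o.append(r[i])
            for r, o in zip(rows_b, outB):
                o.append(r[j])
            i += 1
            j += 1
        elif m == 1:
            for r, o in zip(rows_a, outA):
                o.append(r[i])
            for o in outB:
                o.append("-")
            i += 1
        else:
            for o in outA:
                o.append("-")
            for r, o in zip(rows_b, outB):
                o.append(r[j])
            j += 1
    return (["".join(o) for o in outA], ["".join(o) for o in outB], score)


def align_proteins(proteins: Dict[str, str],
                   guide: Phylogeny) -> Tuple[List[str], List[str]]:
    """Progressive protein alignment following the guide-tree topology."""
    taxa = list(proteins)
    missing = set(taxa) - set(guide.tip_labels)
    if missing:
        raise ValueError(f"taxa absent from guide tree: {sorted(missing)}")
    if len(taxa) == 1:
        return taxa, [proteins[taxa[0]]]
    sub = guide.restrict(taxa)

    def merge(node) -> Tuple[List[str], List[str]]:
        if node < sub.n_tips:
            name = sub.tip_labels[node]
            return [name], [proteins[name]]
        parts = [merge(c) for c in sub.children[node]]
        names, rows = parts[0]
        for more_names, more_rows in parts[1:]:
            a, b, _ = _align_profiles(rows, more_rows)
            rows = a + b
            names = names + more_names
        return names, rows

    return merge(sub.root)


def codon_align(cds_by_taxon: Dict[str, str],
                guide: Phylogeny) -> CodonAlignment:
    """Codon-aware multiple alignment of a group's CDSs.

    Sequences are translated (terminal stops stripped), aligned as proteins
    progressively along the guide topology, and the alignment is
    back-translated to codons, so removing gaps from any output row
    reproduces the (stop-stripped) input CDS exactly.
    """
    stripped = {t: strip_terminal_stop(s) for t, s in cds_by_taxon.items()}
    proteins = {t: translate_cds(s) for t, s in stripped.items()}
    if len(stripped) == 1:
        (t, s), = stripped.items()
        return CodonAlignment([t], [s])
    names, prot_rows = align_proteins(proteins, guide)
    rows = []
    for name, prot in zip(names, prot_rows):
        cds = stripped[name]
        out = []
        k = 0
        for aa in prot:
            if aa == "-":
                out.append(GAP_CODON)
            else:
                out.append(cds[3 * k: 3 * k + 3])
                k += 1
        rows.append("".join(out))
    return CodonAlignment(names, rows)


# ===================================================================== #
# Gblocks-style trimming
# ===================================================================== #

@dataclass
class TrimParams:
    """Conserved-block trimming parameters (Gblocks b1-b5 semantics).

    A column is *conserved* when its most frequent residue occurs in
    strictly more than ``min_conserved_fraction`` of rows, and *highly
    conserved* at ``flank_fraction`` or more; runs of more than
    ``max_nonconserved_run`` contiguous nonconserved columns are rejected,
    blocks are trimmed to highly conserved flanks, and blocks shorter than
    ``min_block_length`` are dropped.  Columns containing any gap are
    rejected unless ``allow_gap_columns``.
    """

    min_conserved_fraction: float = 0.5
    flank_fraction: float = 0.85
    max_nonconserved_run: int = 8
    min_block_length: int = 10
    allow_gap_columns: bool = False

    def __post_init__(self):
        for name in ("min_conserved_fraction", "flank_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.max_nonconserved_run < 1 or self.min_block_length < 1:
            raise ValueError("run/block lengths must be >= 1")


def _column_status(aln: CodonAlignment, params: TrimParams) -> List[str]:
    """Classify each amino-acid column: 'gap', 'non', 'cons' or 'high'."""
    prots = aln.protein_rows()
    n_rows = len(prots)
    status = []
    for i in range(aln.n_codons):
        col = [p[i] for p in prots]
        n_gap = col.count("-")
        if n_gap > 0 and not params.allow_gap_columns:
            status.append("gap")
            continue
        residues = [a for a in col if a != "-"]
        if not residues:
            status.append("gap")
            continue
        top = max(residues.count(a) for a in set(residues))
        if top > params.min_conserved_fraction * n_rows:
            if top >= params.flank_fraction * n_rows:
                status.append("high")
            else:
                status.append("cons")
        else:
            status.append("non")
    return status


def trim_blocks(aln: CodonAlignment, params: TrimParams | None = None
                ) -> Tuple[CodonAlignment, List[int]]:
    """Retain the conserved blocks of a codon alignment.

    Returns the trimmed alignment and the strictly increasing map from
    trimmed codon-column index to original codon-column index.
    """
    if len(aln.rows) < 2:
        raise ValueError("trimming needs at least 2 rows")
    params = params or TrimParams()
    status = _column_status(aln, params)
    n = len(status)
    rejected = [s == "gap" for s in status]
    # reject long runs of nonconserved columns (gap columns break/count
    # as nonconserved for run purposes)
    i = 0
    while i < n:
        if status[i] in ("non", "gap"):
            j = i
            while j < n and status[j] in ("non", "gap"):
                j += 1
            if j - i > params.max_nonconserved_run:
                for k in range(i, j):
                    rejected[k] = True
            i = j
        else:
            i += 1
    # candidate blocks between rejected columns, trimmed to 'high' flanks
    retained: List[int] = []
    i = 0
    while i < n:
        if rejected[i]:
            i += 1
            continue
        j = i
        while j < n and not rejected[j]:
            j += 1
        block = list(range(i, j))
        while block and status[block[0]] != "high":
            block.pop(0)
        while block and status[block[-1]] != "high":
            block.pop()
        if len(block) >= params.min_block_length:
            retained.extend(block)
        i = j
    return aln.codon_columns(retained), retained


def coverage_filter(trimmed: CodonAlignment, original: CodonAlignment,
                    threshold: float = 0.30) -> Tuple[bool, float]:
    """Keep a group iff the trimmed alignment covers >= ``threshold`` of the
    original codon columns (boundary kept)."""
    if original.n_codons == 0:
        return False, 0.0
    coverage = trimmed.n_codons / original.n_codons
    return coverage >= threshold, coverage
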