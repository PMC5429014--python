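"""Codon state space for the 61 sense codons of the universal genetic code.

The codon substitution model operates on the 61 non-stop codons; the three
stop codons (TAA, TAG, TGA) are excluded from the state space.  Module-level
tables are built once at import: codon <-> index maps, the single-nucleotide
adjacency structure (which codon pairs differ at exactly one position, and
whether that change is a transition and/or nonsynonymous), and the genetic
code used for translation.
"""

from __future__ import annotations

import itertools

import numpy as np

NUCLEOTIDES = "ACGT"
NUC_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}

#: universal genetic code, DNA alphabet; '*' = stop
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = ("TAA", "TAG", "TGA")

#: the 61 sense codons in lexicographic (ACGT) order
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
    if GENETIC_CODE["".join(c)] != "*"
)
N_CODONS = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid of each sense codon
CODON_AA = tuple(GENETIC_CODE[c] for c in SENSE_CODONS)

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _build_adjacency():
    """Enumerate ordered sense-codon pairs differing at exactly one position."""
    src, dst, is_ts, is_nonsyn, pos = [], [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            src.append(i)
            dst.append(j)
            pos.append(k)
            is_ts.append(frozenset((ci[k], cj[k])) in _TRANSITIONS)
            is_nonsyn.append(CODON_AA[i] != CODON_AA[j])
    return (
        np.asarray(src, dtype=np.int64),
        np.asarray(dst, dtype=np.int64),
        np.asarray(is_ts, dtype=bool),
        np.asarray(is_nonsyn, dtype=bool),
        np.asarray(pos, dtype=np.int64),
    )


# ordered pairs (i, j), i != j, differing at exactly one codon position
ADJ_SRC, ADJ_DST, ADJ_IS_TRANSITION, ADJ_IS_NONSYN, ADJ_POSITION = _build_adjacency()


def codon_to_index(codon: str) -> int:
    """Index of a sense codon, or -1 for gaps, stops and ambiguity codes."""
    return CODON_INDEX.get(codon.upper(), -1)


def encode_codon_rows(rows, length=None):
    """Encode aligned codon strings as an int matrix; -1 marks gap/ambiguous.

    ``rows`` is a sequence of equal-length in-frame nucleotide strings.
    """
    n_col = (length if length is not None else len(rows[0])) // 3
    out = np.full((len(rows), n_col), -1, dtype=np.int64)
    for r, seq in enumerate(rows):
        for c in range(n_col):
            out[r, c] = codon_to_index(seq[3 * c: 3 * c + 3])
    return out


def f3x4_frequencies(rows, floor: float = 1e-10) -> np.ndarray:
    """Empirical F3x4 codon frequencies from aligned (or unaligned) CDS rows.

    Nucleotide frequencies are tallied separately at the three codon
    positions; each sense codon's frequency is the product of its three
    position-specific nucleotide frequencies, with stop codons removed and
    the result renormalized.  Frequencies are floored at ``floor`` so the
    rate matrix stays diagonalizable through its reversible symmetrization.
    """
    counts = np.zeros((3, 4))
    for seq in rows:
        s = seq.upper()
        for c in range(len(s) // 3):
            for k in range(3):
                b = s[3 * c + k]
                if b in NUC_INDEX:
                    counts[k, NUC_INDEX[b]] += 1
    if counts.sum() == 0:
        raise ValueError("no unambiguous nucleotides to estimate F3x4 from")
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.empty(N_CODONS)
    for i, codon in enumerate(SENSE_CODONS):
        pi[i] = (
            pos_freq[0, NUC_INDEX[codon[0]]]
            * pos_freq[1, NUC_INDEX[codon[1]]]
            * pos_freq[2, NUC_INDEX[codon[2]]]
        )
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def nucleotide_frequencies(rows) -> np.ndarray:
    """Empirical A,C,G,T frequencies over all rows (gaps/ambiguity ignored)."""
    counts = np.zeros(4)
    for seq in rows:
        for b in seq.upper():
            if b in NUC_INDEX:
                counts[NUC_INDEX[b]] += 1
    if counts.sum() == 0:
        raise ValueError("no unambiguous nucleotides in input")
    # floor guards degenerate fixtures where a base never occurs
    counts = np.maximum(counts, 1e-6)
    return counts / counts.sum()
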