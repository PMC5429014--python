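"""Pan-grass syntenic ortholog groups.

Builds the unit of testing for the scan: parse a synteny table, unify rows
that represent the two maize whole-genome-duplication homeologs of one
ancestral locus, attach the closest Dichanthelium homolog to the Setaria
ortholog by local alignment, and classify each group into one of the four
tested patterns of gene relationship:

    i    one ortholog in all six species
    ii   two maize homeologs, one ortholog in the other five species
    iii  rice ortholog missing, one in the other five
    iv   Brachypodium ortholog missing, one in the other five

Everything else is excluded (C4 branches cannot be unambiguously assigned).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd
from Bio import Align

SPECIES_CODES = ("Zm", "Sb", "Si", "Do", "Os", "Bd")
PATTERNS = ("i", "ii", "iii", "iv", "excluded")

#: local-alignment scoring standing in for BLASTN: match +2, mismatch -3,
#: gap open -5, gap extend -2 (a gap of length L costs 5 + 2L)
ALIGNER_SCORES = {"match": 2.0, "mismatch": -3.0,
                  "open": -7.0, "extend": -2.0}
DEFAULT_MIN_SCORE = 50.0


@dataclass
class GeneRecord:
    """One gene: species code, identifier and its CDS sequence."""

    species: str
    gene_id: str
    cds: str

    def __post_init__(self):
        if self.species not in SPECIES_CODES:
            raise ValueError(f"unknown species code {self.species!r}")
        if not self.cds:
            raise ValueError(f"empty CDS for {self.gene_id}")


@dataclass
class OrthologGroup:
    """A syntenic ortholog group: per-species gene lists and its pattern."""

    group_id: str
    members: Dict[str, List[str]] = field(default_factory=dict)
    pattern: str = "excluded"
    note: str = ""

    def member_count(self, species: str) -> int:
        return len(self.members.get(species, []))

    def all_genes(self) -> List[Tuple[str, str]]:
        return [(sp, g) for sp in SPECIES_CODES
                for g in self.members.get(sp, [])]

    def validate(self):
        if self.member_count("Zm") > 2:
            raise ValueError(f"{self.group_id}: more than two maize members")
        for sp in SPECIES_CODES:
            if sp != "Zm" and self.member_count(sp) > 1:
                raise ValueError(
                    f"{self.group_id}: multiple members for {sp}")


def read_synteny_table(path) -> pd.DataFrame:
    """Read the synteny TSV (columns group_id, species, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"group_id", "species", "gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"synteny table must have columns {sorted(required)}; "
            f"found {list(df.columns)}")
    bad = set(df["species"]) - set(SPECIES_CODES)
    if bad:
        raise ValueError(f"unknown species codes in synteny table: {sorted(bad)}")
    return df


def merge_homeologs(rows: pd.DataFrame) -> List[OrthologGroup]:
    """Unify synteny rows that differ only in their maize member.

    Rows are first gathered by ``group_id``; row sets sharing identical
    non-maize membership (the anchors) are then merged into a single group
    holding both maize homeologs, ordered lexicographically.  Three or more
    maize genes for one anchor set mark the group excluded.  The operation
    is idempotent.
    """
    raw: Dict[str, OrthologGroup] = {}
    for _, r in rows.iterrows():
        g = raw.setdefault(r["group_id"], OrthologGroup(r["group_id"]))
        g.members.setdefault(r["species"], [])
        if r["gene_id"] not in g.members[r["species"]]:
            g.members[r["species"]].append(r["gene_id"])

    by_anchor: Dict[frozenset, List[OrthologGroup]] = {}
    singletons: List[OrthologGroup] = []
    for gid in sorted(raw):
        g = raw[gid]
        anchors = frozenset(
            (sp, gene) for sp in SPECIES_CODES if sp != "Zm"
            for gene in g.members.get(sp, []))
        if anchors:
            by_anchor.setdefault(anchors, []).append(g)
        else:
            singletons.append(g)

    merged: List[OrthologGroup] = []
    for anchors in sorted(by_anchor, key=lambda a: sorted(a)):
        parts = by_anchor[anchors]
        gid = min(p.group_id for p in parts)
        maize = sorted({g for p in parts for g in p.members.get("Zm", [])})
        out = OrthologGroup(gid)
        for sp, gene in sorted(anchors):
            out.members.setdefault(sp, []).append(gene)
        for sp in out.members:
            out.members[sp].sort()
        if maize:
            out.members["Zm"] = maize
        if len(maize) > 2:
            out.pattern = "excluded"
            out.note = f"{len(maize)} maize members for one anchor set"
        merged.append(out)
    merged.extend(singletons)
    merged.sort(key=lambda g: g.group_id)
    return merged


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = ALIGNER_SCORES["match"]
    aligner.mismatch_score = ALIGNER_SCORES["mismatch"]
    aligner.open_gap_score = ALIGNER_SCORES["open"]
    aligner.extend_gap_score = ALIGNER_SCORES["extend"]
    return aligner


def best_hit_homolog(query: str, candidates: Dict[str, str],
                     min_score: float = DEFAULT_MIN_SCORE
                     ) -> Optional[Tuple[str, float]]:
    """Best local-alignment hit of ``query`` among ``candidates``.

    Returns ``(gene_id, score)`` or None when the candidate set is empty or
    no candidate reaches ``min_score`` (the missing-ortholog outcome).  Ties
    are broken toward the lexicographically smallest gene id.
    """
    if not candidates:
        return None
    aligner = _local_aligner()
    best_id, best_score = None, -float("inf")
    for gene_id in sorted(candidates):
        score = aligner.score(query.upper(), candidates[gene_id].upper())
        if score > best_score:
            best_id, best_score = gene_id, score
    if best_score < min_score:
        return None
    return best_id, float(best_score)


class HomologIndex:
    """Seeded best-hit search against a fixed CDS pool.

    Candidates are shortlisted by shared 12-mer counts (an inverted index,
    the same seeding idea BLASTN uses) and only the shortlist is scored with
    the exact local aligner.  With ``top=None`` every candidate is scored,
    reproducing :func:`best_hit_homolog` exactly.
    """

    def __init__(self, pool: Dict[str, str], k: int = 12):
        self.pool = pool
        self.k = k
        self._index: Dict[str, set] = {}
        for gene_id, seq in pool.items():
            s = seq.upper()
            for i in range(len(s) - k + 1):
                self._index.setdefault(s[i:i + k], set()).add(gene_id)

    def shortlist(self, query: str, top: int = 3) -> Dict[str, str]:
        from collections import Counter

        counts: Counter = Counter()
        q = query.upper()
        seen = set()
        for i in range(len(q) - self.k + 1):
            kmer = q[i:i + self.k]
            if kmer in seen:
                continue
            seen.add(kmer)
            for gene_id in self._index.get(kmer, ()):
                counts[gene_id] += 1
        if not counts:
            return dict(self.pool)  # no seed hits: fall back to full scan
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        cutoff = ranked[min(top, len(ranked)) - 1][1]
        keep = [g for g, c in ranked if c >= cutoff]
        return {g: self.pool[g] for g in keep}

    def best(self, query: str, min_score: float = DEFAULT_MIN_SCORE,
             top: Optional[int] = 3) -> Optional[Tuple[str, float]]:
        cands = self.pool if top is None else self.shortlist(query, top)
        return best_hit_homolog(query, cands, min_score=min_score)


def classify_pattern(group: OrthologGroup) -> str:
    """The group's pattern of gene relationship (pure count logic)."""
    if group.pattern == "excluded" and group.note:
        return "excluded"  # structurally excluded upstream
    n = {sp: group.member_count(sp) for sp in SPECIES_CODES}
    others = ("Sb", "Si", "Do", "Os", "Bd")
    if n["Zm"] == 1 and all(n[sp] == 1 for sp in others):
        return "i"
    if n["Zm"] == 2 and all(n[sp] == 1 for sp in others):
        return "ii"
    if (n["Os"] == 0 and n["Zm"] == 1
            and all(n[sp] == 1 for sp in ("Sb", "Si", "Do", "Bd"))):
        return "iii"
    if (n["Bd"] == 0 and n["Zm"] == 1
            and all(n[sp] == 1 for sp in ("Sb", "Si", "Do", "Os"))):
        return "iv"
    return "excluded"


def build_ortholog_groups(synteny: pd.DataFrame,
                          cds_by_species: Dict[str, Dict[str, str]],
                          min_score: float = DEFAULT_MIN_SCORE
                          ) -> List[OrthologGroup]:
    """Full grouping stage: merge homeologs, attach Dichanthelium, classify.

    ``cds_by_species`` maps species code to ``{gene_id: CDS}``; the
    Dichanthelium entry is the candidate pool searched for each group's
    closest homolog of the Setaria ortholog.
    """
    groups = merge_homeologs(synteny)
    do_pool = cds_by_species.get("Do", {})
    index = HomologIndex(do_pool) if do_pool else None
    for g in groups:
        for sp, gene in g.all_genes():
            if gene not in cds_by_species.get(sp, {}):
                raise KeyError(f"CDS missing for {sp} gene {gene} "
                               f"(group {g.group_id})")
        if g.member_count("Si") == 1 and index is not None:
            si_gene = g.members["Si"][0]
            hit = index.best(cds_by_species["Si"][si_gene],
                             min_score=min_score)
            if hit is not None:
                g.members["Do"] = [hit[0]]
        g.pattern = classify_pattern(g)
        if g.pattern != "excluded":
            g.validate()
    return groups
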