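"""Forward simulation of codon sequences and full synthetic cohorts.

The simulator is the test bed for the whole scan: it evolves in-frame codon
sequences along the six-taxon grass tree (((Zm,Sb),(Si,Do)),(Os,Bd)) under
the same GY94 branch model the scan fits, with a configurable fraction of
groups carrying an elevated foreground omega, maize whole-genome-duplication
homeolog pairs, rice/Brachypodium gene losses, and a fraction of groups with
a discordant gene history (Sb and Si exchanged).  Selected/lost/duplicated/
discordant groups are allocated by exact counts (not Bernoulli draws) to
group indices derived deterministically from the seed, so ground-truth
tables are reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from ._codons import SENSE_CODONS
from .models import CodonModelParams, SpectralQ, codon_rate_matrix
from .phylo import BACKGROUND, FOREGROUND, Phylogeny
from .scan import label_foreground

SPECIES = ("Zm", "Sb", "Si", "Do", "Os", "Bd")

#: the six-taxon grass species topology
SPECIES_TOPOLOGY = (((("Zm", "Sb"), ("Si", "Do")), ("Os", "Bd")))
#: discordant alternative: Sb and Si exchanged
DISCORDANT_TOPOLOGY = (((("Zm", "Si"), ("Sb", "Do")), ("Os", "Bd")))


def grass_species_tree(tip_length: float = 0.1,
                       internal_length: float = 0.15,
                       topology=SPECIES_TOPOLOGY) -> Phylogeny:
    """The study's species tree with default desk-scale branch lengths
    (codon substitutions per codon site)."""
    return Phylogeny.from_nested(topology, tip_length=tip_length,
                                 internal_length=internal_length)


def simulate_codon_alignment(tree: Phylogeny, params: CodonModelParams,
                             n_codons: int, seed) -> Dict[str, str]:
    """Evolve gap-free in-frame codon sequences down ``tree``.

    The root sequence is drawn from the stationary frequencies; each branch
    applies the transition matrix of its branch class's omega.  Returns a
    dict tip name -> nucleotide sequence.  ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    spectral = {
        cls: SpectralQ(codon_rate_matrix(params, w), params.pi)
        for cls, w in params.omega_by_class.items()
    }
    if BACKGROUND not in spectral:
        raise ValueError("omega_by_class must define the background class")
    states = {tree.root: rng.choice(len(params.pi), size=n_codons,
                                    p=params.pi)}
    for node in tree.preorder():
        if node == tree.root:
            continue
        cls = int(tree.classes[node])
        sp = spectral.get(cls, spectral[BACKGROUND])
        P = sp.transition_matrix(tree.lengths[node])
        # guard tiny negative round-off before row-wise sampling
        P = P / P.sum(axis=1, keepdims=True)
        parent_states = states[tree.parent[node]]
        u = rng.random(n_codons)
        cum = np.cumsum(P, axis=1)
        child = np.empty(n_codons, dtype=np.int64)
        for i in range(n_codons):
            child[i] = np.searchsorted(cum[parent_states[i]], u[i])
        states[node] = child
    out = {}
    for i, name in enumerate(tree.tip_labels):
        out[name] = "".join(SENSE_CODONS[s] for s in states[i])
    return out


# ===================================================================== #
@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the desk-scale conditions used throughout the test suite:
    300 codons per gene, background omega 0.2, foreground omega 4.0 for the
    selected fraction, kappa 2, species-tree branch lengths 0.1 (terminal)
    and 0.15 (internal) expected codon substitutions per site.
    """

    n_groups: int = 200
    fraction_selected: float = 0.1
    omega_bg: float = 0.2
    omega_fg: float = 4.0
    n_codons: int = 300
    maize_duplication_prob: float = 0.1
    rice_loss_prob: float = 0.05
    brachypodium_loss_prob: float = 0.05
    discordant_fraction: float = 0.05
    kappa: float = 2.0
    tip_length: float = 0.1
    internal_length: float = 0.15
    homeolog_length: float = 0.02
    foreground_rule: str = "stem_only"
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_selected", "maize_duplication_prob",
                     "rice_loss_prob", "brachypodium_loss_prob",
                     "discordant_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if (self.maize_duplication_prob + self.rice_loss_prob
                + self.brachypodium_loss_prob) > 1.0 + 1e-12:
            raise ValueError("duplication and loss fractions exceed 1 "
                             "for the per-group pattern slot")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class CohortResult:
    """Generated cohort: sequences, synteny rows and ground truth."""

    sequences: Dict[str, Dict[str, str]]  # species -> gene id -> CDS
    synteny: pd.DataFrame                 # group_id, species, gene_id
    truth: pd.DataFrame
    config: CohortConfig


def _allocate(rng: np.random.Generator, n: int, counts: Dict[str, int]):
    """Deterministically assign labels to exact counts of group indices."""
    perm = rng.permutation(n)
    out = {}
    at = 0
    for name, k in counts.items():
        out[name] = np.sort(perm[at:at + k])
        at += k
    return out


def generate_cohort(config: CohortConfig,
                    out_dir: Optional[Path] = None) -> CohortResult:
    """Generate a full synthetic cohort with ground truth.

    Exactly ``round(n_groups * fraction_selected)`` groups are selected
    (elevated foreground omega); duplication/loss patterns and discordance
    are likewise allocated by exact counts.  If ``out_dir`` is given, the
    per-species FASTAs, the synteny TSV, the truth TSV and a YAML echo of
    the configuration are written there.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_groups
    n_sel = round(n * cfg.fraction_selected)
    n_dup = round(n * cfg.maize_duplication_prob)
    n_rice = round(n * cfg.rice_loss_prob)
    n_bd = round(n * cfg.brachypodium_loss_prob)
    n_disc = round(n * cfg.discordant_fraction)

    pattern_alloc = _allocate(rng, n, {"ii": n_dup, "iii": n_rice,
                                       "iv": n_bd})
    sel_idx = set(_allocate(rng, n, {"sel": n_sel})["sel"].tolist())
    disc_idx = set(_allocate(rng, n, {"disc": n_disc})["disc"].tolist())
    pattern = np.array(["i"] * n, dtype=object)
    for name in ("ii", "iii", "iv"):
        pattern[pattern_alloc[name]] = name

    # mildly non-uniform stationary codon frequencies shared by the cohort
    pi = np.asarray(rng.dirichlet(np.full(61, 50.0)))

    sequences: Dict[str, Dict[str, str]] = {sp: {} for sp in SPECIES}
    synteny_rows = []
    truth_rows = []
    width = max(4, len(str(n)))
    for g in range(n):
        gid = f"g{g:0{width}d}"
        selected = g in sel_idx
        discordant = g in disc_idx
        pat = str(pattern[g])
        topology = DISCORDANT_TOPOLOGY if discordant else SPECIES_TOPOLOGY
        tree = grass_species_tree(cfg.tip_length, cfg.internal_length,
                                  topology)
        if pat == "iii":
            tree = tree.restrict(set(SPECIES) - {"Os"})
        elif pat == "iv":
            tree = tree.restrict(set(SPECIES) - {"Bd"})
        elif pat == "ii":
            tree = tree.with_tip_expanded(
                "Zm", ("Zm_h1", "Zm_h2"), cherry_length=cfg.homeolog_length)
        tree = label_foreground(tree, cfg.foreground_rule)
        omega_fg = cfg.omega_fg if selected else cfg.omega_bg
        params = CodonModelParams(
            kappa=cfg.kappa,
            omega_by_class={BACKGROUND: cfg.omega_bg, FOREGROUND: omega_fg},
            pi=pi)
        group_seed = rng.integers(0, 2**31 - 1)
        seqs = simulate_codon_alignment(tree, params, cfg.n_codons,
                                        int(group_seed))
        gene_ids = {}
        for tip, seq in seqs.items():
            sp = tip.split("_")[0]
            suffix = "" if "_" not in tip else tip.split("_", 1)[1]
            gene = f"{sp}_{gid}{('_' + suffix) if suffix else ''}"
            sequences[sp][gene] = seq
            gene_ids[tip] = gene
        # synteny table covers the five core species; Dichanthelium is
        # attached later by best-hit search against the Do sequence pool.
        # maize homeolog pairs are emitted as two rows sharing the anchors.
        if pat == "ii":
            for h, hom in enumerate(("Zm_h1", "Zm_h2")):
                sub_gid = f"{gid}.{h + 1}"
                synteny_rows.append((sub_gid, "Zm", gene_ids[hom]))
                for sp in ("Sb", "Si", "Os", "Bd"):
                    if sp in seqs:
                        synteny_rows.append((sub_gid, sp, gene_ids[sp]))
        else:
            for sp in ("Zm", "Sb", "Si", "Os", "Bd"):
                if sp in seqs:
                    synteny_rows.append((gid, sp, gene_ids[sp]))
        truth_rows.append({
            "group_id": gid, "pattern": pat,
            "selected": selected, "discordant": discordant,
            "omega_fg": omega_fg, "omega_bg": cfg.omega_bg,
            "kappa": cfg.kappa, "n_codons": cfg.n_codons,
            "seed": int(group_seed),
        })

    synteny = pd.DataFrame(synteny_rows,
                           columns=["group_id", "species", "gene_id"])
    truth = pd.DataFrame(truth_rows)
    result = CohortResult(sequences=sequences, synteny=synteny, truth=truth,
                          config=cfg)
    if out_dir is not None:
        write_cohort(result, Path(out_dir))
    return result


def write_cohort(cohort: CohortResult, out_dir: Path):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sp, genes in cohort.sequences.items():
        with open(out_dir / f"{sp}.cds.fasta", "w") as fh:
            for gene in sorted(genes):
                fh.write(f">{gene}\n")
                seq = genes[gene]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
    cohort.synteny.to_csv(out_dir / "synteny.tsv", sep="\t", index=False)
    cohort.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump({k: (v if not isinstance(v, np.generic) else v.item())
                        for k, v in vars(cohort.config).items()}, fh)


def power_experiment(omega_fg_grid=(0.2, 1.5, 4.0),
                     n_codons_grid=(300,),
                     conditions=(1,),
                     replicates: int = 50,
                     omega_bg: float = 0.2,
                     kappa: float = 2.0,
                     seed: int = 0) -> pd.DataFrame:
    """Type-I error and power of the branch LRT over a condition grid.

    For every (omega_fg, n_codons) cell, ``replicates`` six-taxon
    alignments are simulated under the foreground-labeled species tree and
    the branch LRT is run for each requested condition on the pruned
    alignment.  Cells with ``omega_fg == omega_bg`` measure the type-I
    error.  Rejection fractions are reported at p < 0.05 and at q < 0.2
    (BH within each cell x condition).
    """
    from .align import CodonAlignment
    from .fit import lrt_branch_model
    from .scan import enumerate_conditions
    from .significance import bh_fdr

    rng = np.random.default_rng(seed)
    sp_tree = grass_species_tree()
    sim_tree = label_foreground(sp_tree)
    pi = np.asarray(rng.dirichlet(np.full(61, 50.0)))
    rows = []
    for omega_fg in omega_fg_grid:
        for n_codons in n_codons_grid:
            params = CodonModelParams(
                kappa=kappa,
                omega_by_class={BACKGROUND: omega_bg,
                                FOREGROUND: omega_fg}, pi=pi)
            plans = {c.id: tree for c, tree, _, status in
                     enumerate_conditions(list(sim_tree.tip_labels),
                                          sp_tree, conditions=conditions)
                     if status == "tested"}
            pvals = {cid: [] for cid in plans}
            for _ in range(replicates):
                rep_seed = int(rng.integers(0, 2**31 - 1))
                seqs = simulate_codon_alignment(sim_tree, params,
                                                n_codons, rep_seed)
                aln = CodonAlignment(list(seqs), list(seqs.values()))
                for cid, tree in plans.items():
                    sub = aln.subset(tree.tip_labels)
                    res = lrt_branch_model(sub.taxa, sub.rows, tree)
                    pvals[cid].append(res.p)
            for cid in sorted(pvals):
                p = np.asarray(pvals[cid])
                q = bh_fdr(p)
                rows.append({
                    "omega_fg": omega_fg, "omega_bg": omega_bg,
                    "n_codons": n_codons, "condition": cid,
                    "replicates": replicates,
                    "reject_p05": float((p < 0.05).mean()),
                    "reject_q02": float((q < 0.2).mean()),
                })
    return pd.DataFrame(rows)


def cohort_digest(cohort: CohortResult) -> str:
    """Stable digest of all sequences (reproducibility checks)."""
    h = hashlib.sha256()
    for sp in sorted(cohort.sequences):
        for gene in sorted(cohort.sequences[sp]):
            h.update(gene.encode())
            h.update(cohort.sequences[sp][gene].encode())
    return h.hexdigest()
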