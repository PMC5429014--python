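"""End-to-end scan workflow as independently re-runnable stages.

Stage order: group -> align -> congruence -> scan -> fdr -> report.  Each
stage reads the previous stage's artifacts from the run directory and
writes its own (TSV with headers, FASTA, JSON), so any stage can be re-run
in isolation; :func:`run_pipeline` simply executes them in order.  The
pipeline is a pure function of (inputs, configuration): iteration is in
sorted group order, every exclusion is recorded in the QC report, and
stage counts always conserve (groups in = kept + excluded at every
filter).  Sequence/column indices in output files are 1-based inclusive,
as stated in their column names.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .align import (CodonAlignment, InternalStopError, TrimParams,
                    codon_align, coverage_filter, trim_blocks)
from .congruence import GeneTreeSearch, congruence_test
from .grouping import OrthologGroup, build_ortholog_groups, read_synteny_table
from .phylo import Phylogeny
from .scan import base_tree_for_taxa, run_scan, species_of
from .significance import add_qvalues, enrichment_fisher, merge_candidates
from .simulate import grass_species_tree

logger = logging.getLogger("c4scan")

SPECIES = ("Zm", "Sb", "Si", "Do", "Os", "Bd")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    fasta_dir: str = "."
    synteny_table: str = "synteny.tsv"
    species_tree: Optional[str] = None  # newick path; None = built-in tree
    out_dir: str = "run"
    trim: TrimParams = field(default_factory=TrimParams)
    coverage_threshold: float = 0.30
    fdr_threshold: float = 0.2
    fdr_method: str = "bh"
    foreground_rule: str = "stem_only"
    homeolog_mode: str = "joint"
    conditions: Sequence[int] = tuple(range(1, 10))
    min_taxa: int = 4
    min_hit_score: float = 50.0
    known_genes: Sequence[str] = ()
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.coverage_threshold < 1):
            raise ValueError("coverage_threshold must lie in (0, 1)")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.homeolog_mode not in ("joint", "separate"):
            raise ValueError("homeolog_mode must be 'joint' or 'separate'")
        if isinstance(self.trim, dict):
            self.trim = TrimParams(**self.trim)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path):
        data = asdict(self)
        data["conditions"] = list(self.conditions)
        data["known_genes"] = list(self.known_genes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @property
    def run_dir(self) -> Path:
        return Path(self.out_dir)


@dataclass
class PipelineResult:
    """Bundle returned by :func:`run_pipeline`."""

    scan: pd.DataFrame
    candidates: pd.DataFrame
    qc: pd.DataFrame
    counts: Dict[str, int]
    enrichment: Optional[Dict[str, float]]
    out_dir: Optional[Path]


# ------------------------------------------------------------------ #
# input readers
# ------------------------------------------------------------------ #

def read_cds_fastas(fasta_dir, species=SPECIES) -> Dict[str, Dict[str, str]]:
    """Per-species ``{gene_id: CDS}`` from ``<dir>/<Sp>.cds.fasta`` files."""
    fasta_dir = Path(fasta_dir)
    out: Dict[str, Dict[str, str]] = {}
    for sp in species:
        path = fasta_dir / f"{sp}.cds.fasta"
        if not path.exists():
            raise FileNotFoundError(f"missing CDS FASTA: {path}")
        out[sp] = {rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(str(path), "fasta")}
    return out


def group_taxa_and_cds(group: OrthologGroup,
                       cds: Dict[str, Dict[str, str]]) -> Dict[str, str]:
    """Taxon-name -> CDS map for one group (homeologs as Zm_h1/Zm_h2)."""
    out = {}
    for sp in SPECIES:
        genes = group.members.get(sp, [])
        if sp == "Zm" and len(genes) == 2:
            for i, g in enumerate(sorted(genes)):
                out[f"Zm_h{i + 1}"] = cds[sp][g]
        elif genes:
            out[sp] = cds[sp][genes[0]]
    return out


def load_species_tree(config: PipelineConfig) -> Phylogeny:
    if config.species_tree:
        return Phylogeny.from_newick(Path(config.species_tree).read_text(),
                                     default_length=0.1)
    return grass_species_tree()


def _write_fasta(path: Path, taxa, rows):
    with open(path, "w") as fh:
        for t, r in zip(taxa, rows):
            fh.write(f">{t}\n")
            for i in range(0, len(r), 60):
                fh.write(r[i:i + 60] + "\n")


def _read_alignment(path: Path) -> CodonAlignment:
    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    return CodonAlignment(taxa, rows)


# ------------------------------------------------------------------ #
# stages
# ------------------------------------------------------------------ #

def stage_group(config: PipelineConfig) -> pd.DataFrame:
    """Grouping stage: merge homeologs, attach Dichanthelium, classify.

    Writes ``groups.tsv`` (one row per member, with the group's pattern).
    """
    synteny = read_synteny_table(config.synteny_table)
    cds = read_cds_fastas(config.fasta_dir)
    groups = build_ortholog_groups(synteny, cds,
                                   min_score=config.min_hit_score)
    rows = []
    for g in groups:
        for sp, gene in g.all_genes():
            rows.append({"group_id": g.group_id, "species": sp,
                         "gene_id": gene, "pattern": g.pattern,
                         "note": g.note})
    table = pd.DataFrame(rows, columns=["group_id", "species", "gene_id",
                                        "pattern", "note"])
    out = config.run_dir
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "groups.tsv", sep="\t", index=False)
    logger.info("grouping: %d groups, %d pass patterns i-iv",
                len(groups),
                sum(g.pattern != "excluded" for g in groups))
    return table


def stage_align(config: PipelineConfig) -> pd.DataFrame:
    """Alignment stage: codon-aware align, trim, coverage-filter.

    Writes per-group ``alignments/<id>.aln.fasta`` (trimmed codon
    alignment) and ``alignments/<id>.colmap.tsv`` (1-based trimmed ->
    original codon-column map), plus ``align_qc.tsv``.
    """
    out = config.run_dir
    groups_table = pd.read_csv(out / "groups.tsv", sep="\t",
                               keep_default_na=False)
    cds = read_cds_fastas(config.fasta_dir)
    species_tree = load_species_tree(config)
    aln_dir = out / "alignments"
    aln_dir.mkdir(parents=True, exist_ok=True)
    qc_rows = []
    for gid, sub in groups_table.groupby("group_id", sort=True):
        pattern = sub["pattern"].iloc[0]
        if pattern == "excluded":
            qc_rows.append({"group_id": gid, "outcome": "excluded_pattern",
                            "coverage": "", "detail": sub["note"].iloc[0]})
            continue
        group = OrthologGroup(gid)
        for r in sub.itertuples():
            group.members.setdefault(r.species, []).append(r.gene_id)
        try:
            taxa_cds = group_taxa_and_cds(group, cds)
            guide = base_tree_for_taxa(taxa_cds, species_tree)
            aln = codon_align(taxa_cds, guide)
            trimmed, colmap = trim_blocks(aln, config.trim)
            keep, coverage = coverage_filter(trimmed, aln,
                                             config.coverage_threshold)
        except InternalStopError as exc:
            qc_rows.append({"group_id": gid, "outcome": "excluded_stop",
                            "coverage": "", "detail": str(exc)})
            continue
        if not keep:
            qc_rows.append({"group_id": gid, "outcome": "excluded_coverage",
                            "coverage": f"{coverage:.4f}", "detail": ""})
            continue
        _write_fasta(aln_dir / f"{gid}.aln.fasta", trimmed.taxa,
                     trimmed.rows)
        pd.DataFrame({
            "aln_codon_1based": [i + 1 for i in range(len(colmap))],
            "orig_codon_1based": [c + 1 for c in colmap],
        }).to_csv(aln_dir / f"{gid}.colmap.tsv", sep="\t", index=False)
        qc_rows.append({"group_id": gid, "outcome": "pass",
                        "coverage": f"{coverage:.4f}", "detail": ""})
    qc = pd.DataFrame(qc_rows, columns=["group_id", "outcome", "coverage",
                                        "detail"])
    qc.to_csv(out / "align_qc.tsv", sep="\t", index=False)
    logger.info("alignment: %d pass of %d",
                int((qc.outcome == "pass").sum()), len(qc))
    return qc


def _aligned_groups(config: PipelineConfig) -> Dict[str, CodonAlignment]:
    out = config.run_dir
    qc = pd.read_csv(out / "align_qc.tsv", sep="\t",
                     keep_default_na=False)
    alignments = {}
    for gid in sorted(qc.loc[qc.outcome == "pass", "group_id"]):
        alignments[gid] = _read_alignment(
            out / "alignments" / f"{gid}.aln.fasta")
    return alignments


def stage_congruence(config: PipelineConfig,
                     search: Optional[GeneTreeSearch] = None
                     ) -> pd.DataFrame:
    """Congruence stage: two gene trees per group, quartet distances.

    Writes ``congruence.tsv`` with the per-group verdicts.
    """
    out = config.run_dir
    species_tree = load_species_tree(config)
    rows = []
    for gid, aln in _aligned_groups(config).items():
        homeologs = sorted(t for t in aln.taxa
                           if species_of(t) == "Zm" and t != "Zm")
        ref = species_tree.restrict({species_of(t) for t in aln.taxa})
        verdict = congruence_test(aln, ref,
                                  homeologs=homeologs or None,
                                  search=search)
        rows.append({
            "group_id": gid,
            "qdist_all": (-1 if verdict.qdist_all is None
                          else verdict.qdist_all),
            "qdist_third": (-1 if verdict.qdist_third is None
                            else verdict.qdist_third),
            "pass": int(verdict.passed),
            "tree_all_sites": (verdict.tree_all_sites.newick(digits=6)
                               if verdict.tree_all_sites else ""),
            "tree_third_positions": (
                verdict.tree_third_positions.newick(digits=6)
                if verdict.tree_third_positions else ""),
            "note": verdict.note,
        })
    table = pd.DataFrame(rows, columns=[
        "group_id", "qdist_all", "qdist_third", "pass",
        "tree_all_sites", "tree_third_positions", "note"])
    table.to_csv(out / "congruence.tsv", sep="\t", index=False)
    logger.info("congruence: %d pass of %d",
                int(table["pass"].sum()) if len(table) else 0, len(table))
    return table


def _scan_units(congruent: Dict[str, CodonAlignment],
                homeolog_mode: str) -> Dict[str, CodonAlignment]:
    """Testing units for the scan; 'separate' mode splits homeolog pairs
    into two single-maize units (suffixes .h1/.h2)."""
    if homeolog_mode == "joint":
        return dict(congruent)
    units = {}
    for gid, aln in congruent.items():
        homeologs = sorted(t for t in aln.taxa
                           if species_of(t) == "Zm" and t != "Zm")
        if not homeologs:
            units[gid] = aln
            continue
        for hom in homeologs:
            keep = [t for t in aln.taxa if species_of(t) != "Zm"
                    or t == hom]
            sub = aln.subset(keep)
            sub = CodonAlignment(
                ["Zm" if t == hom else t for t in sub.taxa], sub.rows)
            units[f"{gid}.{hom.split('_')[-1]}"] = sub
    return units


def stage_scan(config: PipelineConfig) -> pd.DataFrame:
    """Selection-scan stage: branch-model LRTs for congruent groups.

    Writes ``scan.tsv`` (one row per group x condition).
    """
    out = config.run_dir
    congruence = pd.read_csv(out / "congruence.tsv", sep="\t",
                             keep_default_na=False)
    passing = set(congruence.loc[congruence["pass"] == 1,
                                 "group_id"])
    alignments = {gid: aln for gid, aln in _aligned_groups(config).items()
                  if gid in passing}
    units = _scan_units(alignments, config.homeolog_mode)
    species_tree = load_species_tree(config)
    scan = run_scan(units, species_tree,
                    conditions=list(config.conditions),
                    foreground_rule=config.foreground_rule,
                    min_taxa=config.min_taxa)
    scan.to_csv(out / "scan.tsv", sep="\t", index=False,
                float_format="%.6g")
    logger.info("scan: %d records for %d units",
                len(scan), len(units))
    return scan


def stage_fdr(config: PipelineConfig) -> pd.DataFrame:
    """FDR stage: per-condition q-values and the merged candidate list.

    Rewrites ``scan.tsv`` with a ``q`` column and writes
    ``candidates.tsv``.
    """
    out = config.run_dir
    scan = pd.read_csv(out / "scan.tsv", sep="\t",
                       keep_default_na=False,
                       na_values=[""])
    scan_q = add_qvalues(scan, method=config.fdr_method)
    candidates = merge_candidates(scan_q, threshold=config.fdr_threshold)
    scan_q.to_csv(out / "scan.tsv", sep="\t", index=False,
                  float_format="%.6g")
    candidates.table.to_csv(out / "candidates.tsv", sep="\t", index=False,
                            float_format="%.6g")
    logger.info("fdr: %d candidate groups", len(candidates.table))
    return scan_q


def stage_report(config: PipelineConfig) -> Dict:
    """Report stage: stage counters, QC report, optional enrichment test.

    Writes ``counts.json``, ``qc_report.tsv``, optionally
    ``enrichment.json``, the config echo and a manifest.
    """
    out = config.run_dir
    groups_table = pd.read_csv(out / "groups.tsv", sep="\t",
                               keep_default_na=False)
    align_qc = pd.read_csv(out / "align_qc.tsv", sep="\t",
                           keep_default_na=False)
    congruence = pd.read_csv(out / "congruence.tsv", sep="\t",
                             keep_default_na=False)
    scan = pd.read_csv(out / "scan.tsv", sep="\t", keep_default_na=False,
                       na_values=[""])
    candidates = pd.read_csv(out / "candidates.tsv", sep="\t",
                             keep_default_na=False)

    per_group = groups_table.drop_duplicates("group_id")
    counts = {"groups_in": int(per_group.shape[0])}
    for pat, k in per_group["pattern"].value_counts().items():
        counts[f"pattern_{pat}"] = int(k)
    counts["excluded_by_pattern"] = int(
        (per_group["pattern"] == "excluded").sum())
    counts["pattern_pass"] = counts["groups_in"] - counts[
        "excluded_by_pattern"]
    counts["excluded_by_alignment"] = int(
        (align_qc.outcome == "excluded_stop").sum())
    counts["excluded_by_coverage"] = int(
        (align_qc.outcome == "excluded_coverage").sum())
    counts["alignment_pass"] = int((align_qc.outcome == "pass").sum())
    counts["excluded_by_congruence"] = int(
        (~congruence["pass"].astype(bool)).sum()) if len(congruence) else 0
    counts["congruence_pass"] = int(
        congruence["pass"].astype(bool).sum()) if len(congruence) else 0
    counts["tested_groups"] = int(scan["group_id"].nunique())
    counts["tested_records"] = int((scan["status"] == "tested").sum())
    counts["skipped_min_taxa"] = int(
        (scan["status"] == "skipped_min_taxa").sum())
    counts["candidates"] = int(candidates.shape[0])

    qc_rows = []
    for r in align_qc.itertuples():
        stage = ("pattern" if r.outcome == "excluded_pattern" else
                 "alignment" if r.outcome == "excluded_stop" else
                 "coverage")
        qc_rows.append({"group_id": r.group_id, "stage": stage,
                        "outcome": ("pass" if r.outcome == "pass"
                                    else "excluded"),
                        "detail": (f"coverage={r.coverage}"
                                   if r.coverage != "" else r.detail)})
    for r in congruence.to_dict("records"):
        qc_rows.append({
            "group_id": r["group_id"], "stage": "congruence",
            "outcome": "pass" if r["pass"] else "excluded",
            "detail": f"qdist_all={r['qdist_all']} "
                      f"qdist_third={r['qdist_third']} {r['note']}".strip()})
    qc = pd.DataFrame(qc_rows, columns=["group_id", "stage", "outcome",
                                        "detail"])
    qc.to_csv(out / "qc_report.tsv", sep="\t", index=False)

    enrichment = None
    scanned = set(scan["group_id"])
    known = [k for k in config.known_genes if k in scanned]
    if known:
        detected = [k for k in known
                    if k in set(candidates["group_id"])]
        p = enrichment_fisher(counts["tested_groups"],
                              counts["candidates"],
                              len(known), len(detected))
        enrichment = {"n_total": counts["tested_groups"],
                      "n_candidates": counts["candidates"],
                      "n_known": len(known),
                      "n_known_detected": len(detected), "p": p}
        with open(out / "enrichment.json", "w") as fh:
            json.dump(enrichment, fh, indent=2, sort_keys=True)
        logger.info("enrichment: %d/%d known genes detected, P=%.3g",
                    len(detected), len(known), p)

    with open(out / "counts.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
    config.to_yaml(out / "config.yaml")
    manifest = sorted(str(p.relative_to(out))
                      for p in out.rglob("*") if p.is_file()
                      and p.name != "MANIFEST")
    (out / "MANIFEST").write_text("\n".join(manifest) + "\n")
    return {"counts": counts, "enrichment": enrichment, "qc": qc}


def run_pipeline(config: PipelineConfig,
                 search: Optional[GeneTreeSearch] = None) -> PipelineResult:
    """Run all stages in order; returns the loaded result bundle.

    Unreadable inputs abort before any computation; per-group failures are
    recorded in the QC report and skipped.
    """
    # fail fast on unreadable inputs before any stage runs
    if not Path(config.synteny_table).exists():
        raise FileNotFoundError(config.synteny_table)
    read_cds_fastas(config.fasta_dir)

    stage_group(config)
    stage_align(config)
    stage_congruence(config, search=search)
    stage_scan(config)
    scan_q = stage_fdr(config)
    report = stage_report(config)
    out = config.run_dir
    candidates = pd.read_csv(out / "candidates.tsv", sep="\t",
                             keep_default_na=False)
    return PipelineResult(scan=scan_q, candidates=candidates,
                          qc=report["qc"], counts=report["counts"],
                          enrichment=report["enrichment"], out_dir=out)
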