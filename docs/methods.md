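# Methods

`c4scan` re-implements an automated genome-wide cross-species selection
scan for C4-photosynthesis genes in grasses as a tested, reusable
pipeline.  The genetic unit is the pan-grass syntenic ortholog group over
six species — maize (Zm), sorghum (Sb), *Setaria italica* (Si),
*Dichanthelium oligosanthes* (Do), rice (Os) and *Brachypodium
distachyon* (Bd) — on the species phylogeny `(((Zm,Sb),(Si,Do)),(Os,Bd))`.
Zm, Sb and Si are C4; Do, Os and Bd are C3.  Because syntenic orthologs
follow the species phylogeny, one uniform tree can be applied to every
gene, which is what makes the scan automatable.

## The codon substitution model and the branch test

Sequences evolve under a Goldman–Yang-style codon model on the 61 sense
codons (universal code).  Instantaneous change is restricted to pairs of
codons differing at one nucleotide position:

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

where `pi_j` is the stationary frequency of the target codon, `kappa` the
transition/transversion rate ratio and `omega = dN/dS`.  Rate matrices
are normalized to one expected substitution per codon per unit branch
length, so branch lengths are comparable across fits.  Codon frequencies
are the empirical F3x4 frequencies of each alignment (position-specific
nucleotide frequencies multiplied, stops removed, renormalized, floored
at 1e-10 so the reversible symmetrization stays diagonalizable); they are
never free parameters.

The branch model assigns each branch to one of two classes.  The null
hypothesis H0 fits a single `omega` shared by all branches; the
alternative Ha fits one `omega_fg` shared by all foreground (C4
transition) branches and one `omega_bg` for the rest.  The statistic
`2(lnL_a - lnL_0)`, clamped at zero, is referred to a chi-square with one
degree of freedom.  Under the default `stem_only` rule the foreground is
the stem branch of every maximal all-C4 clade — on the full tree, the
stem of (Zm,Sb) and the terminal Si branch; a `clade_all` option
additionally marks branches inside C4-only clades.  Alignments with no
variable column are reported as stat 0, p 1 with undefined omega
estimates rather than failing the batch.

Likelihoods are computed by Felsenstein pruning with per-pattern
compression; gap or ambiguous codons contribute a partial likelihood of 1
in every state.  Transition matrices come from one symmetric
eigendecomposition per (kappa, omega) via the reversible similarity
transform `D^1/2 Q D^-1/2`.  Because reversible likelihoods are invariant
to root placement, the two root-adjacent edges of a rooted tree are a
single unrooted edge: only their sum is identifiable, and in the unrooted
branch model they carry a single omega class.  Fits therefore merge them
— the foreground-classed child carries the summed length, the sibling is
pinned at zero — which both matches the model's semantics and removes an
optimization ridge (conditions 8 and 9 place the foreground stem at the
root).

## Maximum-likelihood fitting

Optimization is deterministic coordinate cycling: every branch length is
line-searched (bounded Brent on [0, 20]) against an objective that reuses
cached inside/outside partials, then kappa and the per-class omegas are
line-searched on a log scale (bounds [1e-3, 100] and [1e-4, 50]), until a
full cycle improves lnL by less than 1e-6 (at most 200 cycles).  The
first omega pass scans three fixed log-windows anchored at 0.1, 0.5 and
2.0 and keeps the best, so a fit cannot commit to the wrong side of a
bimodal omega profile; later passes search a window around the current
value.  The alternative fit warm-starts from the null fit's branch
lengths, kappa and omega (its first evaluation equals lnL_0, and every
step is accepted only if it improves, so lnL_a >= lnL_0 holds
structurally).  In the batch scan, conditions after the first warm-start
from the group's first fitted condition; warm starts change only the
optimization path, never the objective, and results stay deterministic.

Measured on one CPU, a six-taxon, 300-codon branch LRT takes about
0.3-0.45 s; null calibration at 200 codons runs at ~0.4 s per replicate.

## Ortholog grouping

The synteny table (TSV: `group_id, species, gene_id`) covers the five
core species.  Rows whose non-maize membership (the anchors) is identical
are unified into one group holding both maize whole-genome-duplication
homeologs (lexicographic order; three or more maize genes for one anchor
set excludes the group).  The closest Dichanthelium homolog of each
group's Setaria ortholog is attached by local alignment (match +2,
mismatch -3, gap open -5, gap extend -2; a gap of length L costs 5 + 2L;
minimum score 50) — a deterministic stand-in for BLASTN.  The pipeline
shortlists candidates by shared 12-mers through an inverted index (the
same seeding idea BLAST uses) and scores only the shortlist exactly;
`best_hit_homolog` itself scans every candidate.  Groups are then
classified into patterns i-iv by member counts; everything else is
excluded because C4 branches could not be unambiguously assigned.

## Alignment and trimming

CDSs are translated (terminal stops stripped; an internal stop excludes
the group), aligned as proteins by progressive profile-profile global
alignment along the species-tree guide topology (BLOSUM62, gap open 10,
extend 0.5, sum-of-pairs column scores, deterministic diag>up>left
tie-breaks), and back-translated to codons, so ungapping any row
reproduces its input CDS.  Trimming re-implements the Gblocks column and
block rules: a column is conserved when its top residue exceeds half the
rows (highly conserved at 85%), runs of more than 8 contiguous
nonconserved columns are rejected, gap-containing columns are rejected,
blocks are cut back to highly conserved flanks, and blocks under 10
columns are dropped.  Groups whose trimmed alignment keeps less than 30%
of the original codon columns are discarded (coverage exactly 0.30 is
kept; the denominator is the original alignment length, chosen over mean
CDS length for determinism under gap insertion).

## Gene-tree congruence filtering

Two gene trees per group — all nucleotide sites, and third codon
positions only — are inferred under GTR+Gamma+I (four gamma categories,
empirical base frequencies) over *all* unrooted topologies (3, 15, 105,
945 for 4-7 taxa), which guarantees the optimum heuristic searches only
approximate.  For speed the search is staged: every topology receives
ordinary-least-squares branch lengths against the Jukes-Cantor distance
matrix (the minimum-evolution screen behind FastME) and the ten best by
residual are re-ranked by branch-length-only ML under rate parameters fit
once on the best-screened topology; the winner — and always the species
topology — then get a full per-topology fit of branch lengths, gamma
shape and invariant fraction, and the max-lnL tree is returned (ties
break toward the canonical topology key).  The returned lnL is therefore
never below the species topology's refined lnL.  In validation the
staged search recovers the generating six-taxon topology from 300-codon
alignments essentially always (internal branches 0.2).

Congruence is operationalized as quartet distance exactly zero, computed
by explicit enumeration of all C(n,4) tip subsets via the four-point
condition on topological path lengths.  A group is excluded only when
*both* gene trees conflict with the species tree.  Maize homeolog pairs
must form a cherry in a gene tree (otherwise that tree fails) and are
collapsed to a single maize tip before comparison.

## The nine conditions and candidate merging

Condition 1 tests the full phylogeny; conditions 2-7 remove one or two C4
lineages ({Zm}, {Sb}, {Si}, {Zm,Sb}, {Sb,Si}, {Zm,Si}); conditions 8 and
9 remove Dichanthelium and the Setaria-Dichanthelium clade.  Removal sets
are applied to each group's pattern-specific tree (homeolog cherries
count as two tips), degree-2 nodes are suppressed, and tests with fewer
than four remaining taxa are skipped.  Homeolog pairs are tested jointly
as a cherry by default; a `separate` mode tests each homeolog as its own
single-maize unit.

P-values are corrected within each condition by Benjamini-Hochberg
step-up (an optional Storey pi0 variant is provided).  BH replaces the
empirical-null local-fdr estimator of the original workflow because it is
distribution-free, deterministic and well defined at small batch sizes;
its q-values are not numerically comparable to local-fdr values fitted to
genome-scale batches.  A group is a candidate iff some condition has
q < 0.2 (strict) *and* omega_fg > omega_bg in that test — the explicit
elevated-direction requirement, since a two-sided branch test can also
flag decreased omega.  Enrichment of known genes among candidates is a
one-sided hypergeometric exact test computed by direct summation in log
space.  (The source study prints Fisher P = 2.3e-9 for 7 of 11 known
genes among 88 of 6784; a standard one-sided hypergeometric on those
counts gives a much smaller value, so that printed number is not a
reproduction target — this package reports the standard exact test.)

## The synthetic-data generator

The generator defines the study conditions the tests run under.  Defaults:
300 codons per gene, kappa 2, background omega 0.2, foreground omega 4.0
for a selected fraction of 10%, species-tree branch lengths 0.1
(terminal) and 0.15 (internal) expected codon substitutions per codon,
maize-duplication probability 0.1 (homeolog cherry branches 0.02), rice
and Brachypodium loss probabilities 0.05 each, and 5% discordant groups
simulated on a fixed alternative topology with Sb and Si exchanged.
Branch lengths are desk-scale choices (the source material states none)
sized so that a six-taxon, 300-codon gene carries clear but not saturated
signal; discordance is topological rather than coalescent — enough to
exercise the filter, not a model of incomplete lineage sorting.  Selected
/ duplicated / lost / discordant groups are allocated by exact counts to
seed-derived indices, so truth tables are deterministic.  Stationary
codon frequencies are a mildly non-uniform Dirichlet(50) draw shared by a
cohort.  Sequences are gap-free and in frame; the aligner's indel
handling is tested separately on constructed cases.  Consequently,
passing tests demonstrate correctness of the statistical machinery and
the pipeline's operating characteristics under the assumed model — not
robustness to alignment error, saturation, or real incomplete lineage
sorting.

## Validation summary (all recomputed by the test suite)

* Pruning log-likelihoods equal brute-force marginalization over internal
  states on all trees with <= 4 tips, codon and nucleotide (|diff| < 1e-8).
* Closed forms: JC transition probability 0.752740 at t = 0.3; two-taxon
  JC lnL -1.67033; JC distance MLE 0.10733 for 10/100 mismatches; gamma
  rates [0.30685, 1.69315] at alpha = 1, k = 2.
* 500 seeded null replicates (6 taxa, 200 codons): LRT rejection at
  p < 0.05 falls in [0.03, 0.07].
* 50 replicates at omega_fg 3 / omega_bg 0.2 (500 codons): median
  estimates within [2.4, 3.6] and [0.15, 0.25].
* Quartet distance equals an independently coded restriction-based
  enumerator on 200 random six-taxon pairs; the worked five-taxon example
  returns exactly 2.
* Congruence filter: >= 90% of concordant and >= 90% of discordant
  synthetic groups (300 codons, internal branches 0.2) are retained /
  excluded respectively.
* A 200-group cohort (10% selected) run end to end recovers >= 50% of the
  selected groups with realized false-discovery proportion <= 0.35 at
  q < 0.2, with stage counts conserving at every filter.  Byte-identical
  re-runs are witnessed on a 10-group cohort (the pipeline contains no
  randomness; the reduced size keeps the determinism check affordable).

## Problem sizes and numerical choices

Test-suite simulations use six-taxon trees, 200-500 codons, and cohorts
of 10-200 groups; `scripts/acceptance.py` re-measures the same quantities
at 100-200 replicates / 100 groups.  These sizes are the package's chosen
desk scale: large enough for stable operating characteristics, small
enough to iterate on.  Bounds: omega in [1e-4, 50], kappa in [1e-3, 100],
branch lengths in [0, 20], gamma shape in [0.05, 20], invariant fraction
in [0, 0.9]; ties in bounded searches resolve toward the lower bound.
Site-model and branch-site tests, amino-acid models, >7-taxon gene trees,
bootstrap supports, de-novo synteny detection and gene-ontology
enrichment are out of scope.
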