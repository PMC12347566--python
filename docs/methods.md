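# Methods

This note documents the models and procedures implemented in `rbcskit`,
the conventions pinned where published descriptions are ambiguous, and the
limits of what the synthetic-data tests demonstrate.

## Coordinates, formats and conventions

Gene coordinates are 1-based inclusive (GFF3 convention) at every module
boundary; all internal interval arithmetic is 0-based half-open, with the
conversion made exactly once via `GeneModel.start0/end0`. PDB ATOM records
are parsed by fixed column slicing (x, y, z from columns 31–54), never by
whitespace; altloc codes other than blank/'A' are skipped, and elements are
inferred from the atom name when the element column is blank. FASTA output
wraps at 60 columns. Newick trees may carry branch-group labels as
`#group` suffixes on node labels (PAML-style); they are stripped into a
label → group map.

Promoter hits are reported TSS-relative: offset −1 is the base immediately
upstream of the annotated gene start (the TSS is operationalized as the
gene start). Upstream extraction takes `[start−L, start−1]` on '+' genes
and the reverse complement of `[end+1, end+L]` on '−' genes, truncating
with a warning at chromosome edges. The anchoring feature type defaults to
`gene` (configurable), since annotations differ in whether promoters are
defined against gene or mRNA records.

## Family curation

Homology filtering uses global pairwise alignment (BLOSUM62, affine gaps:
open 10, extend 1). Percent identity is counted over non-gap aligned
columns; coverage is the fraction of *reference* positions aligned to a
candidate residue. Published pipelines delegate this step to heuristic
search tools without stating the exact identity/coverage definitions; one
reproducible convention is pinned here, and query-coverage is the default
(target- and dual-coverage variants are not implemented). Domain presence
is approximated by local alignment against an editable consensus per
domain, retained when the score reaches a configurable fraction (default
0.5) of the consensus self-score. This is a deliberate surrogate for
profile-HMM search: it keeps the package dependency-light and is adequate
for truncation screening, but it is not position-specific and should not
be used for remote homology. The shipped consensus strings are synthetic
placeholders meant to be replaced with curated models.

## Tandem arrays

Genes on one chromosome are sorted by start and chained while the
inter-gene gap (`next.start − prev.end − 1`, floored at 0 for overlaps) is
≤ `max_gap_bp`. The clustering gap is not standardized in the literature;
the default of 300 kb matches the order of magnitude of reported RBCS
array spans and is exposed as a parameter. Spans are emitted in both
conventions — outermost-coordinate difference and the inclusive +1 variant
— because published span figures do not state which was used. Strand is
ignored for membership.

## Promoter CRE scanning and the paired I-box

Motifs are degenerate IUPAC consensi matched exactly (no mismatches, no
log-odds scores) on both strands, with overlapping hits all reported.
Palindromic consensi yield one hit per strand; a collapse flag deduplicates
them. The shipped library covers the CRE classes commonly reported in RBCS
promoters (light: I-box `GATAAG`, G-box `CACGTG`; drought MYB variants;
ABA-associated MYC variants; stress STRE `AGGGG`; anaerobic ARE; low
temperature LTR; wound WUN/WRE3). Library entries are editable TSV rows
and every analysis parameterizes on the library file — database-exact
consensus strings can be dropped in without code changes.

A paired I-box calls two non-overlapping same-motif hits with
`spacer_min ≤ spacer ≤ spacer_max` (default window [20, 30] bp, bracketing
the reported ~25–26 bp spacing) and the *downstream element's 3' end*
within `max_tss_distance` (default 168 bp) of the TSS. The spacer is the
gap from the upstream hit's end to the downstream hit's start;
start-to-start measurement is available behind a flag. Where the distance
rule anchors (downstream edge vs pair midpoint) is ambiguous in prose; the
downstream edge is pinned.

## Expression analysis

Within-sample shares are 100 × TPM_g / Σ_family TPM; they are unit-free,
so FPKM matrices work identically (cross-unit comparisons between species
are the caller's responsibility). The growth-habit contrast sums TPM over
family members per sample, then applies a two-sample pooled-variance
Student t-test (df = n₁ + n₂ − 2; Welch available behind a flag). The
percent difference is 100 × (W − S) / W with the winter mean as
denominator — the only convention that reproduces both published tissue
contrasts from their printed means (28.44 exactly; 50.31 vs the printed
50.32, consistent with rounding of unrounded means). Zero pooled variance
returns t = 0, p = 1 at equal means and an infinite-t flag otherwise.

## Structure screen

Interface contacts use heavy atoms only (H/D excluded): predicted models
often lack hydrogens, so this maximizes comparability between experimental
and predicted structures. A small-subunit residue is a contact when the
minimum Euclidean distance from its heavy atoms to any large-subunit heavy
atom is ≤ cutoff (default 4.0 Å, boundary inclusive); distances are
reported to 3 dp.

Divergence classification works per alignment column: strict mode calls a
candidate when some residue occurs in ≥ ⌈|C4|/2⌉ C4 species and zero C3
species; relaxed(k) tolerates ≤ k C3 carriers. Gaps are ignored in counts.
Both the alignment-column index and a reference-row position are reported
to avoid off-by-N numbering disputes between reference choices. Both modes
are exposed because the published screen's effective rule admitted one C3
exception for one selected site; strict candidates are always a subset of
relaxed ones.

`kabsch_rmsd` computes the closed-form least-squares superposition
(SVD of the cross-covariance; determinant correction enforces a proper
rotation) and is intended as the post-statistic for trajectory or model
comparisons; molecular dynamics itself is out of scope. Collinear point
sets warn (the rotation is not unique) but the RMSD is still defined.

## Selection analysis

Full ML fitting of branch and branch-site codon models (GY94/F3×4, Model A
site classes) is out of scope. Published fits enter as records of
(model name, np, lnL); the LRT computes 2ΔL = 2(lnL_alt − lnL_null),
clamped at 0 with a warning if negative (possible with lnL rounded to
2 dp), df = np_alt − np_null, and p from the χ² upper tail. The np values
follow the published table's convention (ω parameters only, excluding
branch lengths and κ).

The in-repo estimator is Nei–Gojobori (1986) counting: synonymous site
fractions per codon averaged over the two sequences (changes creating stop
codons count as nonsynonymous, so S + N = 3 × codons exactly); multi-hit
codon pairs averaged over all single-step pathways that avoid stops, with
minimum-stop pathways used as a fallback when every ordering crosses a
stop; Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3), raising a
saturation error at p ≥ 0.75; ω = dN/dS, flagged undefined at dS = 0.
Codons containing ambiguity codes are excluded pairwise with a count.
Group summaries average ω over within-group leaf pairs and report
cross-group contrasts; single-leaf groups are skipped with a warning.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of a `SimulationConfig`; each draws from
its own RNG stream derived from the master seed by a fixed label, so
outputs are bit-reproducible and independent across generators.

- **Genomes**: one chromosome (default 2 Mb) with a planted tandem array
  (default 5 genes of 1 kb separated by 50 kb — inclusive span 205 kb, the
  order of published array spans) plus dispersed singletons. Singletons
  are placed ≥ 2 × array_gap from the cluster and never closer than twice
  the default clustering gap, so planted "dispersed" copies are dispersed
  under the default detector too. No transposons, synteny or strand
  structure is modelled.
- **Promoters**: i.i.d. background (default uniform base composition,
  configurable GC) with motif instances written at exact TSS-relative
  offsets; a planted I-box pair uses the configured spacer (default tests
  use 25 bp) and TSS distance (default 59 bp). Real promoter grammar,
  nucleosome structure and motif clustering are not modelled, so detector
  tests demonstrate correctness of the scan, not biological realism;
  background motif frequencies follow directly from consensus length and
  composition.
- **Codon evolution**: acceptance sampling rather than a full GY94 rate
  matrix — per edge, Poisson(μ·3·L·t) candidate events; transition-biased
  alternative bases (κ, default 2); events creating stops redrawn;
  nonsynonymous events fixed with probability ω of the edge's branch
  group. This reproduces the *ordering* structure of branch-specific ω and
  is adequate for recovery tests, but it is not a reversible substitution
  process and has no indels. Neutral-recovery tests run at κ = 1 because
  the NG86 estimator's equal-weight pathway counting itself assumes no
  transition/transversion bias; with κ > 1 NG86 is known to be biased, a
  property of the estimator, not a defect of the simulator.
- **Expression**: TPM values i.i.d. lognormal per gene × sample (defaults:
  log-mean 7 ≈ 1100 TPM, log-sd 0.5, 6 family genes — family sums in the
  thousands, like photosynthetic gene families), with winter columns
  multiplied by a group factor; sample sizes default to the published
  design (5 winter, 14 spring). Biological covariance between genes,
  tissue effects and count noise are not modelled, so the t-test
  calibration result speaks to the test implementation under a skewed but
  well-behaved null, not to RNA-seq data at large.
- **Toy complexes**: chain L is a row of CA atoms 5 Å apart; each planted
  contact places one chain-S atom at exactly the requested distance from
  its nearest L atom; filler S residues sit ≥ 10 Å away. Geometry only —
  no sterics or chemistry.

## Problem sizes and numerical choices

Recovery and calibration analyses use: 200 replicates of 500-codon
two-leaf simulations for the ω-ordering check (ω 0.2 vs 0.05, μt = 0.1 per
branch of length 0.3); 100 replicates of 1000 codons for neutral-ω
recovery; 1000 null replicates for t-test type-I calibration. These sizes
give Monte-Carlo standard errors comfortably below the decision margins
(e.g. ±0.7 pp on a 5% rejection rate) while keeping the whole suite in
seconds. χ² tail probabilities come from `scipy.stats.chi2.sf` and are
cross-checked against the df = 1 closed form erfc(√(x/2)) to 1e-10.
Pearson r is clamped to [−1, 1] against floating-point overshoot; |r| = 1
reports p = 0 with an infinite t. Tie-breaking in divergence
classification scans residues in descending C4 frequency.

## Known limitations

- No orthology inference, synteny analysis, tree building or alignment
  construction: trees and alignments are inputs.
- The motif and domain libraries are editable surrogates, not database
  exports.
- NG86 underestimates ω under strong transition bias and saturates at
  high divergence; it is a desk-scale companion to, not a replacement
  for, codon-model ML fitting.
- Branch-site site-class parameters (p₀, p₁, ω₂, …) and per-site posterior
  identification are not estimated.
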