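# Methods

## Scope and model

`methmotif` characterizes the relationship between the local DNA sequence
context of CpG sites and the behavior of their methylation: stability
across individuals in normal tissue, and hyper-/hypo-methylation aberration
in cancer.  The unit of analysis is a CpG probe with a 42-nt window — 20 bp
of flank on each side of the central CG dinucleotide.  The window includes
the CpG itself so that motifs containing CG at the probed site remain
discoverable; discovered motifs are not required to contain it.

## CpG selection

Per-CpG variance of beta values across samples uses the unbiased estimator
(divisor n−1).  Stable/unstable sets take values strictly below the 1st /
strictly above the 99th percentile of the variance distribution, with
percentiles computed by linear interpolation between order statistics
(numpy's default).  Both choices — estimator and percentile rule — are
conventional; the strict inequalities follow the definitions of the sets
("below"/"above").  Selections are computed on all loaded CpGs; rows with
missing beta values are dropped at load time.  iDMC tables are split by
their hyper/hypo direction token; conflicting duplicate labels are an
error, not a silent resolution.

## Discriminative motif discovery

Per round:

1. Every exact A/C/G/T word of length 3–8 occurring in the positive set is
   a candidate.  Counting is zero-or-one per sequence; windows containing a
   masked base (N) never match.
2. Each candidate is scored by the one-sided Fisher exact test on the 2×2
   table (positive/background × with/without), computed as the
   hypergeometric tail P(X ≥ k) of the pooled table.
3. The 100 best-scoring words seed best-improvement hill climbing: one
   position at a time is widened to any strict IUPAC superset, accepting
   only strict p improvements.  The first and last columns are never
   widened to the full wildcard N, keeping motif boundaries informative.
   Ties break toward shorter motifs, then lexicographically smaller
   consensus — the procedure is fully deterministic.
4. The round's best motif gets E = p × (number of exact candidate words
   tested in the round).  If E < 0.05 it is emitted, all its match windows
   in both sequence sets are replaced by N, and the search repeats (default
   cap: 20 rounds; the pipeline default is 10).

Forward strand only by default — flanks are oriented relative to the
probed CpG — with a reverse-complement option.  Candidate scoring is
vectorized (an inverted k-mer index plus a vectorized hypergeometric tail),
so a 500/5000 × 42-nt round takes a few seconds on one core.

The E-value corrects only for the words tested within a round; with very
small positive sets (tens of sequences) the correction is lenient and
occasional chance motifs can pass, as in any discriminative elicitation of
this family.  Power properties in the test suite are therefore asserted on
recovery of planted signal, not absence of extras.

## Direction labels and enrichment

A motif's member CpGs are those whose window contains ≥1 match.  The label
rule is strict: frac_hyper > 0.70 → hyper, frac_hypo > 0.70 → hypo, else
undefined.  Both over-representation tails P(X ≥ k) are reported per motif
against the background with known directions — for cancer runs, the input
iDMC set (configurable) — significant at p < 0.05 per direction with no
cross-motif correction (none is applied anywhere p-thresholds are used as
screens).  The two tails of one motif are mutually exclusive below 0.5, so
at most one direction can be significant.

## Genomic annotation

Gene-region counts increment once per region per CpG (a CpG may belong to
several of TSS1500, TSS200, 5'UTR, 1stExon, Body, 3'UTR, so gene counts can
exceed the member count); each CpG has exactly one CGI context class, so
CGI counts sum to the member count.

## Motif distance and clustering

For two IUPAC motifs, every ungapped offset with ≥3 aligned columns is
scored: column similarity is |Sa ∩ Sb| / |Sa ∪ Sb| over allowed-base sets;
the alignment score is the summed similarity divided by max(len a, len b);
the distance is 1 − best score.  Normalizing by the longer length penalizes
length mismatch, so containment is deliberately not distance 0.  The
distance is symmetric, in [0,1], and 0 exactly for identical motifs.
Reverse-complement alignment is off by default.  Clustering is scipy
average linkage on the distance matrix with groups cut at height 0.3
(default); trees are exported as Newick.  Jaccard distance between CpG ID
sets (1 − |∩|/|∪|, two empty sets at 0) serves the set-level comparison of
per-tissue iDMC collections.

## TF matching

Queries are position frequency matrices (uniform over each IUPAC set);
targets are database PWMs.  Alignment is ungapped over all offsets with ≥5
aligned columns, scored by mean column similarity 1 − ‖q−t‖/√2, best of
both target orientations (TF databases are strand-symmetric).
Significance uses a seeded column-shuffle empirical null preserving the
target's column multiset: p = (1 + #{null ≥ observed}) / (n_shuffles + 1),
E = p × database size, filtered at E < 10.  This replaces the analytic
null of the original Tomtom tool with a simpler, directly testable
Monte-Carlo estimate; with 1000 shuffles the p resolution (~10⁻³) is ample
for the lenient E < 10 screen.  The Euclidean column function is one of
Tomtom's standard options.

## Regulation concordance

Concordant: MethylPlus TF at a hyper-methylated motif, or MethylMinus at a
hypo-methylated one; discordant otherwise; undefined labels or unknown
classes are excluded.  Differential expression per target gene is an
unpaired two-sided Wilcoxon rank-sum test — exact enumeration for tie-free
groups of ≤20, otherwise the normal approximation with tie correction — on
raw p < 0.05 with direction from the sign of the tumor−normal median
difference (an exactly zero difference is never called; with n = 3 vs 3
the smallest achievable two-sided p is 0.1, so such pairs cannot be
called at 0.05).  Regulation per pair is a strict >50% majority among DE
targets; zero DE targets → mixed.  The contingency summary is emitted both
by pairs and by unique DE genes, because a cell tally can reasonably count
either; the two tables are written side by side.

## Synthetic data

The generator emulates exactly the features downstream stages consume:

- **Flanks**: i.i.d. bases at a target GC fraction (default 0.5) around a
  fixed central CG; random genomic annotations (0–3 gene regions, one CGI
  class, uniform).
- **Planted motifs**: a concrete instantiation of an IUPAC word overwrites
  a uniformly chosen offset (never touching the central CG) in a fraction
  of a designated subset (default 30%) and of the remainder (default 1%) —
  the enrichment signal discovery must find.  Defaults use a 500-CpG subset
  within 5000 sequences for discovery benchmarks and the 150-CpG hyper-iDMC
  subset within 2000 CpGs for the end-to-end pipeline fixture.
- **Beta values**: per-CpG i.i.d. Beta(μc, (1−μ)c) across samples, with a
  99%/1% split between concentration c=100 (stable) and c=2 (unstable)
  groups at μ=0.5; variance μ(1−μ)/(1+c) differs ~30-fold, a clean but not
  extreme separation.  No sample covariance is modeled — sufficient for
  variance-percentile behavior, not for co-methylation structure.
- **iDMC labels**: disjoint random hyper/hypo subsets (150 + 150 of 2000 by
  default).
- **TF database**: PWMs from consensus words with multinomial count noise
  (50 sites, 0.05 off-consensus floor), classes MethylPlus/MethylMinus/
  unknown at 0.4/0.4/0.2.
- **Expression**: log2-scale values, normal samples N(base, 1) with base ~
  U(4, 10); planted DE genes (80% of a TF's targets when a direction is
  planted) shifted by ±2.0 in tumor — roughly a "large fold change at
  moderate noise" regime where the rank-sum test at n=50/50 has essentially
  full power, which is what the power checks require.  A per-TF "mixed"
  direction shifts each target independently.

Every generator is a pure function of its arguments including the seed;
per-stage child streams are derived from the one config seed, and the TF
database stream is independent of the direction-override stream so the
same database can be re-generated under different planted regulation
scenarios.

What passing tests on this data do **not** show: robustness to batch
effects, probe cross-reactivity, co-methylation covariance, realistic
genomic coordinate structure, or empirically realistic tissue variance
distributions (the variance-group defaults are chosen for test power, not
realism).

## Numerical and degenerate-input choices

- Exact tests use scipy's hypergeometric survival function; the test suite
  verifies agreement with direct pmf-tail enumeration to 1e-10 for all
  configurations with N ≤ 50.
- E-values are floored at the underlying p (a correction factor below 1 is
  never applied).
- Empty selections, empty iDMC tables, conflicting direction labels,
  inconsistent test counts, non-symmetric distance matrices and degenerate
  Wilcoxon groups (<3 values, or all values tied) raise immediately rather
  than propagating NaNs; a single-column TF target is unshuffleable and
  reports p = 1.
- Two empty sets are at Jaccard distance 0 by convention.
- The pipeline manifest contains parameters, per-stage counts and sha256
  checksums of every output, and no timestamps or absolute paths, so a
  same-seed rerun is byte-identical.

## Problem sizes used in the checks

Discovery benchmarks run at 500 positive / 5000 background 42-nt windows;
selection calibration at 10,000 CpGs × 100 samples; Wilcoxon level at 2000
null simulations of 50 vs 50; the end-to-end fixture at 2000 CpGs, 20 TFs
and 200 target genes.  These sizes give the recovery and calibration
properties comfortable statistical margins while keeping the whole suite
fast on a single core.
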