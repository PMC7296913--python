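# Methods

This note documents the models and conventions behind `chromdiff`: what
each stage computes, the assumptions it rests on, what the synthetic
data generator does and does not emulate, and the design choices made
where more than one reasonable convention existed.

## Coordinates and regions

All intervals are 0-based, half-open. BED-family files are read and
written natively; GFF3 starts are decremented on read. Gene sub-regions
are strand-aware: the "first" 1 kb or 20 % of a minus-strand gene is
measured from its higher coordinate. Percent regions use
`floor(0.2 · length)` bp so region boundaries are deterministic
integers. Genes shorter than 1 kb contribute their whole body as the
first 1 kb — no length filter is applied anywhere. The 2-kb upstream
flank is clipped at chromosome bounds. A peak may annotate to several
genes whose first-1-kb regions it overlaps; it counts for all of them.
`merge_intervals` returns the minimal interval cover (touching intervals
coalesce); replicate concordance, in contrast, requires a strict ≥ 1 bp
overlap between replicates before the surviving peaks are merged.

## Coverage scaling

The scaling unit is `(count + 1) / (total base coverage in Gb)`, with
total base coverage the summed fragment lengths of the library. This
normalizes for sequencing effort in *bases*, so libraries with different
fragment-length distributions remain comparable, and it is exactly
inversely proportional to coverage: multiplying a library's coverage by
k divides every scaled value by k. A fragment is counted in every 50-bp
bin (or gene region) it overlaps by ≥ 1 bp — coverage-style counting,
not midpoint assignment — so a 200-bp fragment typically increments
four or five bins. Replicates are averaged only after scaling, and all
mutant − wild-type differentials are taken on replicate-averaged values.

Metagene profiles rescale each gene body to 100 relative bins by linear
interpolation of the native 50-bp values, keep 2-kb flanks at native
resolution, read 5′→3′, and summarize across genes by the median
(positions off a chromosome end are dropped from the median). The flank
width and body bin count are conventions, not estimates; both are
parameters. Summit profiles take the track value at signed 50-bp offsets
in a symmetric window (default ±1 kb) around each summit and report the
per-offset median.

## M-A differential model

For each candidate peak, fragments are counted in a 1000-bp window
centred on the peak midpoint. Single-end fragments are represented by
their 5′ position shifted by half the fragment length toward the centre
(so both strands land on the fragment midpoint). With pseudocount 0.5,
M = log2 ratio and A = mean log2 intensity. The normalization line
M = α + β·A is fitted on peaks common to both samples — the assumption,
as in all M-A normalization, is that common peaks are mostly unchanged —
by Huber IRLS (≤ 50 iterations, tolerance 1e-8), stabilized as the
coordinate-wise median over 100 bootstrap resamples. Each peak of either
sample is tested as its own record; peaks are deliberately *not* merged
across samples first, because a short gained region nested inside a
broad unchanged peak would otherwise be averaged away at the merged
peak's midpoint. Significance: M_norm and A are solved back to rescaled
counts (a′, b′), and the p-value is the exact two-sided binomial
probability of a split at least as extreme as (round a′, round b′) under
p = ½. Cutoffs are p < 0.05 and |M_norm| > 0. Replicate comparisons are
filtered independently; only peaks overlapping (≥ 1 bp) across both
comparisons with the same direction survive, and survivors are merged.
Targets are protein-coding genes with an "up" peak in the first 1 kb,
minus genes that also carry a "down" peak there.

Because counts conditional on their sum are exactly binomial under the
null, the test is exactly calibrated up to discreteness; at window
counts below ~50 per sample the discreteness makes it conservative
(empirical level ≈ 0.043 at λ ≈ 20–200, ≈ 0.046 at λ ≈ 100–500). The
calibration experiment in the tests therefore uses window intensities of
100–500 fragments, typical of 1-kb windows over broad-mark peaks at
standard depth, where discreteness is negligible.

## Mark categories and PRC1 dependency

Mark presence is binary — at least one replicate-concordant peak
overlapping the first 1 kb — and enrichment magnitude never enters
classification. The four H2Aub1 × H3K27me3 categories partition the
universe exactly. A K27-marked gene is PRC1-dependent iff a
replicate-concordant peak of *decreased* K27 in the PRC1 mutant overlaps
its first 1 kb; K27-absence takes precedence (a gene without the mark is
`non_k27` regardless of differential peaks). The same first-1-kb rule is
reused for optional H2A.Z and REF6 presence calls.

## Motifs and the REF6 regression

CTCTGYTY (Y ∈ {C, T}) is scanned on both strands; reverse-strand hits
are reported at their forward-strand start, overlapping matches are all
kept, and N never matches. The motif is non-palindromic, so a position
cannot be double-counted. Clusters are maximal runs of ≥ 4 sorted hits
whose span (first start to last end) fits in 600 bp, found by a linear
two-pointer sweep; overlapping cluster intervals are merged and motif
counts recomputed over the merged interval. Motif membership in a peak
or window is judged by the motif's start coordinate — an explicit,
boundary-unambiguous convention for 8-mers.

The window table pairs the replicate-averaged H2Aub1 and REF6 tracks on
their common 50-bp grid and counts motif starts in [centre − 300,
centre + 300) per bin. The regression is ordinary least squares of
log10(REF6) on log10(H2Aub1) within each motif-count stratum (0–4, 5+);
the +1 scaling pseudocount guarantees the logs are defined. The slope is
invariant to rescaling either track by a constant.

## Statistics

* Hypergeometric enrichment: expected overlap |A||B|/N, fold =
  observed/expected, upper-tail p = P[X ≥ observed].
* Mann-Whitney U: midrank ties; exact two-sided p by full labeling
  enumeration when the pooled sample is ≤ 12 and tie-free, otherwise the
  normal approximation with continuity and tie corrections.
* Up/down asymmetry: one-degree Pearson chi-square against an equal
  split.
* Bonferroni with a caller-fixed family size (m = 6 throughout the
  pipeline's post-hoc families), never inferred from the number of
  p-values supplied.
* ANCOVA: additive OLS `expression ~ h2aub + k27` on the fpkm scale, no
  interaction term — presence of one mark is *adjusted for*, not
  interacted with, the other. EMMs average model predictions over the
  two levels of the other factor with equal weights (the standard EMM
  definition; observed-cell-size weighting was the alternative). With an
  empty design cell the model is still fit and a warning is raised.
* DE filtering: up = {log2FC ≥ cutoff ∧ p_adj < 0.05 ∧ CPM pass}, down
  symmetric; cutoff 1 by default, 4 for externally supplied tables that
  were not re-analyzed. Undetected genes carry log2FC = 0 in
  distribution displays. Up and down sets are disjoint by construction.
* Responsiveness: per-category medians with pairwise Mann-Whitney tests
  (Bonferroni m = 6); genes without a score are excluded, as are probes
  mapping to multiple loci upstream of this package.

## The synthetic study

The generator emulates the statistical structure the pipeline assumes,
not sequencing itself. Defaults are the study conditions: 2 chromosomes
× 1.25 Mb (50,000 bins at 50 bp), 200 non-overlapping genes of 1–4 kb
(~5 % non-coding to exercise the biotype filter), 20 %/20 %/15 % of
genes H2Aub1-only/K27-only/both, 20 planted targets, 8-fold target
enrichment, background 0.02 fragment starts per bp, 200-bp fragments,
2 replicates per condition, planted REF6 slope 0.4, planted target
log2FC 3, responsiveness shift +3 for H2Aub1-marked genes.

Fragments follow a homogeneous Poisson process per constant-rate
segment. Marked gene bodies are enriched by a per-gene fold that is
log-normal around `enrichment_fold` (sd 1 in log2): continuous per-gene
enrichment is realistic and is also what identifies the M~A
normalization trend — with a single fixed fold all common peaks collapse
to one A value and the robust line is unidentified in slope. In the
mutant, target genes' first 1 kb gains H2Aub1 (× fold relative to wild
type, whatever the gene's wild-type state) and loses H3K27me3 (× 0.25).
Called peaks are the true marked regions with boundaries jittered ±30 bp
per replicate, so replicate-concordance logic does real work. H3 control
libraries are flat background.

REF6 fragments are drawn per 50-bp bin with Poisson rate
λ + 1 = C·(H2Aub1 scaled)^slope, where the H2Aub1 value is the realized
replicate-averaged wild-type (or mutant) track and C puts the median bin
at 5 expected fragments. Three deliberate choices make the planted slope
the quantity the pipeline measures: the +1 on the left cancels the +1
scaling pseudocount, so the measured per-bin expectation follows the
power law exactly; coupling to the *realized* H2Aub1 track means the
regression's x is the same quantity used in planting (no
errors-in-variables attenuation); and REF6 fragments span exactly one
bin — appropriate for a punctate DNA-binding factor — so the per-bin law
is not smeared across neighbours by fragment overlap. Only Poisson noise
in REF6 separates planting from measurement.

The DE table plants log2FC = 3 (+ Gaussian noise, sd 0.2) at targets and
0 elsewhere; p-values come from a z-test on three simulated Poisson
replicates per genotype, BH-adjusted. Wild-type expression carries
multiplicative planted mark effects (+1 log2 for H2Aub1, −1.5 log2 for
K27) so the ANCOVA and responsiveness stages have signal to recover.
Motifs are implanted into random sequence (0.3/kb plus the requested
clusters of 4 within 600 bp); ground-truth motif positions are defined
as a rescan of the final sequence, so chance background matches are
included by construction. Motif placement is independent of genes and
marks, which is what makes stratifying the REF6 regression by motif
count a slope-invariance check.

Everything derives from named, per-component substreams of the seed:
identical config + seed gives byte-identical fixture files.

### What the generator does not emulate

Read-level artefacts (sequencing error, mappability, GC bias, duplicate
reads), peak-caller behaviour (peaks are jittered truth, not called from
the fragments), fragment-length variation within a library, biological
replicate variance beyond Poisson counting noise, chromatin-state
autocorrelation beyond gene-scale blocks, and any coupling between motif
clusters and REF6 beyond the H2Aub1 pathway. Passing recovery tests
therefore demonstrates the *pipeline's* correctness and calibration on
data satisfying its model assumptions — not robustness to the
misspecifications of real chromatin data.

## Problem sizes and numerical choices

Tests exercise the primitives on hundreds of randomized instances
against brute-force oracles (per-base masks, all-pairs overlap, naive
8-mer comparison, exhaustive window enumeration, exact combinatorial
enumeration for the small-sample statistics). Recovery experiments use
the default 200-gene / 2.5-Mb study; the M-A calibration experiment uses
10 × 1000 synthetic null peaks. The bootstrap of the normalization fit
uses 100 resamples in the pipeline and 20 in the calibration experiment,
where the fit is nearly noiseless anyway. Degenerate inputs are handled
explicitly: zero coverage, empty gene sets, empty summit lists (warning,
NaN profile), constant-M fits (flat line returned without IRLS),
zero-variance regressions (error, or slope 0 when only y is constant),
and empty ANCOVA cells (warning).

## Known limitations

Exact binomial discreteness makes the differential test conservative at
low window counts. The "merged" convention for concordant peaks is the
union of the replicate calls, which can slightly over-extend true
regions. Whether an original-style analysis filters significance before
or after replicate matching is not fully determined by convention; this
implementation filters per replicate comparison first. Overlapping-gene
disambiguation is "annotate to all". Transcript structure (exons,
isoforms) is out of scope throughout.
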