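# Methods

This note documents the models, conventions, and parameter choices
behind each stage, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want spelled out.

## Off-target scanning

**Model.** A candidate siRNA is any 21–24 nt window of the dsRNA
construct; both strands contribute windows because Dicer processes the
duplex (a flag disables the antisense set). A transcript is a potential
off-target if some window matches it within a mismatch budget measured
as **Hamming distance**: substitutions only, no insertions or
deletions. Gapped similarity is deliberately out of scope — siRNA-guide
pairing tolerates mismatches far better than bulges, and the ungapped
model keeps the scan exactly verifiable against a brute-force oracle.

**Algorithm.** Duplicate window sequences are collapsed before
matching and hits are attributed back to every source position. The
default execution path builds a pigeonhole seed index: for a k-mer
query at mismatch budget *m*, any admissible occurrence must contain
one of *m* + 1 disjoint exact seed chunks of length ⌊k/(m+1)⌋ (21-mers
at *m* = 2 give 7 nt seeds). Exact seed occurrences are looked up,
candidate offsets verified by direct Hamming recount, and transcripts
shorter than the seed fall back to an all-offsets scan. The indexed
path is property-tested to return exactly the brute-force hit set, hit
distances are recomputed before emission, and hit sets are monotone in
the budget.

**Coordinates.** 0-based half-open internally; 1-based inclusive in
reports. Antisense k-mers are positioned on the sense coordinate
system of the construct.

**Evidence combination.** `combine_offtargets` tiers transcripts by
their minimum mismatch count (cumulative tiers: genes at ≤1 mismatch
are a subset of genes at ≤2). Mode `all_mock` uses the in-silico
library alone; `expressed_only` additionally requires the k-mer
sequence (or its reverse complement) to occur among sequenced siRNAs.
Both modes are provided because published off-target gene counts do not
state which evidence rule produced them.

## Small-RNA profiling

Reads are collapsed to unique sequences (counts carried as weights),
length-filtered to 18–30 nt, and mapped **exactly** — zero gaps and
zero mismatches — to either construct strand, which guarantees that
everything profiled derives from the transgene rather than the host
genome. All occurrences are reported; multi-mapping reads are flagged
and counted once per occurrence in positional coverage but once per
read in the size distribution. Positions are first-base offsets on the
strand's own coordinates.

The 21 nt position frequency matrix uses count-weighted frequencies;
per-column information content is 2 − H bits with the plug-in Shannon
entropy and no small-sample correction (columns are probability
vectors; IC ∈ [0, 2]). GC fraction covers all bases of the reads used;
the 5′ A/U fraction averages the A/T share of positions 1–5 (a
correlate of guide-strand loading). A `min_count` parameter (default 1)
controls which collapsed reads enter the matrix, since "highly
enriched" thresholds vary between studies. The library abundance ratio
is a plain ratio of mapped totals with an optional pseudocount
((a+c)/(b+c)) for empty denominators.

## Differential calling

**Units and transforms.** Expression matrices are FPKM-like
(`fpkm = count × 10⁹ / (library_size × length)`); metabolite matrices
are peak intensities with missing cells (never imputed as zero).
Group tests run on log2(value + pseudocount): 1.0 for expression, half
the smallest positive intensity for metabolites.

**Test.** The default is a pooled-variance (Student) t on log2 values,
two-sided. With three replicates per group and a shared noise model,
pooling is the calibrated choice; Welch's t is available
(`mode="welch_log2"`) but its Satterthwaite degrees of freedom are
unstable at n = 3 and measurably conservative (null false-positive
rate ≈ 0.03 at a 0.05 level in simulation). Degenerate features
(fewer than two finite values in a group, or zero variance in both)
get p = 1.0 and a flag rather than an exception.

**Thresholds.** The two assay types use deliberately asymmetric rules:

- DEG: BH-adjusted p < 0.05 (adjustment across the comparison's full
  feature set) **and** fold change ≥ 2 or ≤ 0.5 — inclusive bounds.
- DAM: **raw** p < 0.05 and fold change strictly > 2.0; two-sided by
  default (also < 0.5), with a one-sided flag. VIP values can be
  attached for reporting but never enter the call.

Fold change is the ratio of group means; the pseudocount enters only
when a mean is zero. The metabolite missing-value filter removes a
feature when **any** line group has strictly more than 50% missing
replicates, and runs before calling and scaling.

The qPCR verification path uses the 2^−ΔΔCt relative-expression closed
form (which telescopes across calibrators) and the classical Student t
on raw values. Accurate-mass annotation matches when the ppm error is
strictly below the 25 ppm tolerance.

## Multivariate stages

Pareto scaling divides each centered feature by the square root of its
sample standard deviation — the metabolomics compromise between no
scaling and unit variance; zero-variance features are emitted as zeros
and flagged, and the stored means/scales make recomposition exact.
PCA is an SVD of the feature-centered sample matrix with a
deterministic sign rule (largest-magnitude loading positive);
explained-variance fractions sum to 1 when all components are kept.
Expression ordinations run on log2(FPKM+1); metabolite ordinations on
Pareto-scaled intensities with half-minimum imputation of missing
cells (the standard left-censoring assumption for peak areas).

Hierarchical clustering (scipy linkage; Euclidean or 1 − Pearson,
average or complete linkage) sorts items lexicographically before
computing merges so the dendrogram is invariant to input column order;
output includes a Newick rendering.

OPLS-DA is the Trygg–Wold orthogonal signal correction: up to
`n_orthogonal` class-orthogonal components (default 1) are deflated
from X before one predictive PLS component is fitted against a
centered ±1 class vector. VIP on the single predictive component
reduces to √p·|w| with w normalized, so mean(VIP²) = 1 holds exactly;
the zero-orthogonal special case reproduces a plain PLS-DA first
component, which the tests cross-check against an independent PLS
implementation. The number of orthogonal components and any
cross-validation are exposed as parameters, not asserted.

## Comparison design, set logic, enrichment

With roles {GE, parent, conventional}, all unordered line pairs are
enumerated and grouped: GE/parent → 1, conventional/parent **and**
conventional/conventional → 2, GE/GE → 3, GE/conventional → 4. Labels
order the GE line first and the parent last. The six-line reference
design yields 15 comparisons sized 3/3/3/6.

Venn decomposition supports 2–4 named sets and returns the full
disjoint region partition (regions sum to the union by construction).

Over-representation uses the upper-tail hypergeometric P(X ≥ ListHits)
on a flat term→members annotation, BH-adjusted across terms within one
comparison. The universe is the annotated-and-assayed intersection —
published tables with PopTotal far below the full gene count imply an
annotated-subset background — and is configurable. The fold-enrichment
score (ListHits/ListTotal)/(PopHits/PopTotal) is reported at 4 decimals
alongside a full-precision column; ES > 1 iff the list hit rate exceeds
the population hit rate. Published p-value columns in such tables are
often not reproducible from the printed margins (platform-specific
universes); only the internally consistent score arithmetic is
asserted.

## Synthetic data: what it emulates and what it does not

The generators emulate, at reduced scale, a six-line × three-replicate
equivalence study around an 876 nt construct:

- `gen_dsrna` — i.i.d. bases at a target GC fraction. Real constructs
  have codon structure and the inverted repeat itself; neither matters
  for window enumeration or Hamming matching.
- `gen_transcriptome` — random transcripts with planted construct
  windows carrying an exact number of substitutions; the applied
  distance is re-verified against the emitted sequence. Note a planted
  distance-3 site can legitimately be hit at ≤2 mismatches by a
  *neighboring* construct window; truth checks therefore key on the
  planted (transcript, position, source window) identity.
- `gen_srna_reads` — exact substrings of either strand with first-base
  positions from a hotspot distribution and lengths from a weight table
  (default 70% mass at 21 nt, the Dicer signature), plus optional random
  background. No sequencing errors, adapters, or quality decay are
  simulated — the pipeline stages they would exercise (trimming,
  base-call QC) are out of scope.
- `gen_expression_study` / `gen_metabolome_study` — log-normal
  intensities: log2 value = baseline + effect + N(0, σ). Defaults:
  baseline log2 ∈ U(3,10) (FPKM-like) or U(10,20) (peak areas),
  σ = 0.25 (≈18% CV, tight glasshouse replicates; replicate dispersion
  is rarely reported for such studies, so it is an exposed parameter),
  and a
  genetic-background split — 10% of features shifted by |log2FC| = 3 in
  the conventional lines — which is what makes ordination and
  clustering separate conventional lines from GE lines plus parent,
  and group-2/4 comparisons call many more features than group 1.
  A negative-binomial count option exists for users who want
  integer-valued expression. Metabolite missingness is MCAR at a given
  rate; real missingness is partly intensity-dependent, so the
  missing-value filter is exercised but not its interaction with
  censoring.
- `gen_annotation` — random flat terms plus one term over-drawn in a
  designated feature list by a stated factor, guaranteeing a planted
  enrichment signal.

Passing tests on these inputs demonstrate the *machinery* — exact
recovery of planted signals, calibrated error rates, oracle-identical
scanning — not the biological conclusions of any real dataset, which
depend on deposited reads and a proprietary construct sequence.

## Calibration conditions and problem sizes

The statistical calibration checks use 1,000 features, 6 lines × 3
replicates, and σ = 0.15 ("low dispersion", ≈11% CV), fixed by a
design-time power analysis: under the pooled t with BH over 1,000
features, an 8-fold (|log2FC| = 3) planted effect is then essentially
always detectable, so the ≥95% recovery check verifies the caller's
correctness rather than its power at a marginal signal-to-noise ratio.
The null check asserts the raw-p false-positive fraction lies within 3
binomial standard deviations of the 5% level. Scanner/oracle
equivalence runs on 102 randomized instances (5 transcripts of 25–90 nt
against 50 nt constructs, budgets 0–2) plus planted-site recovery on
the full 876 nt construct; the end-to-end pipeline default runs 40
transcripts, 4,000 reads, 600 genes, and 300 metabolites. All stages
derive their randomness from a single user seed.

## Known limitations

- No thermodynamic or seed-region siRNA efficacy scoring; a Hamming
  match flags a *candidate* off-target only.
- Terms are flat sets: no GO graph topology or term relationships.
- The OPLS implementation targets two-class discrimination with one
  predictive component; multi-class designs are out of scope.
- Fold-change pseudocount handling makes calls near zero means depend
  on the pseudocount convention (documented above).
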