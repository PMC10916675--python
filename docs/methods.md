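# Methods

This note documents the models implemented in `epidiet`, their assumptions,
the defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that affect results.

## Coordinate and data model

All coordinates are 0-based half-open (BED convention); gene tables use the
same convention in a documented TSV dialect (gene id, chromosome, strand,
transcript span, comma-separated exon blocks). The TSS is `tx_start` on the
`+` strand and `tx_end` on the `-` strand. Promoter windows default to
±2 kb around the TSS, strand-aware and silently clipped at chromosome ends.
Genome bins tile each chromosome at 200 bp; the final, possibly shorter bin
is kept so that bins always partition the genome (conservation invariants
are then exact).

Peak-to-feature-class assignment (promoter / exon / intron / intergenic)
uses the peak **midpoint** with precedence promoter > exon > intron. Midpoint
assignment makes the classes mutually exclusive and deterministic; an
any-overlap rule with the same precedence would shift a few percent of
boundary peaks toward the promoter class but not the qualitative ranking.

## Binarization

Per mark, a bin is called occupied when its read count reaches the smallest
integer c\* with P(Poisson(λ) ≥ c\*) ≤ α, where λ defaults to the mark's
genome-wide mean count per bin and α = 1e-4. This is the standard
Poisson-background binarization for chromatin-state modelling; both λ and α
are configurable. At λ = 1, α = 1e-4 the threshold is 7 reads.

## Chromatin-state model

The segmentation model is a hidden Markov chain over bins with independent
Bernoulli emissions per mark: state k emits mark m with probability B[k, m].
Chromosomes are independent sequences; there is no wrap-around. Fitting is
Baum–Welch EM with:

- 5 random restarts from Dirichlet/uniform initializations (self-loop-heavy
  starting transitions), keeping the highest-likelihood fit;
- max 500 iterations, stopping at relative log-likelihood improvement
  ≤ 1e-6;
- parameter floors of 1e-6 on emissions, transitions and the initial law so
  no state becomes absorbing and no emission becomes deterministic (the
  K = 1 closed form is consequently exact only to the floor, which is far
  below test tolerances).

The per-iteration log-likelihood is non-decreasing (EM guarantee; asserted
in tests at 1e-8 relative tolerance). The forward–backward and Viterbi
recursions are numba-compiled; the scaled probability-domain recursion is
used, which is stable down to per-bin emission likelihoods of ~1e-30.

State labels are assigned deterministically after fitting: states are sorted
by descending summed emission probability of H3K4me3 + H3K27ac (falling back
to total emission when those marks are absent), ties broken by descending
genome coverage. S1 is therefore always the most active-promoter-like state
and the quiescent states sort last; with a fixed seed, refits are
bit-identical. Decoding defaults to posterior marginals because every
downstream statistic (genome %, TSS-neighborhood enrichment, state-by-
annotation folds) is a per-bin posterior-mass question; Viterbi is available
when a single most-probable path is wanted. Posterior ties break toward the
lower state index.

Model selection over K is out of scope; K defaults to 6.

### State statistics

- Genome % is base-weighted (remainder bins count their true length) and
  sums to 100 exactly.
- TSS-neighborhood enrichment uses 20 offset bins over [−2 kb, +2 kb),
  oriented along transcription; each offset bin is represented by its
  midpoint's genome bin. fold = P(state | offset) / P(state genome-wide).
- Annotation overlap enrichment merges each annotation before measuring;
  an annotation covering zero bases reports NaN.
- The methylation-by-state statistic takes the contiguous same-state segment
  as the unit of observation: per segment, the fraction of bases covered by
  the merged methylation peaks; a segment is "overlapped" when that fraction
  is positive. Boxplot summaries use median, quartiles and whiskers at
  1.5× the interquartile range.

## Exact differential count test

The study design pools animals into one library per condition, so replicate
dispersion cannot be estimated; the test is therefore conditional and uses a
common dispersion φ supplied by configuration (default 0.05 for realistic
data, 0 for analytic nulls).

Counts are first rescaled to the geometric-mean library size by proportional
rescaling with round-half-even — a deterministic approximation to
quantile adjustment that is exact in expectation and reproducible. Given the
rescaled sum n:

- φ = 0: the split follows Binomial(n, ½);
- φ > 0: the conditional law is obtained by enumerating joint
  negative-binomial probabilities over all splits of n. Because both counts
  share mean and dispersion, this law is free of the mean and equals a
  symmetric beta-binomial with shape 1/φ — which is what the test oracle
  uses as an independent closed form.

The two-sided p-value is the total conditional probability of all splits no
more probable than the observed one (ties included at 1e-12 relative
tolerance); (0, 0) gives p = 1 by convention. Discreteness makes the test
conservative: under a Poisson null the fraction of raw p < 0.05 is ≈ 0.04.

log2 fold changes are computed on library-normalized counts with a
pseudocount scaled to the common library, making the value antisymmetric
under condition swaps. Multiple-testing adjustment offers Bonferroni (the
ChIP/MeDIP default in this design) and BH (used for gene-set and snATAC
results). Calls threshold the **raw** p-value by default, matching the
enrichment-analysis convention of this design; adjusted-p thresholding is a
flag.

## Integration logic

- **Imputed up**: gene gained both H3K4me3 and H3K27ac and neither H3K9me3
  nor H3K27me3. **Imputed down**: gene gained no activating mark and gained
  a suppressive mark; whether one suppressive mark suffices ("or", the
  default) or both are required ("and") is a switch. Up and down sets are
  provably disjoint under either reading.
- **Trend profiles**: for the ordered log2FC triple across the three HFD
  durations, each adjacent difference is classed up (≥ 1), down (≤ −1) or
  flat; the pair of classes maps to codes p1…p9 lexicographically with
  up < flat < down, so p1 is the monotone less-to-more trajectory. The
  classifier is scale-equivariant (scaling values and threshold together
  preserves codes) and the profile space is exactly nine.
- **Concordance**: RNA-up genes are intersected with genes gaining all of
  H3K4me3, H3K27ac and H3K36me3 and neither suppressive mark; RNA-down genes
  with the exact mirror (both suppressive marks gained, none of the three
  active). The mirror is the natural reading of the "reversed pattern" and
  is the stricter of the plausible variants; edge weights in the Sankey
  table are gene counts per (RNA direction, mark) pair.
- **Gene-set enrichment** is the upper-tail hypergeometric probability
  P(X ≥ k) with BH adjustment across terms; terms are intersected with the
  universe first, and the universe defaults to all annotated genes.

## snATAC layer

Fragment records are shifted +4 (start) / −5 (end) on loading to place both
ends on transposase cut sites; records that collapse to non-positive length
are dropped and counted. QC keeps a cell iff fragments-in-peaks ≥ 200 and
≤ the 95th percentile of the input distribution, nucleosome signal ≤ 4 and
TSS enrichment ≥ 2; the percentile cap is computed once on the input table,
so the filter is idempotent. Gene activity counts fragments over the gene
body extended 2 kb upstream of the TSS, then depth-normalizes each cell to
the median total and applies log1p. (The alternative promoter-proximal
peak-to-gene linking window — 1 kb upstream / 100 bp downstream of the TSS —
can be emulated by passing the corresponding windows, but gene-body + 2 kb
is the default activity definition.) TF-IDF/LSI computes
log(1 + 10⁴·TF·IDF) on the top 25% most accessible features and takes a
truncated SVD (30 components; deterministic sign convention); the first
component is dropped when its correlation with cell depth exceeds 0.9 in
magnitude, since it then tracks sequencing depth. Composition change is the
relative change of per-condition percentage shares; a type absent from the
baseline reports NaN. Differential activity is a per-gene two-sided
rank-sum (Mann–Whitney) test within a cell type, BH-adjusted, with direction
from the sign of the median difference; constant genes get p = 1 by
convention. Clustering, UMAP and doublet removal are intentionally out of
scope — cell-type labels come from the truth sidecar or a user label table.

## Synthetic-data generator

The generator emulates the *structure* of the study's data, not its physics:

- a 2-chromosome × 200-kb toy genome with 60 evenly spaced genes
  (non-overlapping promoters, strands 50/50, TSSs aligned to bins);
- a 6-state hidden path at 200-bp bins whose default emissions encode the
  canonical state semantics (active TSS, flanking/enhancer, bivalent,
  repressed, two quiescent states) with self-loop-heavy transitions that put
  roughly three quarters of the genome in the quiescent states;
- promoter/gene-body counts at mean depth 50 with shared negative-binomial
  dispersion φ = 0.05 (Poisson at φ = 0), and 20% of genes planted with a
  +3 log2FC on H3K4me3 and H3K27ac in the HFD conditions; reads are
  fixed-length intervals placed uniformly inside their feature window, plus
  ~20,000 uniformly placed background reads per library so that library
  sizes reflect a realistic background fraction (the planted signal still
  shifts the library composition by ≈ 0.2 in log2 units, which the tests
  absorb);
- methylation peaks of fixed 400-bp width centered on bins sampled
  proportionally to per-state affinity weights (defaulting to high affinity
  for the marked states and low for the quiescent ones);
- an snATAC layer with 2,000 cells per condition whose type labels follow
  the reported hypothalamic composition under chow and its reported relative
  shifts under HFD (renormalized), lognormal fragments-in-peaks, gamma
  nucleosome-signal and TSS-enrichment covariates drawn directly (the QC
  filter, not covariate physics, is the testable content), and fragments
  placed in extended gene bodies with a 5× boost on each type's marker gene.

Everything is deterministic under the configured seed (per-generator
sub-streams of one seed sequence), and every generator emits a truth sidecar
consumed by recovery tests. What passing tests therefore show is that the
algorithms recover planted structure under the stated noise model; they do
not validate read-level artifacts (GC, duplication, doublets, peak-calling
errors) that real libraries contain.

## Problem sizes and tolerances

Simulation-based checks use 50,000 bins for HMM parameter recovery
(emissions and transitions within ±0.05, decoding ≥ 95%), 10,000 features
for null calibration (raw p < 0.05 in ≤ 6% of features), 2,000 intervals per
set for the interval-join oracle (exact agreement), totals n ≤ 200 for the
exact-test enumeration oracle (agreement to 1e-10), N ≤ 50 for the
hypergeometric oracle, and five seeds for the uniform-affinity
Kruskal–Wallis null (mean p well above 0.01; the null design uses equal
dwell times across states so segment-length distributions match). These
sizes were chosen so that Monte-Carlo tolerances are sharp while the whole
suite runs in well under a minute per check.

## Known limitations

- The conditional test assumes a *common* known dispersion; replicate-based
  (trended/tagwise) estimation is out of scope by design.
- Library normalization is proportional rescaling only; composition-aware
  normalization (e.g. trimmed means) is not implemented, so strongly
  asymmetric planted signal shifts null log2FCs slightly.
- The TSS-neighborhood statistic represents each offset bin by its midpoint;
  TSSs not aligned to bin boundaries blur adjacent offsets by up to one bin.
- The beta-binomial equivalence used by the oracle holds only for equal
  means after rescaling; the implementation's negative-binomial enumeration
  is the general route.
- The snATAC layer tests QC, normalization math, composition and rank-sum
  calls; it does not attempt clustering or label transfer.
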