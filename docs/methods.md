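# Methods

## Model

`driverrank` scores genes in one tumor sample by network propagation
of differential expression. The network is a directed graph over gene
symbols with 0-1 adjacency *A* (*A<sub>ij</sub>* = 1: gene *i*
regulates gene *j*; self-loops allowed, duplicate edges collapsed).
The prior *f<sub>j</sub>* is the absolute difference between log-scale
tumor and normal expression of gene *j*; it is nonnegative by
construction. The recursion

  r<sup>t+1</sup> = (I − D) f + D M r<sup>t</sup>

uses the column-normalized transition matrix
M<sub>j,i</sub> = A<sub>j,i</sub>/deg<sub>i</sub> (deg<sub>i</sub> =
in-degree of *i*; columns of dangling genes, deg = 0, are all zero)
and the diagonal damping matrix D with d<sub>i</sub> =
deg<sub>i</sub>/(deg<sub>i</sub> + μ). Under this orientation a
gene's score accumulates the scores of its downstream targets, each
divided by the target's in-degree — the "impact on downstream
differential expression" reading — while the damping is driven by the
gene's own in-degree exactly as the recursion is written. A
`transpose` flag reverses the edge orientation for users who prefer
out-degree-driven damping; the literal orientation is the default.

All damping factors are < 1, so the affine map is a contraction and
the fixed point r = (I − DM)<sup>−1</sup>(I − D) f is unique. Two
independent routes compute it:

* `rank_genes` — power iteration from r₀ = f;
* `rank_genes_direct` — a sparse LU solve of the linear system.

Their agreement (within 10× the iteration tolerance, ∞-norm) is
asserted in the tests; neither path is derived from the other.

### Convergence and the scale of ε

Iteration stops when ‖r<sup>t+1</sup> − r<sup>t</sup>‖₂ < ε (default
ε = 10⁻³; L1/L∞ selectable). The tolerance is inherited from the
PageRank literature, where the rank vector is a probability
distribution; an absolute tolerance is only meaningful on that scale.
`rank_genes` therefore iterates on the unit-mass prior f/‖f‖₁ and
multiplies the converged scores by ‖f‖₁ afterwards — exact, because
the fixed point is linear in f. This makes both the iteration count
and the percentile output invariant to rescaling the expression data,
and on networks shaped like curated pathway collections (see the
generator below) the recursion converges in well under 20 iterations
for any μ between 0.01 and 20. Genuinely degenerate damping (the
validated range for μ is [10⁻⁶, 10⁶]) is rejected at the API.

Scores are converted to percentile ranks, 100 · (average fractional
rank)/N ∈ (0, 100], over **all** N genes of the patient (scores exist
for unmutated genes too). Percentiles are the only quantity consumed
downstream, so the raw-score scale is irrelevant.

### Parameters

| parameter | default | meaning |
|---|---|---|
| μ | 3 | damping half-saturation: a gene with in-degree μ has d = 0.5; larger μ shifts weight from network structure to the gene's own differential expression |
| ε | 0.001 | convergence tolerance on the unit-mass update norm |
| max_iter | 100 | iteration cap; non-convergence is flagged, never silent |
| δ | 0.85 | Condorcet penalty multiplying the percentile of a non-altered gene in a pairwise contest |
| top_n | 30 | aggregate-rank window for novel-driver calling |
| min_freq / rare_threshold | 0.02 | recurrence thresholds: novel drivers are altered in > 2 % of patients, rare drivers in < 2 % |
| fold_threshold | 2.0 | minimum CNV fold change (|log₂ ratio| ≥ 1) |

## Condorcet aggregation

Candidates are the genes altered in at least one patient. For a pair
(A, B), eligible voters are the patients with an alteration in A or B;
within an eligible patient each gene's percentile is multiplied by δ
if the gene is not altered there, and A takes the patient iff its
penalized score is strictly greater — exact ties go to B, following
the "otherwise" branch of the pairwise rule as printed. Pairs with no
eligible patients contribute no wins. The pairwise relation is
completed into a total order by Copeland score (number of contests
won), tie-broken by summed win margin and then lexicographically; the
output is deterministic and invariant to patient and candidate
ordering. Schulze/Kemeny completions are out of scope.

## Driver calling

**Maximally selected rank statistic.** The phrase "cutoff maximizing
the number of known drivers above it" is degenerate read literally (a
cutoff of 0 maximizes any count), so the cutoff is the standard
maximally selected two-sample statistic: candidate cutoffs are the
observed percentile values within the central 10th–90th quantile span,
each scored by the continuity-uncorrected 2×2 chi-square of
(above/below cutoff) × (gold/non-gold), and the smallest maximizer is
returned. A flat statistic is flagged low-confidence. The cutoff is
computed per patient (an explicit cutoff can be supplied instead).

**Chauvenet outlier rule.** A patient's rank of a gene is
significantly high iff n · P(Z > z) < 0.5, one-sided, where z
standardizes the value against the gene's percentile ranks across all
cohort patients (sample mean and sd, ddof = 1). Fewer than three
cohort values or zero spread yields an explicit "not callable" result,
never a silent false.

A personalized driver must be altered in the patient and pass both
hurdles independently; it is tagged rare below the 2 % cohort
frequency. Novel drivers (cohort level) must rank in the aggregate
top 30, be altered in strictly more than 2 % of patients, and be
absent from the gold standard. CNV events require |log₂ ratio| ≥ 1
and, by default, a sign-concordant signed expression difference
(amplification ↔ up, deletion ↔ down); the expression-magnitude
threshold defaults to "any nonzero concordant change" since no value
is prescribed, and is configurable.

## Evaluation utilities

Top-N precision is |top-N ∩ gold|/N; recall divides by the number of
distinct gold genes altered anywhere in the cohort (stated explicitly
because the printed formula leaves the denominator's scope ambiguous);
F1 is the harmonic mean with the 0/0 → 0 convention. The
subsampling experiment draws random patient subsets without
replacement and re-aggregates; per-patient rankings are computed once
for the full cohort and reused, which is exact because a patient's
ranking does not depend on the rest of the cohort. Tuners grid-search
μ (score: mean percentile of altered gold genes over sampled patients)
and δ (score: aggregate top-N precision), breaking ties toward the
smaller parameter for reproducibility; when the requested 100 samples
exceed the cohort, the whole cohort is used. The rare-driver
distribution uses non-cumulative half-open frequency bins
[0, 1 %), [1 %, 2 %), …, counts patients (not calls) per bin, and
compares subgroup pairs with an uncorrected chi-square on the binned
counts — bins empty in both groups are dropped.

## Synthetic data

The generator emulates the statistical structure the method assumes,
not any real dataset's marginals:

* **Network.** Heavy-tailed out-degree (a 10 % hub fraction emits
  edges at 6× the base rate; the base rate is set so the mean
  out-degree matches its target), heavy-tailed in-degree (lognormal
  target propensities, σ = 2), and hierarchy: each gene has a uniform
  hierarchy position and all but a 5 % feedback fraction of its edges
  point strictly downward. This reproduces three features of curated
  pathway aggregates: hub regulators, a sizable fraction (~15–25 %)
  of genes with no incoming edges, and predominantly feed-forward
  signal flow with sparse feedback. Feedback edges and self-loops
  attach only to genes that already have a feed-forward regulator —
  in curated networks feedback acts on pathway-internal, regulated
  components, and without this rule random wiring occasionally creates
  isolated feedback islands (e.g. two genes regulated only by each
  other) whose round-trip gain approaches 1 as μ → 0, trapping the
  recursion in modes real networks do not exhibit.
* **Cohort.** The normal reference is a log-scale baseline
  ~ Normal(8, 2) floored at 0, drawn once per cohort. Per patient,
  drivers are sampled with probability ∝ 1 + out-degree (drivers tend
  to be hubs) and perturb their breadth-first downstream cone:
  expression at depth k ≤ 3 shifts by ±signal·decay^k (one random
  sign per driver event; defaults signal = 5, decay = 0.5).
  Passengers are sampled uniformly and inject nothing. Gaussian noise
  (sd = 1) is added everywhere, giving the default signal-to-noise of
  5 at the driver itself.

What passing tests on this generator do **not** show: performance on
real tumor data, where networks are incomplete and biased, expression
changes are not additive cascades, and alteration calls carry their
own error. One consequence worth noting: because drivers are sampled
hub-biased and the propagation model deliberately favors connected
genes, planted drivers outrank passengers slightly even at zero
signal — the generator's null guarantee is about injected expression,
not about rank.

Default problem sizes in the tests and the acceptance script
(networks of up to 500 genes, cohorts of up to 50 patients, 10–20
replicate seeds) were chosen so the whole suite runs on a laptop in a
couple of minutes while keeping every estimate comfortably away from
its acceptance margin.

## Known limitations

* Edges are unweighted; weighted propagation and heat-diffusion
  variants are out of scope.
* Gene symbols are opaque, case-sensitive strings; alias resolution is
  upstream curation.
* The maxstat interpretation (2×2 chi-square over central candidate
  cutoffs) is one defensible reading of an underspecified procedure;
  it is isolated behind `maxstat_cutoff` and an explicit `cutoff`
  override is accepted everywhere.
* Whether self-loops count toward the damping in-degree is not
  prescribed; they are counted here, and excluding them is possible by
  removing self-loops from the network before ranking.
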