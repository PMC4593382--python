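# Methods

## The subsampling model

A sequencing run at depth m < N is modelled as a uniform draw of m
fragments without replacement from the N aligned fragments of the original
run — an m-out-of-n bootstrap on the alignment file. The sampling unit is
the **fragment** (read name): all alignment records sharing a name,
including the mate of a paired read or an unmapped mate, travel together.
The draw size is round(f·N) with round-half-even, which is unbiased across
the depth grid; an explicit floor would bias every subsample slightly
shallow. f = 1.0 performs a degenerate draw-all rather than skipping, so R
identical replicates exist at full depth and the bookkeeping
(|depth grid| × R files per sample) is uniform.

Selection is a pure function of (fragment *set*, fraction, seed): fragment
ids are sorted before the RNG draws, so reordering the input file cannot
change which fragments are selected. Replicate r at any depth uses seed
`base_seed + r`, and the manifest records (sample, fraction, replicate,
seed, path, fragment count) so any replicate can be regenerated from its
row alone.

Under this model the count of a gene with c reads in a subsample at
fraction f is hypergeometric with mean f·c — the law the test suite and the
acceptance run verify by Monte Carlo. Direct scaling of a count matrix by f
preserves totals exactly (Σ f·c_ij / Σ c_ij = f) but has no sampling
variability and cannot push a gene across a detection threshold
stochastically; the expressed-gene comparison quantifies exactly this
failure. Note the regime where the two visibly diverge at θ = 1: genes with
counts just above θ/f are kept deterministically by scaling but lost by
real subsampling with probability (1−f)^c. Genes *below* θ/f are lost by
both (a scaled singleton at f = 0.1 is 0.1 < 1), so a fixture meant to
exhibit the divergence must concentrate counts a little above θ/f, which is
how the synthetic sample used in the tests and the acceptance run is built.

## Counting and normalization

The counter is a minimal featureCounts-style summarizer: one increment per
fragment, assigned to the single gene whose exon union its aligned blocks
overlap by ≥ `min_overlap` bases (default 1). Gapped alignments contribute
their CIGAR blocks, not the whole reference span, so spliced reads do not
hit intronic genes. Fragments overlapping two or more genes follow the
ambiguity policy (`discard` by default, `count_all` optionally); secondary
and supplementary alignments are skipped; counting is unstranded by default
because the protocol's strandedness is not assumed. Annotations are kept
1-based inclusive (GTF convention) internally and converted to 0-based
half-open only at the SAM arithmetic boundary, so both formats round-trip
bit-exactly. Exons of a gene are merged by interval union, so overlapping
exon records are not double-counted in the RPKM length L_i.

CPM and RPKM are computed exactly as defined (N_i·10⁶/N_lib and
N_i·10⁶/(N_lib·L_i)); the CPM vector sums to 10⁶, hence its mean over the
full G-gene annotation is 10⁶/G at any depth — used as a built-in
self-check (≈ 42.29 for G = 23,648).

## Gompertz fitting and depth estimators

Saturation curves (expressed-gene count vs depth) are fitted with
f(x) = a·exp(−b·exp(−c·x)) by nonlinear least squares over **all**
replicate points pooled (not their medians), so replicate scatter enters
the asymptotic standard errors taken from the covariance of the fit.
x is the depth fraction by default; an absolute-reads scale is available
(the fitted rate then divides by the library size). Initialisation:
a₀ = 1.05·max(y); b₀ by inverting the curve at the smallest x;
c₀ ∈ {0.5, 1, 2, 4, 8}/max(x) as a multi-start ladder, keeping the
lowest-RSS solution; all three parameters are bounded positive. A fit that
never converges is returned flagged rather than raising, and constant
curves collapse to a ≈ the constant rather than crashing.

A sample counts as *saturated* when the fitted curve's relative slope at
full depth, (df/dx)/a at x = 1, is below `saturation_tolerance`
(default 10⁻³ per unit f — a detector default, reported in the output, not
a scientific constant). If no sample saturates, Estimator I (mean library
size) and Estimator II (maximum library size) are reported as lower bounds
on the depth required; with the published read totals of the eight-sample
breast-cancer cohort (`desire.studydata`) these evaluate to 32,245,737 and
46,677,107 reads.

## Moments and group tests

Distribution moments are taken across genes within one sample: unbiased
variance (n−1), skewness m₃/m₂^{3/2} and **plain** kurtosis m₄/m₂² with
1/n central moments. Plain rather than excess kurtosis is deliberate: the
quantity is reported as a distribution descriptor, not a normality
deviation, and the choice is documented so tables are interpretable. On
constant input the shape moments are undefined and reported as an explicit
`None` sentinel. By default moments run over the full annotation vector
(zeros included), which keeps the CPM mean identity exact; a θ-filtered
variant (threshold applied to *raw* counts before the normalized values
are selected) is available.

Group comparisons use two-sample t-tests reporting two-sided, left-sided
(A < B) and right-sided p-values. Welch's unequal-variance test is the
default for real comparisons; Student's pooled test is available and is
what the calibration simulation uses, because under an equal-variance
normal null it is exactly calibrated whereas Welch is measurably
conservative at n = 4 per group. Expressed-gene tests take the median over
R replicates per sample per depth, then test group means of those medians
per depth. Moment tests pool the per-depth medians across the depth grid
(a 9-depth grid gives n = 9 per condition). No multiple-testing correction
is applied across depths or moments; the tables report raw p-values.

## The synthetic-data generator

The generator emulates the *structure* of the cohort's bulk RNA-seq
samples: a handful of chromosomes with non-overlapping 1–3-exon genes,
log-normal spread of expected expression across genes (default
lognormal(1, 1.5)), negative-binomial count noise (default dispersion
α = 0.2 in Var = μ + αμ²), a noise fraction of reads in intergenic space
(default 5%), and fixed-length single-end reads (75 bp) placed uniformly
within exon unions. Counts are produced by modulating the expression
profile with per-gene Gamma(1/α, α) factors and drawing a multinomial
conditioned on the configured library size — marginally negative-binomial
overdispersion with an exact total, so a subsample at f has exactly
round(f·N) fragments. Gene gaps exceed the read length, so at zero noise
the counter recovers the simulator's true counts **exactly**; this
end-to-end identity is the generator's key test.

The two-group cohort shares one expression profile; the second group's
profile is shrunk affinely toward its mean so its across-gene variance is
multiplied by `group_effect` (exactly, mean preserved) — a disease state
that narrows the expression distribution without moving its CPM mean,
which is the signal the moment comparison is built to detect.

What the generator does **not** emulate: sequencing errors and quality
scores, splicing junctions and isoform structure, GC/length biases,
multi-mapping ambiguity, and genome-scale library sizes. Passing tests
therefore demonstrate the correctness of the subsampling, counting and
inference machinery under the stated sampling model, not robustness to
alignment artefacts of real data.

## Problem sizes

Simulated studies use genomes of tens-to-hundreds of genes and libraries
of 10³–10⁴ fragments; these sizes were chosen once as the package's test
conditions. Monte-Carlo checks use 200 subsampling replicates, 100
noisy-curve fits and 2,000 null t-tests; empirical rates at those sizes
are judged against 3σ binomial error. The analytic identities (CPM mean,
scaling ratio, library-size arithmetic) are size-independent and checked
at the real annotation size G = 23,648.

## Known limitations

- Fragment assignment uses the exon-union overlap of pooled per-fragment
  blocks; exon-level or junction-aware counting is out of scope.
- The Gompertz family is the only growth model offered (the logistic would
  be a drop-in alternative but is not implemented).
- Subsampling reads the source file once per replicate; for very large
  BAMs an index-aware streaming design would be preferable.
- The saturation detector is a heuristic on the fitted slope; curves fitted
  on few depths can flag spuriously in either direction.
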