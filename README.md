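# desire-rnaseq

Subsampling of aligned RNA-seq reads to simulate sequencing experiments at
reduced depth, with the downstream analysis that depends on it: gene-level
counting, CPM/RPKM normalization, expressed-gene saturation curves with
Gompertz growth fits, optimal-sequencing-depth estimation, and comparison of
expression-distribution moments between phenotype groups.

## Who this is for

Designers of bulk (or single-cell) RNA-seq experiments who need to answer
"how many reads are enough?" from pilot data, and analysts who want
statistically honest surrogates of lower-depth sequencing runs. The naive
shortcut — multiplying a count matrix by a fraction *f* — preserves total
counts exactly but is not what a shallower sequencing run produces; this
package implements the faithful alternative and quantifies the difference.

## The method

**DESIRE** (depth-of-sequencing iterative reduction) is an *m*-out-of-*n*
bootstrap on the alignment file: from a sample's N aligned fragments, draw
round(f·N) fragments uniformly **without replacement**, R times per depth
fraction f ∈ {0.1, …, 0.9, 1.0} (defaults R = 24, i.e. 240 surrogate
datasets per sample). Each draw is written as a new SAM/BAM that behaves
like a real sequencing run at depth f·N — crucially, f refers to the whole
library, not to each gene, so per-gene subsample counts are hypergeometric
with mean f·c.

Downstream, for gene i with count N_i, library size N_lib = Σ_i N_i and
exon-union length L_i (kb):

- CPM: c_i = N_i · 10⁶ / N_lib  (so the CPM mean over all G genes is
  pinned at 10⁶/G regardless of depth)
- RPKM: c_i = N_i · 10⁶ / (N_lib · L_i)
- expressed gene at threshold θ: raw count c_ij ≥ θ, θ ∈ {1, 10, 50, 100}
- saturation curve: expressed-gene count vs f, fitted with the Gompertz
  growth function f(x) = a·exp(−b·exp(−c·x)), where c is the growth rate
- optimal depth: if no fitted curve has flattened at full depth
  ((df/dx)/a above tolerance at x = 1), the mean and the maximum library
  size are **lower bounds** on the depth needed for saturation
  (Estimators I and II)
- distributional shape: mean, variance, skewness m₃/m₂^{3/2} and plain
  kurtosis m₄/m₂² of the expression distribution across genes within a
  sample, compared between groups by two-sample t-tests (two-, left- and
  right-sided)

A synthetic-data generator (annotation + negative-binomial expression +
pre-aligned single-end reads with known true counts) makes the whole
pipeline runnable and testable without downloads.

## Worked example

```python
from pathlib import Path
from desire import (SimulationConfig, simulate_cohort, SubsampleSpec,
                    generate_replicates)
from desire.subsample import Manifest
from desire.counting import count_fragments
from desire.normalize import cpm
from desire.moments import distribution_moments, compare_moments
from desire.saturation import build_saturation_curves, fit_gompertz

out = Path("example")
cfg = SimulationConfig(n_genes=120, library_size=8000, group_effect=0.5, seed=1)
cohort = simulate_cohort(cfg, n_per_group=3, out_dir=out)

spec = SubsampleSpec(depth_grid=(0.1, 0.3, 0.5, 0.7, 0.9, 1.0),
                     replicates=8, base_seed=1)
manifest = Manifest()
for s in cohort.samples:
    manifest.records.extend(generate_replicates(s.path, spec, out / "reps").records)

curves = build_saturation_curves(manifest, cohort.annotation, (1, 10), "desire")
fit = fit_gompertz([c for c in curves
                    if c.sample_id == "groupA_s1" and c.theta == 1][0])
print(fit.summary().round(3))
```

prints the fitted Gompertz parameters with their asymptotic standard
errors for that sample's θ = 1 saturation curve:

```
                  estimate  std_error
a (asymptote)      118.536      0.391
b (displacement)     0.487      0.022
c (growth rate)      6.032      0.388
```

(118.5 of the 120 simulated genes are reachable at saturation; the rate
c ≈ 6 means the curve has essentially plateaued well before full depth at
this small simulated library.) Comparing the CPM distribution moments
between the two groups — group B was simulated with half the across-gene
expression variance of group A —

```python
summaries = []
for rec in manifest.records:
    cv = count_fragments(rec.path, cohort.annotation, sample_id=rec.sample)
    summaries.append(distribution_moments(cpm(cv), fraction=rec.fraction,
                                          replicate=rec.replicate,
                                          sample_id=rec.sample))
labels = cohort.labels
print(compare_moments([m for m in summaries if labels[m.sample_id] == "groupA"],
                      [m for m in summaries if labels[m.sample_id] == "groupB"]))
```

```
     moment  p_two_sided  p_left_sided  p_right_sided
0      mean    1.000e+00     1.000e+00      1.000e+00
1  variance    1.122e-10     1.000e+00      5.612e-11
2  skewness    5.294e-10     1.000e+00      2.647e-10
3  kurtosis    5.704e-09     1.000e+00      2.852e-09
```

The mean is uninformative by construction (CPM pins it at 10⁶/G ≈ 42.29
over the full annotation), while the higher moments detect the group
difference decisively, with the right-sided tests (group A > group B)
carrying the signal — the motivation for moment-based signal detection
when no feature selection is applied.

The same pipeline is available from the shell:

```
desire simulate  --n-genes 120 --library-size 8000 --out-dir example
desire subsample example/groupA_s1.sam --out-dir example/reps -R 24
desire count     example/*.sam --annotation example/annotation.gtf --out counts.tsv
desire analyze   --manifest example/reps/manifest.tsv \
                 --annotation example/annotation.gtf --out-dir example/report
```

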