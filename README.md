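# coitad

TAD calling from Hi-C contact matrices with multi-radius "circle of
influence" features and hierarchical density-based clustering.

## The problem

Topologically associating domains (TADs) are contiguous genomic regions
whose loci contact each other far more often than they contact neighboring
regions; on a Hi-C contact matrix they appear as dense squares along the
diagonal. This package locates those squares on a single-chromosome matrix
and is aimed at anyone analyzing chromatin architecture who needs domain
calls from a plain-text contact map, plus the tooling to benchmark a caller:
a planted-domain Hi-C simulator and a Measure-of-Concordance evaluator.

## The method

For every diagonal bin *i* and radius *r*, the **circle of influence** is
the neighborhood of matrix cells within *r* of cell (i, i), flattened into a
feature vector (the *semi-circle* variant keeps only the half on or above
the diagonal, since the matrix is symmetric). Radii run from 2 up to

    max radius = (max TAD size) / resolution        (default 800 kb)

For each radius the per-bin vectors are clustered with **HDBSCAN** under the
Euclidean metric; consecutive bins with the same cluster label are merged
into segments, and each segment is classified as a **gap** (zero contact),
a **TAD** (length ≥ ceil(180 kb / resolution) bins), or a **boundary**
region (shorter). Each radius's call is scored by the mean, over its TADs,
of

    quality(TAD_i) = intra(i) − inter(i, j)

where intra(i) is the mean contact inside TAD i and inter(i, j) is the mean
contact between TAD i and its adjacent TADs (averaged over both existing
neighbors). The radius with the best overall quality is selected; every
radius's call is still written out. Optional PCA preprocessing at a chosen
variance-retention level is available but off by default — it does not help,
and hurts under noise.

Concordance between two domain partitions A and B is scored as

    MoC(A, B) = ( Σ_ij F_ij² / (|a_i|·|b_j|) − 1 ) / ( √(N_A·N_B) − 1 )

with F_ij the bin overlap of a_i and b_j, MoC = 1 for N_A = N_B = 1.

## Worked example

Simulate a 200-bin chromosome at 40 kb with ten planted domains, telomeric
and centromeric gaps, and mild noise; call TADs; evaluate concordance:

```
$ GAPS=$(python -c 'print(",".join(map(str, [*range(3), *range(88,108), *range(189,200)])))')
$ coitad simulate --noise-level 4 --seed 3 --gap-bins "$GAPS" \
    --out-matrix sim.txt --out-truth truth.domains
wrote 200x200 matrix to sim.txt, truth to truth.domains

$ coitad call sim.txt --resolution-kb 40 --out-dir out
selected radius: 2
best call: 10 TADs, 21 boundary regions, 3 gap regions
outputs written under out/

$ coitad moc out/domains_best.domains truth.domains --n-bins 200
0.8234
```

The caller evaluated radii 2–20, picked radius 2 by the intra−inter quality
score, and recovered all ten planted domains (10 TADs called) with a
concordance of 0.82 against the planted partition — boundary bins at domain
junctions account for the missing concordance. `out/` contains per-radius
BED and bin-index domain files, `quality.tsv` (one row per radius with the
selected row flagged), and `domains_best.*` for the selected radius.

The same pipeline is available as a library:

```python
from coitad import benchmark_spec, simulate_hic, run_pipeline

matrix, truth = simulate_hic(benchmark_spec(noise_level=8, seed=5))
result = run_pipeline(matrix)
print(result.best_radius, result.best_call.counts())
```

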