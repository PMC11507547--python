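# Methods

## Model and procedure

The caller treats TAD detection as density-based clustering of local
neighborhood profiles. Each diagonal bin *i* of a symmetric N×N contact
matrix is summarized by the vector of contact values in its circle of
influence: the cells `(i+di, i+dj)` for offsets `(di, dj)` within a radius
*r* of the origin. Because the matrix is symmetric, the semi-circle variant
(offsets with `dj ≥ di`, i.e. on or above the main diagonal) carries the
same information at half the length and is the default. Bins inside the
same domain see similar neighborhoods; bins in different or weaker domains
see different ones, so a density clustering of the N vectors groups
same-domain bins. Maximal runs of equally-labeled consecutive bins become
segments, classified gap / TAD / boundary, and an intra-versus-inter
contact score picks the best radius from the schedule.

Assumptions worth stating plainly:

* the input matrix is used as-is — no ICE/KR normalization is applied or
  expected; the method tolerates (and in practice exploits) the coverage
  structure of raw matrices;
* domains are non-overlapping and non-hierarchical: each bin belongs to at
  most one called TAD;
* a TAD spans at least 180 kb and at most roughly 800 kb; the lower bound
  is enforced on calls (segments shorter than `ceil(180/res)` bins become
  boundary regions), the upper bound only caps the radius schedule — a
  longer run of same-cluster bins is still reported as one TAD.

## Neighborhood geometry

The radius-1 neighborhood is the familiar 9-cell compass block (center plus
the eight adjacent cells). For larger radii two geometries are provided:
`euclidean_disk` (default; cells with `di² + dj² ≤ r²`, always including
the full first ring so radius 1 keeps its nine cells) and
`chebyshev_square` (the whole `(2r+1)²` window). Neighborhoods reaching
past the matrix edge are zero-padded so every bin yields a constant-length
vector, which the clustering stage requires. Offsets are enumerated in a
fixed documented order; Euclidean distances between vectors are invariant
to any such order (asserted by a property test), so the choice is purely
cosmetic.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `max_tad_size_kb` | 800 | caps the radius schedule via `max_r = max_size/res` |
| `min_tad_kb` | 180 | minimum TAD span; `min_bins = ceil(180/res)` |
| `shape` | semicircle | semicircle or full circle neighborhood |
| `geometry` | euclidean_disk | disk or square neighborhood |
| `min_cluster_size` | `max(2, min_bins)` | smallest dense group HDBSCAN may call a cluster — tied to the smallest biologically admissible TAD |
| `min_samples` | library default (= `min_cluster_size`) | HDBSCAN core-distance neighbor count |
| `pca.enabled` | off | optional PCA of the feature table before clustering |
| `pca.retention` | 0.75 | fraction of variance kept when PCA is on |

HDBSCAN runs with `allow_single_cluster` so that a matrix that is one big
dense domain yields one cluster rather than all-noise. Noise bins (label
−1) are never merged into neighboring clusters; a run of noise bins forms
its own segment, which is the correct behavior for the sparse stretches
between dense squares. Cluster ids are relabeled in first-appearance order
along the diagonal so repeated runs are byte-identical.

PCA standardizes columns with the population variance, drops zero-variance
columns (zero padding at the matrix edges routinely produces them), and
keeps the smallest k components reaching the retention level. At retention
1.0 this is a rotation of the standardized features, so clustering results
coincide with clustering the standardized table directly (asserted in the
suite). The pipeline default leaves PCA off: on the benchmark matrices
reduced features are never better and are noticeably worse under heavy
noise, so the recommended configuration is semicircle features, no
reduction.

## Quality score and radius selection

`quality(TAD_i) = intra(i) − mean_j inter(i, j)` over the existing adjacent
TADs j (one term at the chromosome ends; a lone TAD scores its intra mean).
The overall score of a radius is the mean over its TADs, and the selected
radius is the argmax with ties to the smallest radius; a call with no TADs
scores −inf and can never win. Adjacency is defined on the ordered list of
TAD segments, skipping intervening gap and boundary segments. Averaging
(rather than summing) over the two neighbors keeps interior and terminal
TADs on the same scale.

A caveat observed on synthetic data: because `inter` is a mean over the
full rectangle between two TADs, calls consisting of very large merged
domains can score competitively (the rectangle between two huge adjacent
domains is dominated by long-range cells with near-zero background). On
matrices with realistic gap structure this rarely wins the argmax, but it
is the main way the selection can go wrong on gap-free matrices.

## The synthetic benchmark

`simulate_hic` builds a chromosome as

1. distance-decay background `base / (1 + α·|i−j|)` with `base = 10`,
   `α = 0.5`;
2. planted square blocks on the diagonal with intensities from an
   alternating weak/strong ladder `intra_level · (1 ± spread)`
   (`intra_level = 20`, `spread = 0.3`). Real domains differ in contact
   enrichment; perfectly identical blocks would also make interior bins of
   different domains exact duplicates in feature space — a degenerate input
   no real matrix produces;
3. Poisson count sampling at sequencing depth 2 (counts are drawn as
   `Poisson(depth·λ)/depth`): raw Hi-C is integer counts, so shot noise is
   present even at noise level 0;
4. additive symmetrized half-normal noise of scale `noise_level` — the
   graded dial, with levels 4, 8, 12, 16, 20 spanning easy to hard relative
   to the default intra level of 20;
5. unmappable bins (`gap_bins`) zeroed in row and column last, so they stay
   empty at every noise level, exactly like bins with no mapped reads.

The canonical study condition (`benchmark_spec`) is a 200-bin chromosome at
40 kb resembling a small two-arm chromosome: a 3-bin leading telomeric gap,
five domains of 14–20 bins per arm, a 20-bin centromeric gap, and an 11-bin
trailing gap. The planted partition depends only on the layout, never on
the seed. Noise-sweep summaries use 20 seeds per level.

What the generator does **not** emulate: coverage biases along the genome,
loops and flares at domain corners, nested sub-domains, and
translocation-style long-range structure. Passing benchmarks therefore
demonstrate the machinery recovers clean planted block structure under
graded noise — not calibrated performance on real chromatin.

## Behavior on the benchmark, and a structural limitation

On the two-arm benchmark the selected call recovers the right number of
domains (≈10 called on a 10-domain truth at noise 4) and its concordance
with the truth declines monotonically with the noise level (means ≈0.67 at
noise 4 down to ≈0.36 at noise 20 over 20 seeds).

Bin-exact recovery (MoC = 1.0), however, is structurally out of reach even
on noiseless matrices, and this is a property of the method worth
understanding before using the calls for base-pair-precise boundary work.
Circle-of-influence features are translation-invariant: a bin's vector
depends only on its local neighborhood pattern, not its genomic position.
Consequently (a) the one or two bins flanking each domain junction have
"mixed" vectors lying between the two domain clouds, and bins at
structurally equivalent positions near *different* junctions are one
another's nearest neighbors — they either form a small parasitic cluster
(splitting runs) or drop out as HDBSCAN noise (truncating each domain by a
bin or two); and (b) the first and last bins of the matrix carry
zero-padded vectors far from every cluster. Across a wide sweep of
generator and clustering settings the best observed noiseless concordance
was ≈0.99, with the loss always concentrated in single junction bins.
Boundary uncertainty of about one bin (one resolution unit) is therefore
inherent.

## Numerical choices and degenerate inputs

* Asymmetric input is symmetrized as `(M + Mᵀ)/2` when the maximum
  asymmetry exceeds 1e-6 relative, with a logged warning; NaN loads as 0 so
  unmappable bins fall through to the gap rule.
* The gap test inspects the full intra-segment submatrix, not only the
  diagonal entry; for the all-zero segments the two readings agree.
* "At least the minimum TAD length" is inclusive (`≥ min_bins` with
  `min_bins = ceil(180/res)`), so a called TAD never spans less than 180 kb.
* Radius-selection ties go to the smallest radius; MoC is clamped to [0, 1]
  against floating-point overshoot; a single-domain vs single-domain
  comparison is defined as 1.
* Zero-TAD calls score −inf; empty partitions are rejected rather than
  scored.

## Known limitations

* Single chromosome, dense in-memory matrices; no `.hic`/`.cool` parsing.
* No nested or overlapping domains.
* The quality score's large-domain bias described above.
* Boundary placement is uncertain by about one bin; downstream analyses
  (e.g. boundary-marker enrichment) should use a matching tolerance.
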