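# Methods

## Coordinate model

Genomes are ordered collections of replicons (name, length, circular
flag).  Coordinates are 0-based and half-open (BED convention); bin *i*
of width *s* covers [*i·s*, (*i*+1)·*s*) locally, with the last bin of a
replicon possibly short.  The genome-wide matrix concatenates replicons
in layout order; cis/trans status is derived from the bin table.  All cis
statistics (DI, P(s), scalograms, significance) are computed per replicon;
windows and distances wrap on circular replicons using the shorter arc,
so no separation ever exceeds half the replicon length.

## SCN normalization

Sequential component normalization alternately divides each column and
then each row of the valid-bin submatrix by its vector norm (Euclidean by
default; "sum" is offered when row-stochastic output is easier to read).
Convergence is declared when the maximum relative entry change between
iterations falls below `tol` (default 1e-6); the default iteration cap is
2000 because on realistic 530-bin maps the linear convergence of the
alternating scheme needs roughly a thousand iterations to reach that
tolerance.  After the final iteration the matrix is re-symmetrized as
(M + Mᵀ)/2, since alternating row/column steps break exact symmetry at
the residual level.  Bins with zero coverage, or coverage below a chosen
quantile of the nonzero coverages (default quantile 0.02 in the CLI),
are masked first and stay zero.  Balancing is genome-wide by default — the
merged all-replicon matrix is one object — with a per-replicon switch.

Properties relied on downstream: scale invariance (SCN(αM) = SCN(M)) and
exact removal of separable biases b_i b_j K_ij, both verified to 1e-6 in
the acceptance suite.

## Directionality index and CID calling

For each bin the upstream sum A and downstream sum B are taken over
`scale_bp` of flanking sequence (default 100 kb = 20 bins at 5 kb),
excluding the main diagonal, wrapping on circular replicons and
truncating on linear ones.  With E = (A+B)/2,

    DI = sign(B − A) · ((A−E)²/E + (B−E)²/E),    DI = 0 when A + B = 0.

A boundary is called where a run of at least `min_run_bins` (default 3)
bins with DI ≤ −θ meets a run of at least `min_run_bins` bins with
DI ≥ +θ, allowing at most one intervening near-zero bin.  The magnitude
threshold θ defaults to the 60th percentile of |DI| over valid bins —
an adaptive choice, since DI magnitudes are chi-square-like sums whose
scale depends on depth and normalization — and can be fixed explicitly.
The boundary is reported as the interval spanning the transition bins,
with the interval midpoint as representative position; CIDs are the
segments between successive boundary midpoints (on a circular replicon
there are exactly as many CIDs as boundaries; on a linear one, boundaries
plus one).  Boundary calls are invariant to global scaling of the matrix.

Boundary-set comparison uses greedy nearest matching of midpoints within
`tol_bins` (circular distance in bins), each boundary matched at most
once; recovery against planted truth reports matched precision, recall
and F1.

## Distance decay and significant contacts

P(s) is the mean contact value per distance stratum over valid cis pairs,
excluding the self-diagonal; strata are one per bin distance, or
logarithmically spaced on request, and empty strata are absent rather
than zero.  The decay exponent is the slope of a log-log linear fit over
a stated range (5–500 kb in the benchmarks, clear of both the diagonal
and the circular plateau near L/2).

The expected model smooths the per-stratum empirical means by isotonic
regression constrained non-increasing in distance, then floors the result
at the smallest positive stratum mean so every tested pair has a strictly
positive expectation.  Per pair, the p-value is the upper Poisson tail
P(X ≥ obs | μ = expected(s)); q-values are Benjamini–Hochberg over all
tested pairs; reported pairs satisfy p < α, q < α and count > 2 (α = 0.05).
This is a native re-implementation of spline-based distance-decay
significance callers: at bacterial sequencing depths the Poisson tail and
a binomial coupled to the total count agree closely, and the isotonic fit
needs no knot tuning.  Significance runs on raw counts with the expected
model from the same raw map; bias-corrected calling can be had by passing
a custom expected model.  The main diagonal is never tested.

Calibration note: with discrete Poisson counts the strict tail p-value is
conservative, so the pooled fraction of p < 0.05 under the null sits
slightly below 0.05; at expectations of order 10² per pair (short/mid-range
5 kb bins at 5e6 depth, the regime the null benchmark draws from) the
deficit is small (~0.045 pooled).  The probability that BH rejects at
least once in 1000 null tests is ~4%, so the clean-run rate is estimated
over 2000 replicates in the benchmarks to keep binomial noise small
relative to the 95% bound.

## Scalograms and ratio maps

The scalogram accumulates each bin's cis contacts over flanks ±w and
records the smallest half-width (bp) reaching 15/30/45/60/75/100% of the
total within ±`max_halfwidth` (default 500 kb, clipped with a warning to
half the replicon on circular replicons).  Monotonicity across levels is
exact by construction.  The ratio map reports
log2((a+ε)/(b+ε)) per (bin, distance), averaging the upstream and
downstream directions; ε defaults to the 5th percentile of the pooled
positive entries of both maps, which keeps the map antisymmetric under
swapping conditions and stabilizes sparse distal entries.

## 3D embedding and compactness

Contact-to-distance conversion uses d = c^(−1/α) (α = 1 by default) on
positive normalized contacts; missing distances are completed by shortest
paths over the contact graph (an error lists components if the graph is
disconnected) and coordinates come from classical MDS into three
dimensions, centered on the centroid.  The result is an *average
structure*: the organism is polyploid and intra- vs inter-copy contacts
are indistinguishable, so models summarise the population and support
metric comparisons, not literal single-molecule shapes.  On noiseless
synthetic curves (ring and folded "boat" arms) the round trip
structure → contacts → embedding recovers the shape with Procrustes
RMSD/Rg ≤ 0.15 (in practice ≈ 1e-8: classical MDS on an exact Euclidean
distance matrix is exact).

Metrics: Rg is the root-mean-square distance of points from their
centroid.  Global compactness GC is the mean over all pairs of
1/(d_ij/Rg) — scale-free by construction; local compactness LC(scale)
restricts the same mean to pairs with genomic separation ≤ scale
(shorter-arc, within replicon).  Exact formulas for these two summaries
are this package's definitions: harmonic-type means of inverse Rg-scaled
distances, chosen so that higher = more compact, LC → GC as the scale
grows, and uniform coordinate scaling changes neither.  Coincident points
are rejected by name.  Rg and compactness are reported per replicon.

The PPI proximity test maps each gene to the bin holding its midpoint,
drops pairs collapsing to one bin (counted), and compares PPI-pair spatial
distances against all distinct valid bin pairs with a one-sided
Mann–Whitney test.

## Integration statistics

Boundary genes are genes overlapping any boundary interval extended by
`flank_bins`; feature tests are one-sided Mann–Whitney (boundary larger
for expression and gene length, smaller for G+C), requiring at least five
genes per group and non-constant features.  The per-bin transcription
track is the overlap-length-weighted mean expression of overlapping
genes; its Pearson correlation with the matrix diagonal is reported with
a two-sided p after standardizing both tracks.  Sliding-window DEG
enrichment counts DEG midpoints per window (5 kb step, 100 kb window,
wrapping), with an empirical null that reassigns DEG labels uniformly
over the annotated genes — preserving gene density, which overlap-based
or per-bp nulls would not — and BH correction across windows
(conservative under window overlap).  Midpoint assignment avoids double
counting within a window phase.  G+C profiles count G/C among unambiguous
bases only; the fraction of boundaries below the genome average is
computed on boundary-interval mean GC versus the replicon-wide mean.

## Synthetic data generator

The generator's expected cis matrix is a product of independent factors:
power-law decay s^(−α) (α = 1 by default; the self-diagonal takes the
s = 1 value), a within-CID block factor (contrast 2 by default, planted
boundary bins defining the domains), an optional inter-arm secondary
diagonal 1 + a·exp(−(arc/w)²) on designated replicons (a = 0.3, w = 8 bins
— faint, as in the real maps), and multiplicative per-bin biases
exp(N(0, 0.3)).  The matrix is scaled to a total expected depth (5e6
pairs by default, matching the benchmark conditions) and sampled cell-wise
Poisson — cell independence is what makes the significance-calibration
nulls exact.  Condition modifiers: "uv" multiplies the decay by s^(+0.3)
(relative short-range depletion) and deletes a stated subset of
boundaries (domain fusion); "mutant" halves contacts below 100 kb and
deletes boundaries in a contiguous region.  Because depth is held fixed,
short-range depletion re-weights mass toward long range, and the embedded
structures of "mutant" maps have systematically smaller Rg — the planted
compaction direction that the paired 10-model comparison detects.

Default planted geometry for Chr1-scale benchmarks: 530 bins of 5 kb,
8 boundaries with pairwise spacing ≥ 40 bins (200 kb), so that domains
remain resolvable at the 100 kb DI scale and CID sizes stay in the tens
to hundreds of kb.

Expression/DEG tracks: genes laid head-to-tail with exponential spacers
(~500 genes on Chr1, lognormal lengths around 0.9 kb), lognormal
expression (σ = 1); genes overlapping a boundary ±3 bins receive
configurable length and expression multipliers (flank 3 yields the
~50/450 boundary/interior split used in the power benchmarks; the 2×
expression multiplier is the planted effect).  DEG labels are drawn with
weight 10 inside designated 100 kb windows and weight 1 elsewhere.  PPI
pairs are sampled with weight exp(−β·d/Rg) on a structure (β = 0 null,
β = 5 planted effect).

What the generator does *not* emulate: replication-associated coverage
gradients (ori→ter), restriction-fragment granularity, inter-replicon
biology beyond a uniform trans floor, polymer-physics constraints, and
correlated (non-Poisson) technical noise.  Passing recovery tests
therefore demonstrates algorithmic correctness under a faithful
phenomenological model, not robustness to every artifact of real
libraries.

## Benchmark problem sizes

The acceptance suite uses: 5 Chr1-scale maps (530 bins, depth 5e6) for
boundary recovery; one 530-bin map plus an 80-bin separable-bias example
for SCN checks; 2000 null replicates of 1000 Poisson pairs for
calibration; three 530-bin maps (depth 5e6) for exponent recovery;
150-point noiseless curves and 10 Poisson-resampled maps per condition
(depth 1e6) for structure metrics; and 100 seeds per rate for the four
integration procedures (500–600 genes, 100–530 bins, 2000 permutations).

## Known limitations

- The DI threshold is adaptive by percentile; on maps with no real
  boundaries it will still rank bins, and calls there are suppressed only
  by the run-length requirement.  Fixed thresholds are available.
- BH across overlapping sliding windows is conservative; an
  effective-number correction is not implemented.
- Embedding is a documented stand-in for dedicated reconstruction
  software and is intended for metric-level comparisons (Rg, GC/LC),
  not publication-quality shapes.
- Trans (inter-replicon) significance calling is out of scope; trans
  contacts only enter the genome-wide SCN balance and embeddings.
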