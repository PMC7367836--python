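# Methods

This note documents the statistical model behind `fragsig`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that
affect reproducibility.

## Replication-timing profiles (`repliseq`)

Two-fraction Repli-seq yields early- and late-fraction read counts per
fixed genomic bin (default 5 kb). The RT value of a bin is

```
RT = log2((early + c) / (late + c))
```

with pseudocount `c = 1` to stabilise low-count bins. Bins whose total
coverage (early + late) falls below `min_coverage = 10` reads are
masked (NaN): below that depth the log-ratio is dominated by shot
noise. Profiles are quantile-normalized across replicates by
rank-matching to the mean of the sorted vectors, computed over the
bins unmasked in *all* profiles, so that replicate-to-replicate
distributional shifts (library size, S-phase gating) do not masquerade
as RT change. Smoothing uses a truncated Gaussian kernel
(radius = int(4σ + 0.5)) with symmetric edge padding; masked gaps are
not smoothed across. Genome-wide RT is trisected into early/mid/late
thirds by rank (tertiles), and metagene matrices stretch gene bodies to
100 bins with native-resolution flanks, ordering genes largest-first.

## RT variability (`rt_variability`)

RT is aggregated into non-overlapping windows (default 100 kb = 20
bins; a window is dropped if more than `max_masked_frac = 0.5` of its
bins are masked). The significance threshold is calibrated from
replicate noise: pool all within-condition pairwise per-window
differences and set

```
threshold = 2 × SD(pooled differences)
```

so that, under Gaussian replicate noise, a between-condition difference
exceeding the threshold is roughly a 2σ event. A window is flagged as
variable iff |mean(APH) − mean(control)| ≥ threshold **and** every
cross-condition replicate pair agrees in sign (sign-consistency guards
against a single outlying replicate). Adjacent flagged windows with the
same direction merge into variable regions. Per-window ΔRT signatures
are clustered by k-means (`k = 5`, 50 restarts, seeded) and labelled
from the cluster mean's control level and direction of change
(for example "early-delayed", "late-advanced"); per-cluster paired
t-tests are Benjamini–Hochberg corrected.

## Transcription (`transcription`)

Nascent-transcription gene expression is reads per million per kilobase
of gene body, computed from binned counts with partial-bin weighting.
Genes below a silence floor of 0.5 RPM/kb are "silent"; expressed genes
are split into quartiles q1–q4 by rank, and "highly transcribed" means
q3 or q4. Gene sizes are classified small (< 250 kb), medium
(250–300 kb), large (> 300 kb); large genes are further split into
rank-quartile subgroups L1 (largest) to L4.

## TAD architecture (`tad_architecture`)

Boundaries are minima of a diamond separation score: for each bin, the
mean contact frequency in the `w × w` (default `w = 10` bins at 25 kb)
square linking the regions up- and downstream, log2-scaled relative to
the chromosome mean. The score is computed with a summed-area table
(O(n) per bin). Minima are called with `scipy.signal.find_peaks` on the
negated score with prominence `min_depth = 0.3` and minimum separation
4 bins — a boundary must be a clear dip, and two boundaries closer than
100 kb are not resolvable at this window. CTCF enrichment at boundaries
uses a shuffle null: peaks are re-placed uniformly at random,
chromosome-constrained, into non-overlapping positions, and the
empirical p-value uses the add-one estimator
`p = (1 + #{null ≥ observed}) / (1 + n_iter)`, which is never 0 and is
uniform on its support under the null.

## Fragility calls (`fragility`)

The verdict for a gene is the conjunction of four binary components:

1. **is_large** — body > 300 kb;
2. **is_highly_transcribed** — expression quartile q3/q4;
3. **is_rt_delayed** — at least one delayed variable region overlaps
   the body (half-open interval overlap);
4. **spans_boundary** — a called boundary midpoint lies strictly inside
   the body.

Candidates are refined by V-shape detection on the ΔRT (APH − control)
track: the body plus 500 kb flanks is smoothed (Gaussian, σ = 2 bins),
the vertex is the ΔRT minimum inside the body, depth is measured
relative to the median of the flanks, and a V requires a rise of at
least `min_depth / 2` on both sides (default `min_depth = 0.5` RT
units, i.e. a quarter RT unit of relief per side). The core fragile
region is the contiguous run of bins within `cfr_fraction = 0.8` of the
depth. V-detection annotates candidates by default
(`require_v = False`); it can optionally gate the verdict.

## Synthetic-data generator (`synthetic_data`)

Defaults (the benchmark condition): 4 chromosomes × 50 Mb, 500 genes,
12 planted fragile genes (bodies 400–700 kb, high expression, each
spanning a TAD boundary with the planted V vertex at the boundary
midpoint), 12 intra-TAD delayed controls (delayed but spanning no
boundary), planted V depth −1.5 RT units, 4 replicates per condition,
replicate noise N(0, 0.2) i.i.d. per bin, 200 reads per 5 kb bin.

The latent control RT field is Gaussian-smoothed white noise rescaled
to [−3, 3]; the APH field subtracts planted V-shaped (fragile/control
genes) or box-shaped (advanced regions) perturbations. Reads are
generated with a base-2 logistic link: the early-read probability is

```
p = 1 / (1 + 2^(−RT))
```

so that the measured `log2(early/late)` is, in expectation, the latent
RT itself — the link has unit slope in log2-odds. (A natural-log
logistic would scale measured RT by 1/ln 2 ≈ 1.44 and make planted
depths unrecoverable on their own scale.) Early counts are
Binomial(200, p) per bin; nascent transcription is Poisson with
per-gene rates proportional to planted expression levels.

What the generator does **not** emulate: mappability and GC biases,
copy-number variation, S-phase sub-fraction structure beyond
early/late, distance-dependent Hi-C contact decay (block matrices are
piecewise-constant plus Poisson noise), spatially correlated replicate
noise, and expression changes under APH. It is a positive/negative
control bench, not a genome simulator: planted effects are recoverable
by construction and the controls (delayed-but-intra-TAD genes) probe
exactly one verdict component.

## Numerical and reproducibility choices

- All floating-point text output uses the `%.10g` format; `run_log.json`
  is written with sorted keys and no timestamps, so identical config +
  seed ⇒ byte-identical outputs.
- All randomness flows from a single integer seed; internal components
  use fixed offsets of it (simulation seed, seed+1, …) or
  `numpy.random.default_rng` seeded explicitly. k-means restarts are
  seeded.
- Interval intersection uses sorted-array `searchsorted` scans
  (O((n+m) log m)); the test suite checks them against brute-force
  all-pairs oracles.
- Windowing drops a trailing partial window rather than padding it, so
  every window mean averages the same number of bins.

## Limitations

- The verdict is a hard conjunction of thresholded components; genes
  near a threshold (for example 299 kb, or expression at the q2/q3
  boundary) flip discretely. No uncertainty is propagated into the
  verdict.
- The variability threshold assumes replicate noise is exchangeable
  across conditions and approximately Gaussian at the window scale.
- Boundary calling operates on dense per-chromosome matrices at a
  single resolution; no multi-resolution reconciliation or balancing
  (ICE) is performed — input matrices are assumed normalized.
- The enrichment shuffle preserves peak lengths and chromosome
  assignment but not local chromatin context (GC, gene density).
- k-means signature classes depend on `k`; labels are heuristics over
  cluster means, not model-based calls.
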