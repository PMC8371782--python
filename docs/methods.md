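# Methods

## Model and assumptions

The normalization rests on one biological assumption: across the
samples being compared, the *average* regulatory signal (histone mark,
transcription-factor binding, chromatin accessibility) over genes whose
expression is constant between those samples is itself constant. Any
systematic difference observed in the density tracks over those genes
is then attributed to technical variation and inverted. The assumption
fails, and the method must not be used, when the profiled protein is
itself globally perturbed between conditions (overexpression or
knockdown of the target); spike-in protocols are the right tool there.

Input tracks are assumed to be background-corrected densities (e.g.
peak-caller output already corrected for input, GC content and copy
number). `chipnorm` never models the control track itself.

## Constant-gene selection

Genes are ranked by cross-sample mean expression and split into
`n_bins = 100` contiguous equal-size bins (remainder genes go to the
lowest bins); within each bin the `ceil(percent/100 × bin_size)` genes
with the smallest cross-sample standard deviation are kept
(`percent = 10`). Binning by expression level ensures anchors exist at
every signal intensity, which the quantile mode in particular relies
on. Decisions worth noting:

- SD is the sample standard deviation (ddof = 1) on the CPM-scale
  values directly; no variance-stabilizing transform. Silent genes
  (all-zero) are retained — stably silent genes are valid anchors.
- Ties in mean or SD are broken by gene id, making the selection
  platform-independent.
- FPKM/TPM inputs are multiplied per gene by exon length (union of the
  gene's exons) in kb before ranking. The residual per-sample constant
  that distinguishes TPM from FPKM is irrelevant: only per-gene
  cross-sample mean/SD rankings are consumed downstream, and those are
  invariant to per-sample scaling. Microarray values are used unlogged
  and without length correction.

## Signal matrices

The scale-regions matrix rescales each gene body to `body_length`
(default 40 kb) by averaging the track over equal-width genomic
sub-intervals with exact fractional-base coverage weighting (a
sub-interval edge inside a base weights that base by the overlap), and
appends non-rescaled flanks (default ±4 kb) binned at `bin_size`
(default 10 bp); default row width 4000 + 2×400 = 4800 bins. Rows are
laid out 5′→3′: minus-strand rows are reversed relative to genomic
coordinates, with TSS = `start` for plus and `end` for minus genes.
Uncovered bigWig positions and flank stretches beyond chromosome edges
count as signal 0 (density tracks denote absence of reads by absence of
intervals). Binning and resampling are averaging operators, so the
matrix is exactly affine in the track values — a property the tests
exercise directly.

## Linear (affine) normalization

The reference is the sample whose overall mean matrix value is the
median across samples (lower median for even counts; ties broken by
sample id). Each other sample's constant-gene mean bin profile is
regressed on the reference profile by ordinary least squares with
intercept, and the raw track values are corrected as
`v → max(0, (v − β)/α)`. A fit with α ≤ 0 is rejected with a pointer to
the quantile mode — a non-positive slope means the samples are not
positively related over the anchors and an affine inversion would be
meaningless. The reference track passes through unchanged.

## Quantile normalization

Genes are sorted by their mean intensity over all bins and samples and
split into `k = 20` near-equal contiguous groups. The k × n_samples
matrix of per-sample group means is quantile-normalized in the classic
way (sort each column, replace by the across-sample mean at each rank).
Each sample then gets a monotone value map through its
(original group mean → target) knot pairs, applied to every track
value, with linear extension beyond the outermost knots (strong peaks
exceed all constant-gene group means; clamping them to the last knot
would flatten biology) and a clamp at 0.

The smoother through the knots is a monotone cubic (PCHIP) interpolant,
after collapsing duplicate knots (averaging their targets) and an
isotonic (pool-adjacent-violators) correction of the targets; with
fewer than 4 distinct knots the map degrades to monotone
piecewise-linear interpolation with a warning. A penalized smoothing
spline was considered and rejected: it is not guaranteed monotone — a
non-monotone value map can invert signal ordering, which is
biologically indefensible — and it does not reproduce the knot targets
exactly, whereas the whole point of the map is to send each group mean
to its quantile-normalized target. PCHIP is monotone by construction,
exact at the knots, and parameter-free, which also removes a hidden
smoothing constant from the reproducibility surface.

The quantile procedure operates on the k-vector of group means, not on
per-bin values: each intensity group contributes one observation per
sample. With k = 20 anchors spanning the intensity range, the fitted
map is well constrained wherever signal actually occurs.

## Evaluation

Normalization success is scored on mean TSS profiles of the constant
genes (8 kb window, 10 bp bins, strand-oriented), split into Zone 1
(−4, −1) kb, Zone 2 (−1, +1) kb and Zone 3 (+1, +4) kb. For each zone
and unordered sample pair the percent difference of the areas under
the curves is `100·|Aᵢ − Aⱼ| / ((Aᵢ + Aⱼ)/2)`, averaged over pairs. The
pair-mean denominator is a deliberate choice (the quantity has no
canonical definition): it is symmetric in the pair and bounded by 200%.
Areas are Riemann sums over bins whose centers fall in the zone; the
three zones tile the window exactly, so their areas sum to the window
total. A pair with both areas zero scores 0 with a warning.

## Expression-stratified profiles (antibody QC)

Genes are clustered into low/medium/high expression by 1-D k-means
(k = 3, 10 restarts, fixed seed, default 42) on log1p-transformed
values of one chosen sample (or the across-sample mean); raw-scale
clustering is available via a flag but is dominated by outliers on
heavy-tailed expression data. Cluster labels follow ascending centers.
The mean TSS profile per stratum is plotted with gene counts; the
package renders the diagnostic and leaves the verdict (specific vs
cross-reactive antibody) to the user.

## Synthetic worlds

The fixture generator emulates exactly the structure the method
assumes: a toy multi-chromosome genome; non-overlapping genes (≥10 kb
spacing, bodies 1–5 kb); log-normal base expression (meanlog 3,
sdlog 1.5, wide enough that 100 expression bins are non-degenerate at
1000 genes); a base track of uniform background 0.5 plus one Gaussian
promoter peak per gene (SD 300 bp, height = 0.1 × expression); and
per-sample tracks `αₛ·base + βₛ`, optionally with multiplicative
Gaussian noise per 10 bp step. A `constant_fraction` of genes (default
10%) is exactly invariant across samples; all other genes receive
per-sample fold changes that are mean-centered (their cross-sample mean
stays at the base level) with a guaranteed minimum spread (default
10%), on top of ~1% multiplicative measurement noise applied to every
gene. Truth (constant gene ids, α/β, coordinates) is recorded as JSON.

Design notes:

- Truth-constant genes are stratified across the expression range
  (every 10th gene in base-expression order), matching the picture that
  invariant genes exist at every expression level and giving each
  selector bin an anchor to find. Mean-centering the fold changes keeps
  the mean-expression ordering equal to the base ordering, so the
  stratification survives measurement; the minimum fold spread keeps
  "variable" genes genuinely more variable than the anchors.
- Track values are quantized to multiples of 1/256, making them exactly
  representable in bigWig's 32-bit float storage; with dyadic (α, β)
  the planted affine relation between samples is bit-exact through a
  write/read round trip, so exactness tests are meaningful.
- What the generator does *not* emulate: read-level sampling noise,
  peak-shape diversity, enhancer (non-promoter) signal, copy-number or
  GC biases, and background that varies along the genome. Passing tests
  therefore demonstrate correctness of the algorithms under the model's
  own assumptions, not robustness to every artifact of real data.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere; GTF converts at the
  parser boundary. Exon length is the union of a gene's exons, not the
  longest transcript (deterministic across annotation versions).
- Genes on chromosomes absent from a track are dropped (with a count)
  at matrix time, not parse time: annotations are often broader than
  the assay.
- OLS on a constant reference profile is refused (unidentifiable
  slope). Duplicate quantile knots are collapsed by averaging.
  Bodies shorter than one bin are dropped with a warning.
- Problem sizes in the test suite and acceptance script (worlds of
  200–1000 genes, 2–5 samples, ~5–7 Mb chromosomes) were chosen as the
  smallest at which all 100 expression bins, 20 intensity groups and
  the three zones are simultaneously non-degenerate.

## Known limitations

- The affine mode assumes one global linear distortion; intensity-
  dependent distortions need the quantile mode.
- Zone statistics are relative measures between the samples at hand;
  they do not certify absolute signal levels.
- No spike-in support and no differential-binding calling; normalized
  tracks are meant to feed downstream differential tools.
- Expression and track samples must be matched by the user; the package
  does not reconcile sample identities across files.
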