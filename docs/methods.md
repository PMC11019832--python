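# Methods

This note documents the algorithms and parameter conventions implemented
in `chromadyn`, in the order the pipeline runs them. Coordinates are
0-based, half-open (BED convention) throughout; GTF input is 1-based and
converted on read.

## Interval primitives

`merge_intervals(intervals, gap)` sorts per chromosome and merges any
two intervals whose gap is ≤ `gap` (non-strict; `gap=0` merges touching
or overlapping intervals). The result is the transitive closure: it
equals the fixed point of pairwise merging, which the test suite
verifies against a brute-force closure oracle.

## Differential open-chromatin regions (DOCRs)

1. **Nucleosome-free filter.** Accessibility fragments with length
   strictly less than 100 bases are retained; a 100-base fragment is
   dropped.
2. **Global OCR set.** Per-sample peak calls are pooled and merged in
   two stages: first with `gap=0` (overlap only), then with `gap=100`.
   The two-stage form is equivalent to a single closure merge at gap
   ≤ 100 but mirrors how per-sample peak sets are typically combined.
3. **Counting.** Fragments are assigned to an OCR if they overlap it by
   at least one base (half-open overlap test). Counting is exact and
   independent of fragment order.
4. **Testability gate.** An OCR enters testing only if it has ≥ 100 raw
   reads in *every* sample of the contrast. The gate uses raw counts,
   before normalization.
5. **Differential test.** The negative-binomial engine (below) produces
   per-region log2 fold change, p-value, and Benjamini–Hochberg FDR.
   DOCRs are regions with FDR strictly < 0.05, split into GAIN
   (log2FC > 0) and LOST (log2FC < 0).
6. **Genomic category.** Each DOCR is classified by its *center* with
   precedence promoter > genic > intergenic. The promoter window is
   [TSS − 1000, TSS + 500) in gene orientation: on the + strand that is
   `[tss - 1000, tss + 500)`; on the − strand the window mirrors around
   the TSS with the same half-open downstream edge. Genic means inside
   any gene body.
7. **Chromatin state.** A 15-state segmentation is represented in
   200-base bins; the consensus state of a region is the argmax of
   per-state overlap across its bins, with ties broken toward the
   lowest state index.

## Negative-binomial differential engine

Implemented from first principles in `chromadyn.nb`:

- **Size factors** are median-of-ratios: the geometric mean is taken
  over features with no zero counts, and each sample's factor is the
  median of its count/geomean ratios. A global multiplicative shift
  across all features is therefore absorbed by normalization — only
  relative changes are detectable.
- **Dispersion** is estimated per feature by method of moments on
  normalized counts, then a trend `α(μ) = a0 + a1/μ` is fit across
  features (refit once after excluding gross outliers), and per-feature
  estimates are shrunk toward the trend on the log scale
  (empirical-Bayes weighting by the spread of residuals).
- **Test statistic.** The Wald statistic is the log2 ratio of
  normalized group means over its standard error. The delta-method SE
  of a log mean ratio, `sqrt(cv²_t + cv²_c)` with
  `cv² = (1/n) Σ (1/μ_i + α)`, is anti-conservative at small n, so the
  engine applies a second-order correction:

  ```
  se = sqrt((cv²_t + cv²_c) · (1 + 2·(cv²_t + cv²_c)))
  ```

  This keeps the null type-I error at p < 0.05 near the nominal 0.05
  for 3-vs-3 designs at moderate dispersion (verified in the acceptance
  suite: type-I error within [0.035, 0.065] on 2,000 null regions).
- **Multiple testing** uses Benjamini–Hochberg via statsmodels.
- Features with all-zero counts return NA; contrasts with fewer than
  two replicates per group are refused.

## Transcription-start-site calling

Input is strand-specific 5′-end base counts.

- **Threshold.** Candidate positions must carry at least `min_count`
  reads (inclusive). When not set, the threshold is chosen from a
  Poisson background model: the smallest count whose genome-wide
  expected number of false positives is below 10⁻⁶ per base
  (`poisson.isf` at 1e-6 on the mean background rate), floored at 5.
- **Greedy selection.** Candidates are taken in descending count order;
  accepting a call suppresses all same-strand candidates within 1000
  bases. Count ties are broken toward the 5′-most position — the
  smaller coordinate on +, the larger on −.
- **Classes.** A call is **obsTSS** if a same-strand annotated TSS lies
  within 1000 bases (inclusive); otherwise it is **uTSS**, subdivided
  into genic (inside any gene body, either strand) or intergenic.
- **Divergent pairing.** For a + strand reference call at position `p`,
  the nearest − strand call in `[p − 1000, p]` is its divergent
  partner. One pair is emitted per *reference* call, so a single call
  may appear in two pairs (once as reference, once as partner).
  The pair class follows the partner: obsTSS partner → bidirectional,
  uTSS partner → PROMPT-like. Symmetric duplicates are collapsed,
  preferring the obsTSS perspective.
- **Distance statistics** between two pair sets use the Wilcoxon
  rank-sum test; groups with n < 3 are flagged unreliable.

## Signal matrices and metaplots

- **Depth normalization** scales a coverage track by
  `1e7 / total_fragments` (a per-10-million convention). Tracks carry a
  normalized flag, so normalization is idempotent; a track without a
  recorded fragment total is rejected.
- **Anchored matrices** integrate coverage exactly over 100 equal bins
  of a fixed window around each anchor, using run-length arithmetic
  (no base-pair sampling error). Minus-strand rows are reversed so
  columns read 5′→3′. Rows whose window leaves the chromosome are
  truncated and flagged.
- **Scaled matrices** use a 10 + 20 + 10 layout: 10 bins over a 2,000
  base upstream flank (200 b each), 20 bins over the body scaled to its
  length, 10 bins downstream. Regions shorter than 20 bases collapse
  the body into one merged bin.
- **Subtraction** (e.g. H3-normalized or input-subtracted signal) is
  elementwise on matrices with identical row sets; negative values are
  retained, not clipped.
- **Metaplots** are column means; the SEM uses the population standard
  deviation over rows divided by √n.
- **Row transforms**: centering subtracts the row mean; z-scoring
  divides by the population standard deviation, with zero-variance rows
  mapped to zeros and flagged.

## Super-enhancers

A ROSE-style procedure:

1. **TSS exclusion.** Peaks whose *center* lies within 2,500 bases
   (inclusive) of any annotated TSS are removed.
2. **Stitching.** Surviving peaks are merged when separated by ≤ 12,500
   bases (non-strict).
3. **Scoring.** Each stitched region's score is the background-
   subtracted mark signal summed over its constituent peaks, floored at
   0.
4. **Cutoff.** Scores are ranked ascending and both axes scaled to
   [0, 1]. The cutoff is the first point where the finite-difference
   slope over a window of `max(round(slope_window · n), 1)` ranks
   reaches 1; regions with scaled score strictly above the cutoff value
   are super-enhancers. For the analytic curve y = x⁶ this yields a
   super fraction of `1 − 6^(−1/5)` ≈ 0.301, which the acceptance suite
   checks to ±0.01 at n = 10,000. The cutoff is affine-invariant in the
   scores. With a finite slope window the tangent condition triggers
   slightly before a sharp planted gap, so on a landscape of `n_bulk`
   background regions plus clear outliers the caller may include up to
   ~`window − 1` top bulk regions; shrinking the window to one rank
   recovers a planted set exactly.
5. **Set comparison.** Two SE sets are partitioned into shared /
   condition-specific by interval overlap, and each SE is tested for
   overlap with the DOCR set.

## Cohort integration

- **Clustering.** A regions × samples signal matrix is row-centered and
  clustered with Ward linkage on Euclidean distance; the tree is cut at
  k clusters (default 6). Labels are relabeled contiguously 1..k in
  order of first appearance; columns are ordered basal-subtype samples
  first. Cluster recovery is measured by adjusted Rand index against
  planted structure (≥ 0.9 required in the acceptance suite). Row
  centering makes the clustering invariant to constant per-region
  shifts.
- **Composition tables** cross-tabulate cluster membership against
  chromosome, with margins equal to cluster sizes.
- **ER-style matrices** are scaled (mark − input) profiles in an
  externally supplied row order, then row z-scored.
- **Expression join.** For each DOCR, RNA fragments are counted in the
  inclusive window [center − 250, center + 250] (a fragment overlapping
  the last base counts), the nearest gene is attached, and its
  differential-expression flag uses inclusive thresholds: up if
  log2FC ≥ 1 and FDR ≤ 0.05, down if log2FC ≤ −1 and FDR ≤ 0.05, else
  not significant.

## Synthetic data

All generators are pure functions of `(config, seed)`. Each pipeline
stage draws from an independent stream via
`np.random.default_rng([seed % 2**31, stage_index])`, so adding a stage
never perturbs another stage's data.

- **Annotation**: non-overlapping gene bodies with strands, from which
  TSS sites derive.
- **Accessibility**: fragments with a bimodal length mixture
  (nucleosome-free 36–99 b, mono-nucleosome 150–250 b), reads
  concentrated in planted open regions ≥ 2,500 bases apart, and a
  designated differential fraction planted symmetrically: GAIN regions
  are boosted in treated samples and LOST regions in control by the
  same factor, with 3 + 3 samples.
- **Start-seq**: strand-specific 5′ ends at annotated and unannotated
  anchors ≥ 2,000 bases apart, with divergent partners at log-normal
  distances whose class medians differ by design.
- **Signal tracks**: unimodal and bimodal profiles over constant H3 and
  input baselines, for matrix/metaplot validation.
- **SE landscape**: a Pareto-tailed bulk score distribution plus
  planted outliers at ≥ 4× the bulk maximum, separated by > 12,500
  bases so stitching cannot merge truth regions.
- **Cohort**: block-structured region × sample signal with two subtypes
  and opposing block means.

Generator defaults define the study conditions; tests and the
acceptance report consume them as-is (the one exception — a steeper
score tail for the exact-SE-recovery check — is an explicitly
constructed verification scenario, not a changed default).

## Orchestration

`run_pipeline` executes stages simulate → docr → tss → signal → se →
cohort → expr, each declaring its upstream dependencies. Outputs are
plain text (TSV/JSON/BED-like); `manifest.json` records a SHA-256 per
file, enabling byte-level reproducibility checks and staged resumes.
Running a stage whose inputs are missing raises `DependencyError`
(CLI exit code 3); invalid configuration raises a validation error
(exit code 2). The CLI (`chromadyn`) exposes each stage and a `run`
command with `--stages`, `--seed`, `--outdir`, and YAML `--config`
overrides.
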