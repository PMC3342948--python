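# Methods

`tfcoreg` implements the computational core of a transcription-factor
co-regulation study: detecting where a factor binds (ChIP-seq peak
calling), which genes respond when each factor is knocked down (pooled-rank
differential expression), whether two factors share targets (co-regulation
statistics), which sequence motifs distinguish responsive promoters (PSSM
enrichment with an adaptive cutoff), and how binding sites relate to genes
and to other binding-site sets (interval analyses). The motivating use case
is the MITF–YY1 axis in melanocytes, but nothing in the code is specific to
those factors.

## Skellam-null peak calling

Reads are represented by their 5' start positions only; there is no
fragment-shift or duplicate-filtering model. The genome is tiled with
windows (default 200 bp, step 50 bp) and each window contributes the count
difference `D = C_chip − C_ctrl`. Under the no-enrichment null both counts
are Poisson, so `D` is Skellam:

    P(D = k) = e^{−(μ1+μ2)} (μ1/μ2)^{k/2} I_k(2√(μ1 μ2)),

with `μ1 = r·λ_local`, `μ2 = λ_local`, `r` the ChIP/control depth ratio and
`I_k` the modified Bessel function. The pmf is evaluated in log space with
the exponentially scaled Bessel function (`ive`), and the upper tail
`P(D ≥ d)` by log-space summation, so p-values remain meaningful far below
1e−300 and are never exactly zero. `μ2 → 0` degenerates to a pure Poisson;
`μ1 → 0` to its reflection.

The local control rate `λ_local` is the maximum of the control-window means
over nested spans of 1×, 5× and 25× the window size and a genome-wide
floor — the conservative local-background idea of Poisson window callers,
transplanted to the count-difference statistic. The exact normalization
procedure of the original analysis is not public; scaling the null upward
by the depth ratio (control is never scaled down) is this package's
reconstruction, and both `r` and the λ rule are recorded in the JSON
summary of every run. One-sided p-values are used (peaks are excess ChIP
signal); significant windows within one window size of each other are
merged; the summit is the midpoint of the most significant window (no
summit rule is standard at this window scale); merged peaks touching any
excluded interval (blacklist regions: satellites, rRNA) are dropped.
Default cutoff p ≤ 1e−6, overridable.

For efficiency the caller screens windows with the exact bound
`P(D ≥ d) ≥ P(D = d)`: a window whose pmf at its observed difference
already exceeds the cutoff cannot be significant and its tail sum is
skipped. This is a pure shortcut, not an approximation.

## Pooled-rank differential expression (RSA style)

All `N = m·G` replicate log fold-changes are pooled and ranked increasingly;
ties break deterministically by (value, experiment index, gene index) —
arrays rarely tie, but determinism is a contract here. For a gene with
ranks `r_1 < … < r_m` the score is `min_j P(X ≥ j)` with
`X ~ Hypergeom(N, m, r_j)`: the chance that j or more of its m values fall
in the pooled top `r_j` by luck. The minimum over j is reported without
selection correction, matching the redundant-siRNA-activity procedure this
follows; the statistic is a ranking device, and the q-value step absorbs
scale. Up-regulation is scored on a second, decreasing ranking (equivalent
to scoring the negated table), not by reusing the increasing one.

q-values multiply the Benjamini–Hochberg step-up values by a Storey
estimate `π0 = min(1, #{p > λ}/((1−λ)n))` with λ = 0.5 by default; forcing
`π0 = 1` reproduces BH exactly (asserted in tests against statsmodels).
The default significance cutoff is q ≤ 0.01.

## Co-regulation statistics

Two views over the paired knockdowns, with x = mean log fold-change across
the first factor's replicates and y = the same for the second factor:

* **Bagged lowess with a randomization envelope.** The red curve is the
  pointwise mean of lowess fits (tricube weights, span 0.3, two
  robustifying iterations) over 100 bootstrap resamples, evaluated on a
  fixed grid covering the central 98% of x. The null band is the pointwise
  min/max of single lowess fits over 1000 datasets in which the
  x-coordinates are shuffled (over all plotted genes by default; a subset
  mask can restrict the shuffle). Escape from the band is reported per grid
  point with no multiplicity correction — it is a descriptive graphic, and
  is read as such. Lowess fits use `delta` interpolation (0.5% of the x
  range) for speed and are linearly extrapolated from the nearest distinct
  fitted pair where a bootstrap resample's x range misses the grid ends;
  on exactly collinear data the curve is exact to machine precision.

* **Top-k overlap curves.** For each k and each sign mode (down/down =
  co-activated, up/up = co-repressed, and the two antagonistic modes), the
  overlap between the two top-k lists (ranked by the RSA p-values of the
  matching direction) is scored by the exact hypergeometric upper tail of
  a 2×2 table on the shared gene universe. The default k grid is
  100–400 in steps of 100. The lower end is deliberately not smaller: in
  the synthetic world every gene of a class shares one effect mean, so
  *which* class members occupy the very top ranks is replicate noise,
  uncorrelated between the two knockdowns — at k far below the planted
  class size (~300 true-signal genes per direction) the overlap statistic
  probes that noise ordering rather than the planted structure. On real
  data, where per-gene effect sizes vary and correlate between factors,
  small k behaves better; the grid is a config entry.

## Motif enrichment with an adaptive cutoff

Motifs are count matrices (JASPAR-style text accepted) with a pseudocount
of 0.01 × column total and log2-odds scoring against a background (uniform
by default); ambiguous bases contribute zero. Each region is reduced to its
best window score over both strands (region-level presence/absence, which
is what a binomial test over regions assumes). The hit cutoff is chosen per
motif as the observed score minimizing the exact one-sided binomial
p-value — over- or under-representation, both reported — of foreground hits
at the background hit rate, the rate clamped to `[1/(2B), 1−1/(2B)]` so
zero-background motifs stay finite. Minimizing over cutoffs is a selection;
`calibrate_by_label_permutation` re-runs the whole minimization under
fg/bg label permutation and reports `(1 + #{perm ≤ obs})/(n_perm + 1)`.
The calibrated p, not the raw minimum, is what should gate conclusions.
Matched random background regions reproduce the foreground count and
length multiset with uniform placement avoiding an exclusion set; GC
matching is deliberately not on by default (count/length matching is the
documented contract).

## Interval analyses

Coordinates are 0-based half-open throughout (BED convention); reports
print 1-based positions via a single pair of converters. Overlap fraction
counts an A interval once if it shares ≥ 1 bp (configurable) with any B
interval. Site specificity removes a target site when any other-set site
lies within 5 kb of its summit, boundary inclusive ("within 5 kb"), with
midpoints standing in for unrecorded summits. Peak-to-gene assignment
attaches a peak to every gene whose TSS is within 5 kb of the summit or —
beyond that window — whose intron (default) or gene body (option) contains
it; both rules appear in the source analysis and both are exposed.
Signed TSS distances are positive downstream in gene orientation.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of (spec, seed) and each returns truth
objects sufficient to score the downstream stage.

* **ChIP tracks**: control uniform; ChIP piecewise-uniform, `enrichment`×
  the baseline inside planted non-overlapping peaks. Defaults: 2 × 1 Mb
  genome, 50 peaks of 300 bp, 8× enrichment, 400k ChIP / 250k control
  reads — a ~40× scale-down of the real libraries (~15M ChIP vs ~9M
  control) that preserves the per-window count regime (tens of reads per
  200 bp window). Not modelled: mappability, duplicates, fragment-length
  structure, sequence bias.
* **Expression tables**: replicate value = class mean ± effect + Normal
  noise. Defaults: 2000 genes; classes co-activated 200, co-repressed 150,
  each single-factor 100, antagonistic 0, rest null; effect 1.5, noise
  s.d. 0.3; 6 experiments on the MITF side (two cell lines × two hairpins
  plus one external paired dataset, as in the real design) and 4 on the
  YY1 side (two cell lines × two hairpins; the real YY1 arrays are
  described only as "a similar analysis", so the minimal analogous layout
  is used). Antagonistic defaults to zero because the reference world is
  the co-regulation scenario; set it positive to exercise the antagonistic
  modes. Not modelled: per-gene effect-size variation (see the k-grid note
  above), probe-level noise, inter-gene correlation.
* **Sequences**: i.i.d. letters at a stated GC (default 0.41, the human
  genome-wide value); planted instances drawn column-wise from the PWM at
  a uniform offset and strand. Defaults 300 + 300 regions of 200 bp, plant
  rates 0.4 vs 0.05. Not modelled: repeats, CpG islands, k-mer composition.
* **Peak-set pairs**: the requested overlap fraction holds exactly by
  construction, so interval statistics can be asserted without tolerance.

A green test on this world therefore establishes correctness of the
statistics and their implementation contracts — not calibration on real
genomic covariate structure.

## Numerical choices and degenerate inputs

Hypergeometric and binomial tails come from scipy; the Skellam pmf/sf are
in-package (log-space, as above) and are cross-checked in the test suite
against a truncated Poisson-convolution oracle and against
`scipy.stats.skellam`, which the implementation itself never calls.
p-values are floored at the smallest positive double rather than 0.
Empty read tracks warn and return no peaks; all-equal x in lowess, empty
p-value lists, k beyond the universe, and identical fg/bg score lists are
rejected or flagged rather than silently handled. Per-stage pipeline seeds
are `master*10 + stage_index (mod 2^31−1)`, recorded in the manifest along
with sha256 digests of every stage output.

## Known limitations

* The peak caller's normalization is a documented reconstruction, not the
  original (unpublished) procedure; absolute peak counts on real data will
  differ even at matched cutoffs.
* The minimum-hypergeometric statistic is anti-conservative as a p-value
  (minimum over m tails); treat it as a ranking score and rely on q-values,
  or on the permutation-calibrated variant for the motif analogue.
* The randomization envelope is a pointwise min/max band, not a
  simultaneous confidence band.
* Interval queries are exact but O(n·m) in the worst case per chromosome;
  fine at 10^4–10^5 intervals, not engineered for whole-genome 10^7-scale
  sets.
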