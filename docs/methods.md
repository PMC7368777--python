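# Methods

This note documents the models, estimators, numerical choices and known
limitations of each chromloop stage, and what the synthetic generators do
and do not emulate.

## Coordinate and interval conventions

All coordinates are 0-based half-open (BED convention); browser-style
1-based inclusive spans are converted on input (`intervals.from_browser`).
Overlap anywhere in the package means ≥ 1 bp intersection. Nearest-feature
queries measure the gap between closest interval edges (0 when
overlapping), with ties broken by leftmost target start for determinism.
The one exception is gene grouping in `expression.group_genes`, where the
TSS is a point and the distance is the base-to-base difference to the
nearest covered base of a feature, so "feature starting exactly 20 kb
downstream of the TSS" measures 20,000 and falls on the boundary (grouped
as `neither` under the strict `<`/`>` rules).

## Motif scanning

PWM scores are sums of per-position log2 likelihood ratios against an
explicit background (uniform by default). Both strands are scanned; a hit
requires score strictly greater than the threshold (10 for the CTCF motif,
the conventional FIMO-style cutoff); windows containing `N` score −∞.
`contains_cpg` flags a CG dinucleotide in the forward-strand genomic
subsequence (strand-symmetric). Anchor building takes the best-scoring
motif per peak, ties going to the leftmost position and then the `+`
strand.

## Windowed differential binding

The genome is tiled in `window_size` (default 200 bp) windows with step =
half window; per-window counts are read midpoints falling in the window.
The count model is negative binomial with variance `μ + αμ²` and one
pooled dispersion `α` shared across windows, estimated by moments:

```
α̂ = Σ_w,g (s²_wg − m̄_wg) / Σ_w,g (m̄²_wg − s²_wg/n_g)
```

The denominator uses `m̄² − s²/n` (an unbiased estimate of `μ²`); the naive
`Σ m̄²` is inflated by the sampling variance of the group mean and biases
`α̂` low. Because the per-window test plugs the dispersion in as known, the
test uses `α̂ + 2·SE(α̂)` (window-level delta-method SE), a conservative
plug-in that keeps p-values valid under estimation uncertainty at a
negligible power cost (measured: null probability of any BH discovery 0.04
at nominal 0.05; power 0.97 for 4-fold effects at 50 reads/window, 3v3).

The p-value itself is exact conditional: if group sums are NB with a
shared success parameter, then `S_A | S_A+S_B = T ~ BetaBinomial(T, n_A/α,
n_B/α)` (negative hypergeometric), and the two-sided p sums all outcomes no
more likely than the observed one (minimum-likelihood ordering, as in
Fisher's exact test). This assumes comparable per-replicate depths (a
balanced design); gross depth imbalance is the job of the MA-normalization
route, not this test. A delta-method Wald z on the log ratio of group
means is reported for direction and diagnostics. With fewer than two
replicates in a group the model falls back to a conditional binomial test
and flags `fallback=True`.

Adjacent significant windows (window-level BH FDR < 0.05) of the same
direction are merged; site counts are recounted over the merged span, the
normalized fold uses depth-scaled counts with pseudocount 0.5, and the
site p/FDR is the minimum over member windows. Standard-stringency
filtering then requires union-peak overlap, ≥ 10 reads summed over all
replicates (both groups), strictly > 2-fold, and FDR < 0.05.

## Peak calling, artifacts, RIPM, FRiP

The built-in caller is deliberately simple (the package contract accepts
external peak BEDs anywhere peaks are consumed): pooled read midpoints in
200-bp windows, Poisson tail p < 1e−5 against a uniform genome-wide
background rate, overlapping significant windows merged, summit at the
maximum-count 50-bp bin. Peaks whose coverage is exclusively one stack of
≥ 5 identical-coordinate reads (no other overlapping read) are removed as
PCR artifacts, as are peaks intersecting an optional blacklist.

RIPM normalization divides in-peak read counts by (reads overlapping any
union peak)/1e6, separately per factor; FRiP = reads-in-peaks / total
mapped. FRiP matching of merged samples uses stratified exact
subsampling — in-peak reads of the deeper sample are randomly subsampled
to exactly the shallower sample's in-peak count and out-of-peak reads by
the same factor — so the equal-reads-in-peaks post-condition holds to
rounding (±1 read) rather than to binomial noise.

## MA normalization (lenient tier)

Per peak, `M = log2((m+½)/(f+½))` and `A = ½·log2((m+½)(f+½))`. Common
peaks are those with ≥ 10 reads in both samples; an ordinary least-squares
line of M on A is fitted over common peaks after trimming the 5% most
extreme M values (guards small toy peak sets), and subtracted from M.
P-values use a normal approximation with delta-method variance
`(1/(m+½) + 1/(f+½))/ln²2`; BH adjustment is genome-wide. Lenient sites
need |rescaled fold| ≥ 2, p-adj < 0.01 and > 15 reads in the upregulated
sample, and must not overlap a standard-tier site (the two tiers are
disjoint by construction). The post-rescaling p-value model is a
documented surrogate — the reference MA-normalization tool does not
publish its exact variance function.

## Classification and proximity

Replicate-overlap rules are hard-coded tables (see README) over ≥ 1 bp
overlaps, using the replicate peak sets of the sex with higher binding at
the site. Proximity categories are assigned with strict precedence
Proximal (< 20 kb site-edge to sex-biased TSS) > IntraTAD (site and a
sex-biased TSS inside the same intra-TAD loop) > TAD > Outside, so the
labels partition every site set.

## Loop prediction

Candidates are all `(+ anchor, − anchor)` pairs with the `+` anchor
upstream, both inside one TAD. The reference loop-discovery method's exact
scoring is not published in full; this package uses the transparent
reconstruction `score = √(strength₅·strength₃)·exp(−span/λ)` with λ =
200 kb (configurable), which prefers tightly bound anchors and the
~150 kb loop scale. The top `initial_count` (default 20,000) candidates
are accepted greedily in score order (ties: smaller span, then leftmost);
a candidate is rejected iff it partially crosses an accepted loop in the
same TAD — nesting to any depth is allowed and anchors may be shared
across loops (nested structures produce more loops than distinct anchors).
The greedy selection is exactly characterized by: a candidate is accepted
iff it is compatible with every accepted higher-priority candidate; the
test suite verifies this against a naive independent implementation for
all toy TADs with ≤ 12 anchors.

## 4C-seq pipeline

*Reduced genome.* Every exact GATC occurrence is a cut site (overlapping
occurrences allowed); fragment boundaries are cut-site start coordinates
plus chromosome termini. Each cut contributes an upstream flank
`[c−105, c)` and a downstream flank `[c+4, c+109)`, truncated at
chromosome ends. When consecutive cut sites are exactly flank+4 apart the
two facing flanks are the same genomic interval; such twins are inherently
ambiguous mapping targets and the read simulator never samples them.

*Mapping.* A trimmed read maps when it equals the prefix of exactly one
reduced-genome entry; non-unique or unmapped reads are 3′-trimmed by 10 nt
(2 nt for ≤ 50-nt reads) and retried down to 20 nt. This exact-substring
unique mapper is adequate for error-free synthetic reads; an external
aligner can be substituted for real data behind the same per-fragment
count interface.

*Profiles.* Fragment signal is the sum over the fragment's two flanks;
RPM = count × 1e6 / uniquely mapped reads for the viewpoint. Smoothing is
a sliding 11-fragment median in genomic fragment order per chromosome,
with symmetric window shrinkage at ends (for per-replicate scaling,
median-then-scale and scale-then-median commute, so smoothing RPM values
is equivalent to normalizing smoothed counts). Replicates are merged by
per-fragment median; the viewpoint fragment ± 2 neighboring fragments are
masked (self-ligation region).

*Interaction calling.* Per side of the viewpoint, a line is fitted to
log(smoothed + ½) vs log(distance) (≥ 30 fragments per side required);
z = residual / (1.4826 × MAD of residuals); one-sided normal p; BH over
tested fragments; fragments with z > 3 and FDR < 0.05 within one fragment
of each other merge into regions, whose ± 2.5 kb neighborhood is
additionally summarized by a Stouffer-combined z. A log–log linear fit is
the simplest monotone surrogate for the reference tool's decay fit; it is
the component most likely to need replacement (e.g., isotonic regression)
for real data with plateaus or trans contacts.

*Sex comparison.* Per region, per-replicate RPM sums are compared between
sexes with a Welch t test on log2(RPM + ½) — depth-invariant and robust
with 3 replicates per sex; identical groups give p = 1 by a degenerate-tie
guard, and BH FDR is computed across tested regions (threshold 0.1). A
moment-based NB test would be unstable with the handful of regions
typically tested per viewpoint.

## Depletion response

FPKM = count × 1e9 / (length × total). Relative expression divides each
replicate by the gene's WT mean + 1e−6 (all-zero genes stay finite at 0;
the WT mean of ratios is 1 by construction). Eligible genes (FPKM > 1,
M/F > 3) are grouped proximal (< 20 kb from nearest male-biased DHS *and*
H3K27ac region), distal (> 20 kb from both), else neither; a relaxed mode
uses *either* for proximal. The contrast reports each gene's mean
depleted-replicate relative expression, group medians, and a two-tailed
Mann-Whitney p.

## Synthetic generators: what they emulate, and what they do not

The generators encode the study design this package targets: 4+4 CTCF and
3+3 cohesin ChIP replicates with ~4-fold planted sex effects at a subset
of CAC/CNC/Lone peaks; NB counts (variance = mean + 0.1·mean²) over a
uniform background tuned to a realistic FRiP of ~0.2; DpnII fragments with
geometric ~256-bp spacing; 4C libraries of 200,000 reads per replicate, 3
replicates per sex, 20-nt reading primer + 105-nt captured flank, a pure
power-law cis contact decay (exponent 1, offset 2 kb, 2% trans mass),
planted 5-fold focal interactions spanning ~2.5 kb blocks (three shared,
one female-only), and a junction fraction of 0.2 (0.3 in the rescue
check) with uniform 15–90-nt first segments; a 4+4 WT vs cohesin-depleted
expression design with lognormal noise σ = 0.2 and planted suppressions of
10-fold (distal) and 1.4-fold (proximal) — the magnitudes reported for
this contrast in the literature. Default toy genomes are 2 × 400 kb; the
expression genes live on an annotation-only virtual chromosome with
100-kb spacing so distance grouping is exact by construction.

Deliberately not modeled: sequencing errors and quality scores, PCR
duplication beyond the artifact-stack rule, mappability and GC biases,
chromatin-state heterogeneity, non-monotone contact structure (TAD
boundaries in the 4C background), and real motif degeneracy (planted
motifs are exact consensus embeddings, so motif recovery tests measure
scanner correctness, not weak-site sensitivity). Passing closed-loop tests
therefore demonstrates algorithmic correctness and calibration under the
stated model, not robustness to every artifact of real libraries.

## Problem sizes and runtime choices

Monte-Carlo sizes are chosen to make the checks statistically meaningful
at desk scale: 200 null replications × 2,000 windows for test calibration,
50 seeds for the end-to-end 4C and depletion recoveries in the test suite,
and 12 seeds in the acceptance script (whose quantities are rates over
72 planted interactions and ~37,000 fragment tests). The full test suite
runs in ~3 minutes on one CPU; the acceptance script in ~1 minute.
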