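# Methods

This note documents the models and procedures nestnet implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter when comparing
against other implementations.

## Expression preprocessing

Two low-expression filters serve the two analysis arms. The
differential-expression filter keeps a gene iff its total count is at least
one per sample (total ≥ n over n samples) **and** its zero-count samples do
not exceed one third of the stratum (stated for 30-sample strata as "zero in
more than 10 of 30 removed"). The co-expression filter removes a gene if its
zero-TPM samples exceed one third of any brain-region group (stated for
60-sample groups as "more than 20 of 60"). Both cutoffs scale
proportionally with stratum/group size, and the strict inequalities are kept
exactly: a gene at the boundary (zeros equal to the cutoff) is retained.
Filters are deterministic, idempotent, and order-stable.

Counts are normalized by median-of-ratios: the per-gene reference is the
geometric mean across samples over genes nonzero in every sample; each
sample's size factor is the median of count/reference over those genes.
This preserves between-gene rank order within each sample. log2(TPM + 1) is
the working scale for all network analyses; the pseudocount defaults to 1
and is configurable. PCA for sample-level QC uses log2(normalized count + 1)
as an approximate variance-stabilizing transform; a zero-variance input is
reported with an explicit degenerate flag rather than an arbitrary rotation.

## Co-expression network and modules

Gene-gene similarity defaults to the biweight midcorrelation with the
standard 9-MAD tuning constant; genes whose MAD is zero but variance is not
fall back to mean/SD centering, and constant genes yield correlation 0 with
a warning. Adjacency is signed-hybrid: `a_ij = max(cor_ij, 0)^β` with β = 6
and a zero diagonal, so anti-correlated genes are simply unconnected.
Topological overlap is the standard unsigned form
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
`TOM_ii = 1`.

Module detection is average-linkage hierarchical clustering on 1 − TOM with
a **static** cut (default height 0.99) and a minimum module size of 30;
smaller clusters are pooled into `unassigned`. This is a deliberate
simplification of dynamic tree cutting: it is deterministic, has one
interpretable parameter, and recovers planted modules reliably
(adjusted Rand index ≥ 0.9 in the recovery experiment). Its known
limitation is that a static height can trim part of a genuine module's
branch into `unassigned` at marginal seeds rather than adaptively following
branch shape; detected clusters remain pure in our experiments. Labels are
canonicalized (sorted by size, then smallest member id), making the
partition invariant to gene input order. An optional eigengene-correlation
merge step exists behind `merge_height` and is off by default.

Module eigengenes are the first right singular vector of the
gene-standardized module submatrix (unit-norm per-sample scores), with the
sign fixed so the mean gene-eigengene correlation is nonnegative; the
explained-variance fraction is reported. A single-gene module degenerates to
the standardized gene and is flagged. Module membership (MM) is the Pearson
correlation of a gene with the eigengene.

## Modular differential connectivity

`kwithin` follows its definition: the sum of a gene's Pearson correlations
with all other module genes within one group's samples (self-correlation
excluded; constant genes contribute 0 with a warning). MDC is the ratio of
summed kwithin, nesting over reference; a denominator below the floor
(default |Σ kwithin| ≥ 0.1) makes the MDC undefined — flagged, excluded
from classification, and reported.

The permutation P-values use the strict-inequality counting form
`p_gain = 1 − (1/M)·#{MDC_obs > MDC_p}` (and symmetrically for loss), with
M = 10,000 by default and an optional (+1)/(M+1) correction off by default.
Permutations whose denominator falls below the floor are dropped; if more
than 1% do, the test errors instead of reporting a misleading P. BH
adjustment is applied within each (stratum × comparison × direction) family
over its modules, configurable. Classification follows the published rule:
gain iff adjusted p_gain < 0.05 and MDC > 2; loss iff adjusted
p_loss < 0.05 and MDC < 0.5.

**Choice of the exchangeable unit.** Three permutation schemes are
implemented. `paired` swaps each gene's (kwithin_E, kwithin_ref) pair with
probability ½; `pooled` shuffles all 2G kwithin values; `samples` — the
default — permutes the group labels of the samples and recomputes the
summed kwithin on every split. The kwithin-value schemes are natural
readings of "permuting kwithin between groups", but both are strongly
anticonservative in exactly the regime this statistic targets: within a
co-expression module the per-gene kwithin values are highly correlated
(they share samples and a common latent factor), so value-level permutation
underestimates the null variance of the ratio. Measured on the exchangeable
null (both groups at within-module correlation 0.3, 50 genes, 10
samples/group), raw p_gain rejects at ~35% (paired) and ~39% (pooled)
versus 4–5% for sample-label permutation. Samples are the exchangeable unit
under the null hypothesis that both groups share one expression
distribution, so `samples` is the default; the other schemes remain
available for comparison. The sample-permutation inner loop uses the
identity Σ_offdiag cor = ‖Σ_g u_g‖² − G (u_g the unit-normalized centered
gene vectors), which makes M = 10,000 permutations of a 50-gene module a
~0.2 s computation.

**Power at the published thresholds.** The gain rule requires MDC > 2. A
module planted at within-group correlation 0.6 versus 0.3 has a population
connectivity ratio of exactly 2.0, i.e. it sits *on* the decision boundary;
at 10 samples/group the sampled MDC straddles 2 (median ≈ 2.1), so only
about half of such replicates are classified gain no matter how powerful the
P-value component is. Recovery approaches 1 once the planted ratio is
comfortably above 2 (e.g. 0.75 vs 0.3, ratio 2.5, as in the demo pipeline).
This is a property of the threshold rule at that effect size and sample
size, not of the test.

## Module-behavior correlation and hubs

NBF correlations are Pearson r between an eigengene (recomputed on the
E-group samples of a stratum, 10 samples in the reference design) and an
action frequency, with the two-sided P from the t distribution on n − 2 df.
P-values are reported raw at α = 0.05 — no multiplicity adjustment, matching
the analysis this mirrors; the calibration experiment confirms the ~5% null
rate at n = 10. Gene significance is the Pearson correlation of a gene with
a trait; binary state traits are coded 0/1 (point-biserial). The hub rule is
strict: |MM| > 0.8 and |GS| > the top-1% family quantile of |GS| (inclusive
empirical quantile with linear interpolation — the published constants 0.51
and 0.77 are the *outputs* of this rule on the original data, so the
quantile, not the constants, is the contract). Hub selection is monotone in
both thresholds.

## Over-representation

The category map assigns genes to neuron projection, in situ neurogenesis,
and other neurogenesis; the composite neurogenesis category is their union,
honoring the hierarchy rule that a neuron-projection gene also counts as a
neurogenesis gene but not conversely. The test is the one-tailed
(greater) Fisher exact test — implemented as the hypergeometric upper tail —
of a gene list against the expressed-gene background of the relevant region.
List-level results are reported unadjusted (α = 0.05); module-family scans
apply BH across modules within each category. Category construction from GO
term hierarchies is out of scope: the map is an input file, and the
generator produces synthetic ones.

## Behavior statistics

Frequencies are occurrence-seconds × 3600 / recorded-seconds, bounded by
[0, 3600] and robust to shortened recordings (normalization uses actual
recorded length; the reference design lost 4 minutes for one pair).
Mann–Whitney U tests are two-sided; with both groups at n ≤ 8 the P-value is
exact by full enumeration of all C(n+m, n) assignments with midrank tie
handling (the deviation-from-nm/2 two-sided definition), otherwise the
normal approximation with tie correction is used. Sidedness is not stated in
the source analysis; two-sided is the default. The BH family is all actions
× all three treatment pairs within a sex. Material-usage correlations are
Pearson with t-based P, with configurable pair exclusions (the reference
analysis excluded one pair whose material supply was refreshed).

## Synthetic generator

Each module has one latent standard-normal factor per (region, sex) stratum,
independent across strata (the analyses are stratified, so cross-stratum
correlation is irrelevant to them). Gene g of module m is
`loading_g(treatment) · f_m + N(0, noise_sd)` with
`loading = base_loading × multiplier[treatment]`, giving expected
within-module correlation `loading² / (loading² + noise_sd²)` — recorded per
module × treatment in the ground truth and verified to ±0.02 at n = 1000 in
the test suite. Latent values are emitted as `TPM = 2^(latent + 8) − 1`
(clipped at 0), a monotone map chosen so that the downstream log2(TPM + 1)
transform reproduces the latent scale essentially exactly while keeping the
TPM-zero filters exercisable; an optional dropout rate injects exact zeros.
Behavior frequencies in E samples are affine in the coupled module's factor
plus Gaussian noise, clipped to [0, 3600] seconds/hour; nonnesting samples
draw |N(0, 5)| near-zero frequencies. Category fixtures plant a chosen gene
list into a target category at a controlled rate over a background rate.

What the generator does **not** emulate: library-size variation and
count-level (negative binomial) noise, correlated modules, hub-and-spoke
within-module topology (all genes share one loading), trial effects, or
sex-specific expression differences. Passing tests therefore demonstrate
the statistical machinery — calibration, power at planted effect sizes,
oracle-exactness — not performance on real RNA-seq data, where filtering,
normalization quality, and module structure are harsher.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| soft power β | 6 | adjacency exponent, positive correlations only |
| correlation (network) | bicor | 9-MAD biweight midcorrelation |
| correlation (kwithin, MM, GS) | Pearson | as those quantities are defined |
| cut height | 0.99 | static cut on 1 − TOM |
| min module size | 30 | smaller clusters → unassigned |
| permutations M | 10,000 | P-value resolution 1/M; warning below 100 |
| permutation scheme | samples | see above; `paired`/`pooled` available |
| denominator floor | 0.1 | \|Σ kwithin\| below → MDC undefined |
| MDC thresholds | > 2 gain, < 0.5 loss | with BH-adjusted P < 0.05 |
| MM / GS hub rule | 0.8 / top-1% quantile | strict inequalities |
| log2 pseudocount | 1 | configurable |

Experiment problem sizes (500 null modules at M = 1000; 100 gain replicates;
2000 NBF null replicates; 200-gene recovery fixture) were chosen to keep
Monte-Carlo standard errors a few times smaller than the acceptance bands
they are compared against while remaining quick on a single CPU.

## Known limitations

- The static tree cut can shed part of a module at marginal seeds (purity is
  preserved; completeness is not guaranteed).
- The MDC permutation test assumes samples are exchangeable between groups
  under the null; trial pairing or batch structure would violate this and is
  not modeled.
- No dynamic tree cut, blockwise module construction, or scale-free-fit
  diagnostics; the network stage is not a drop-in replacement for the full
  reference WGCNA workflow.
- Differential-expression testing itself is out of scope; DEG lists are
  consumed as inputs to the enrichment stage.
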