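# Methods

## Scope and data model

`ribotome` analyzes paired IP/total RNA-seq count matrices from
cell-type-tagged ribosome affinity purification (Ribotag/TRAP) designs.
The canonical layout is four conditions (an uninjured baseline plus three
post-injury timepoints), three biological replicate pairs per condition
and two fractions per pair, i.e. 24 samples, with 15–20k detected genes.
Counts, sample sheets, gene sets and qPCR plates are plain TSV/GMT/YAML
throughout; gene identifiers are opaque strings.

## Normalization and filtering

Genes with fewer than 10 summed counts across all samples are removed
before any modelling (the conventional low-count pre-filter; the
threshold is the `min_count` option). Size factors are RLE
(median-of-ratios): reference genes are those with no zero count, each
sample's factor is the median ratio of its counts to the per-gene
geometric means, and factors are rescaled to geometric mean 1. The
estimator refuses to run when no zero-free gene exists rather than
silently switching to a pseudo-reference.

PCA is computed on `log2(normalized count + 1)`, gene-centered, with
samples as observations and an exact SVD (the randomized solver is
avoided for bit-reproducibility). This transform is a pragmatic choice;
a variance-stabilizing transform would give slightly different variance
fractions.

## The negative-binomial interaction model

Per gene, counts follow NB(mu, alpha) with `log mu = offset + X beta`,
offset the log size factor. The full design is
`intercept + pair(within condition) + condition + fraction +
fraction:condition`; the reduced design drops the interactions. Aliased
pair columns (the first pair of each condition, in input order) are
dropped deterministically and any remaining rank deficiency is an error
naming the aliased columns.

Fitting is iteratively reweighted least squares, vectorized across genes
(batched p x p solves), with at most 100 iterations and a relative
deviance tolerance of 1e-8; non-converged genes are flagged and their
p-values set missing rather than dropped. Coefficients, contrasts and
covariances are reported in log2 units. The coefficient covariance is
the inverse expected information.

### Dispersion estimation

The gene-wise estimate is the method-of-moments value
`(var − mean)/mean^2` on normalized counts, pooled across
fraction x condition cells by a df-weighted ratio of sums and floored at
1e-8. With three replicates per cell this raw estimate is far too noisy
for calibrated Wald inference, so by default it is moderated: a
parametric trend `alpha(mu) = a0 + a1/mu` is fitted by trimmed least
squares to informative gene-wise values, and log gene-wise estimates are
shrunk toward the log trend with weights given by the sampling variance
of a log-dispersion estimate at the design's residual df
(`trigamma(d/2)`) versus the robust prior spread of gene-wise values
around the trend (floored at 0.25). Genes more than two prior standard
deviations above the trend keep their gene-wise value (dispersion
outliers). `moderate=False` recovers the raw estimator.

### Test reference distributions

Because the plugged-in dispersion carries finite information, Wald
statistics are compared against a Student-t reference with
`df = residual df + prior df`, where the prior df is the value whose
`trigamma(df/2)` equals the estimated prior variance — the moderated-t
construction. The LRT uses the matching moderated-F reference
(`F(df_interaction, df_moderated)`), which tends to the chi-square as
replication grows. With moderation disabled the normal and chi-square
references are used. On global-null simulations (5,000 genes, 24
samples) this keeps the Wald p-value distribution KS-uniform and the
q < 0.05 rejection fraction at ~0; with plain normal references the same
data give visibly anticonservative tails.

### Paired versus unpaired contrasts

Pair effects make the IP/total enrichment and differential-enrichment
contrasts within-pair comparisons, removing tissue-level baseline
variation — that is what pairing is for. But with pairs nested in
condition, condition main effects would be identified only through each
condition's reference pair, roughly doubling their error and producing
unstable estimates for low-count genes. Condition contrasts
(injury-vs-baseline within either fraction) are therefore taken from the
same model refit without pair columns, while enrichment and interaction
contrasts keep the paired fit. `pair_term=False` collapses everything
onto the unpaired fit.

## Enrichment profile and decision rules

All thresholds are log2-scale and bundled in `Thresholds`: enrichment
0.5, high specificity 2.0, DEG call 1.0, differential enrichment 1.0,
arm-2 enrichment 1.0, q 0.05. Classification: enriched if
`Log2FC(Total) > 0.5` at q < 0.05, highly specific if additionally > 2,
depleted if < −0.5, else neutral (strict inequalities). Raw injury DEGs
are IP-fraction calls at |log2FC| > 1, q < 0.05, per direction.

The two-arm filter accepts a raw call as high-confidence when either

1. arm 1 — the differential-enrichment Wald contrast satisfies
   |dLog2FC| > 1 at q < 0.05 *and* its sign matches the call direction
   (sign agreement is how "same direction/magnitude" is
   operationalized: it keeps cell-type-driven changes and rejects calls
   whose IP change merely mirrors a total-RNA change); or
2. arm 2 — the gene is constitutively enriched, `Log2FC(Total) > 1` at
   q < 0.05 in the baseline *and* the focal timepoint. Requiring the two
   relevant conditions rather than all four matches the per-timepoint
   framing of the filtration; a stricter all-timepoints variant is a
   one-line change on the profile tables.

The differential-enrichment q comes from the per-timepoint Wald
contrast; the gene-level LRT can additionally be required for arm 1
(`lrt_screen=True`, default off). Acute-phase candidates are
high-confidence acute up-calls whose late response is either not a
significant upregulation (q ≥ 0.05 or log2FC ≤ 1) or at least two-fold
(1 log2 unit) below the acute response. Gene-set regulation summaries
count set members past ±0.5 log2 at q < 0.05 and report the median
log2FC of the regulated subset; unmapped members are reported, never an
error.

Known sensitivity cost: genes with an intermediate share of their total
abundance coming from the tagged cell type can fail both arms — their
total-RNA signal rises enough to pull |dLog2FC| under 1 while their
baseline enrichment sits under the arm-2 cut. On synthetic data this
loses roughly 5–15% of genuinely regulated genes; the trade is
deliberate and mirrors the conservative intent of the filter.

## Gene-set statistics

Marker-overlap diagnostics use the exact hypergeometric upper tail
(`P(X ≥ k)`) and the representation factor `k / (n1 n2 / N)`; the
contamination panel runs one test per (DEG list, cell-type marker set),
BH-adjusts across the panel and flags cell types with RF > 1 at
q < 0.05. The universe defaults to all genes surviving the count filter
and is always written out explicitly.

Operon overlaps are scored as `z = (k_obs − null_mean)/null_sd` over R
random subsets of the expressed universe matching the query size.
R = 10 follows common practice but is fragile: the tool warns below
R = 100 and always reports the analytic hypergeometric moments
(mean `nK/N`, variance `nK(N−K)(N−n)/(N^2(N−1))`) plus both the
sample-sd (R−1, used in z) and population-sd versions, since the
convention is ambiguous.

## qPCR quantification

ddCT with multiple references: technical replicates are averaged on the
Ct scale, `dCt = Ct_target − mean(Ct_refs)` per sample (arithmetic mean
of Ct = geometric mean of expression; the three references are weighted
equally), `ddCt = dCt_IP − dCt_total`, fold = `2^−ddCt`. Undetected
wells make the fold missing with a reason, never silently zero. Group
comparisons use the two-tailed Mann–Whitney U test; while
`n1*n2 ≤ 400` the two-sided p is exact — the permutation distribution of
the mid-rank sum over the observed pooled values is computed by
subset-sum dynamic programming (doubled ranks keep sums integral under
ties) and `p = 2·min(P(≤), P(≥))` capped at 1 — otherwise the
tie-corrected normal approximation is used.

## The synthetic experiment generator

The generator emulates the study design rather than read-level
artifacts. Per cell type, relative expression profiles are lognormal
(shared gene abundance times an independent per-type factor); marker
genes are skewed toward their type by a uniform 10–50x factor, which
guarantees the ≥ 8-fold marker property by construction; three reference
genes are pinned to exactly equal shares in every type (the housekeeping
property ddCT relies on). The total-fraction expectation is the
mixture-proportion-weighted sum of effect-modulated profiles; the IP
expectation is `purity x (OL pool) + (1 − purity) x (total pool)` —
ambient admixture proportional to total-RNA composition, the mechanism
that reproduces the real contamination signature (IP changes driven by
total changes with unchanged depletion). Counts are NB draws at
per-sample lognormal library sizes; a single generator seeded from the
config drives every draw.

Defaults (the simulated study conditions): 16,000 genes; 4 conditions x
3 pairs x 2 fractions; mixture with OLs at 20% of the baseline pool and
a microglial surge at dpi2 (35% of the pool); IP purity 0.90 / 0.75 /
0.85 / 0.90 across naive/dpi2/dpi10/dpi42 (25% acute admixture); library
size mean 4e6, CV 0.15; NB dispersion gamma(2, 0.01) (mean 0.02 —
replicates are pools of animals, which suppresses biological
variability); 300 OL-regulated genes with log2 effects from
{±1, ±1.5, ±2, ±2.5, ±3} in balanced acute / decaying / sustained
temporal patterns; 200 genes regulated identically in all cell types;
150 microglial "inflammatory" genes surging 3 log2 units in their cell
type at dpi2. Regulated genes are drawn only from transcripts detectably
expressed in the OL pool (≥ 0.25x the mean relative expression) — an
OL-specific effect on a gene OLs barely express is biologically
meaningless and statistically unestimable. The first operon set is
seeded with planted acutely-upregulated genes (hit rate 0.45), emulating
a de-silenced repressive-complex target set; the others are uniform
draws.

What the generator does *not* emulate — and hence what passing tests do
not certify on real data: read-level noise (mapping, duplication, GC),
gene length and isoform structure, correlated gene programs,
batch/lane effects, pair-level biological baselines (pairs share only a
library-size draw), sex effects, and secondary contamination routes
(e.g. adjacent-tissue cell types). The contamination model is purely
ambient-proportional.

Validation scenarios (`ribotome.scenarios`) fix three configurations:
the global null (no effects, constant mixture, pure IP) for calibration;
a recovery scenario (planted ±1/±2, 200 genes each, pure IP) measuring
estimator bias and RMSE in isolation — admixture attenuation is a
property of the contamination scenario, not of the estimator — and the
default contamination scenario (desk-scale 12,000 genes) for filter
performance. Problem sizes (5,000-gene calibration/recovery runs,
12,000-gene contamination runs, R = 10^4 resampling checks) are chosen
so the full validation completes in well under a minute on one core
while keeping Monte-Carlo error far below the decision margins.

## Numerical and degenerate-input choices

IRLS linear predictors are clipped at ±30 (natural log) to survive
all-zero cells; a 1e-10 ridge stabilizes the information solves; the
dispersion floor is 1e-8, below which draws and likelihoods use the
Poisson limit. BH leaves missing p-values missing. Negative LRT
statistics (possible only through convergence failure) are clipped to
zero with a warning. The degenerate all-zero contrast is rejected, as
are non-nested LRT designs and fits with mismatched dispersions. Empty
DEG lists, empty gene sets and panels with zero overlaps all produce
well-formed zero-count outputs rather than errors.

## Reproducibility

Every stochastic component takes an explicit seed; the pipeline manifest
records seed, thresholds, package versions and a sha256 per artifact.
Result tables are written with a fixed float format, so identical config
and seed produce byte-identical files (verified in the test suite and
the acceptance script).
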