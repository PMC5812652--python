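# Methods

## Scope and data model

The package analyzes bulk RNA-seq of whole animals systemically challenged
with a panel of bacteria. The canonical design it targets (and that the
simulator reproduces) is: 10 live bacteria — 3 with Lys-type peptidoglycan
(Gram-positive: Ml, Ef, Sa) and 7 with DAP-type (Gram-negative: Ec, Sm,
Ecc15, Pr, Ps, Db11, Pe) — plus an unchallenged control (UC), a sterile
wound (SW), and two heat-killed inocula (EfHK, PrHK), sampled at 12, 36 and
132 h post-challenge with 3 replicates. The four high-virulence bacteria
(Sa, Ps, Db11, Pe) kill their hosts early and are sampled at 12 h only. The
nine UC samples (3 per timepoint) are collapsed into a single control pool;
every (condition, timepoint) group — live, wound, or heat-killed — is
contrasted against that same pool. Nothing in the code is specific to this
panel: conditions, PGN labels, virulence classes and timepoints come from
the sample sheet.

## Normalization

Within-sample scaling uses counts per million (CPM). Genes with CPM < 1.2
in more than *n* − `min_samples` samples are removed before testing;
`min_samples` defaults to the smallest replicate-group size, so a gene
expressed in one complete replicate group survives. The published text this
follows does not say whether the filter was per-sample or on the average
CPM; the per-sample rule was chosen because it is the stricter and more
common reading, and `min_samples` is exposed for users who prefer another.

Between-sample factors are trimmed means of M-values (TMM). The reference
sample is the one whose 75th-percentile CPM is closest to the mean of those
percentiles (ties to the first sample). For sample *k* vs reference *r*,
over genes positive in both and with y < N:

    M_g = log2((y_gk/N_k)/(y_gr/N_r))
    A_g = 0.5*log2((y_gk/N_k)*(y_gr/N_r))
    w_g = (N_k - y_gk)/(N_k*y_gk) + (N_r - y_gr)/(N_r*y_gr)

The top and bottom 30% of genes by M and 5% by A are discarded (the
method's standard trim fractions) and log2 f_k is the 1/w-weighted mean of
the surviving M values; factors are rescaled to geometric mean 1. If fewer
than 10 genes survive trimming the factor falls back to 1 with a warning.
Note one subtlety: multiplying a sample's counts by a constant leaves every
M-value (and hence composition correction) unchanged, but the precision
weights 1/y − 1/N shift with depth, so that sample's own factor can move by
a few percent; the factors of all other samples are exactly unchanged
relative to one another.

## Differential expression

Counts are modeled as negative binomial with variance mu + phi*mu^2.

**Dispersion.** Within each replicate group (each contrast's treatment
samples and the control pool), counts are scaled to the group's
geometric-mean effective library; the moment estimate (v − m)/m² from the
group mean m and unbiased variance v is pooled across groups weighted by
degrees of freedom and floored at 0. Per-gene estimates are shrunk toward a
common value: phi_g = 0.3*phi_hat_g + 0.7*phi_common. The common value is
the across-gene **mean** of the moment estimates, not the median: at 2–8
degrees of freedom the moment estimator is strongly right-skewed, so the
median sits ~10% below the true dispersion (measured on simulated NB data
at phi = 0.2) and using it as the shrinkage target makes the exact test
anti-conservative; the mean is nearly unbiased. The median is retained in
the returned estimates as a diagnostic.

**Exact test.** Counts of both groups are rescaled to the geometric mean of
their effective library sizes (real-valued "pseudo-count" scaling, group
sums rounded to integers so the conditional lattice is well defined). Group
sums of n i.i.d. NB(mu, phi) variables are NB(n*mu, phi/n); conditioning on
the total s, the two-sided p-value is the summed conditional probability of
all splits (t, s − t) whose probability is ≤ that of the observed split
(ties included, relative tolerance 1e−12), capped at 1. At phi = 0 this
reduces exactly to the conditional binomial (Poisson) test. Conditional
weights are computed by the pmf-ratio recurrence
NB(t+1)/NB(t) = (t+r)q/(t+1) over a window of ±12 unconditional SDs around
the expected split, always extended to include the observed split; the
neglected tail mass is below ~1e−25 of the distribution, far beyond the
precision of any reported p-value, and the window covers the entire range
for small totals. This keeps the ~62,000 gene × contrast tests of a full
experiment to seconds.

**Calling.** Benjamini–Hochberg step-up adjustment is applied within each
contrast (the correction family is not stated in the source analysis; per
contrast matches per-condition DE counting downstream). A gene is DE when
q < fdr (strict; default 0.05) with **no fold-change cutoff**; fdr = 0.1
reproduces the relaxed-threshold sensitivity analysis. Displayed log2 fold
changes use prior-count-damped (0.5) normalized group means; the prior
affects display only, never the test.

## Core, unique, and partition sets

A bacterium supports a gene if the gene is DE for it at ≥ 1 timepoint; the
per-bacterium direction is the log2FC sign at the smallest-q timepoint
(ties to the earliest — arbitrary but deterministic). The **core** at
cutoff c (default 7 of 10) is all genes with support ≥ c; direction is
up/down when a strict majority of supporting bacteria agree, else the gene
is flagged *discordant* rather than dropped (the source reports up and down
cores but never defines mixed-direction handling). Core sets nest by
construction: cutoff c+1 ⊆ cutoff c.

**Unique genes** respond to exactly one of the live bacteria across all
timepoints; heat-killed and wound conditions do not count toward
uniqueness (they are reported as separate response sets). The **Gram/PGN
partition** splits responding genes into Lys-only / DAP-only / both by the
PGN labels of their supporting bacteria; within each exclusive set, the
stricter "all members, consistent direction" subsets are also reported.
Control overlaps are the 7 Venn cells of (core, wound-responsive,
heat-killed-responsive) plus pairwise overlaps with any external gene
list. The 20%-rule annotation (|mutant − wildtype| / wildtype ≥ 0.20)
flags pathway-regulated genes given wildtype and pathway-mutant expression
levels; non-positive wildtype levels are marked unevaluable.

## Trajectory kinetics

Only conditions observed at all three timepoints are classified. Per gene ×
condition: genes significantly induced at one early timepoint (12/36 h) and
significantly repressed at the other (or vice versa) are excluded as
sign-flips — in the simulator these are planted at 1% of genes. Genes never
DE are nonresponsive. A gene DE early but not at 132 h has **recovered**
(loss of significance only; the point estimate is not additionally required
to shrink, per the definition adopted). Otherwise the recovery ratio
r = log2FC(132 h)/peak is computed, where the peak is the early log2FC of
largest magnitude in the gene's overall direction (max for up, min for
down, direction taken from the early DE call with the larger |log2FC|):
r ≥ 1.25 → *continued*, 0.75 ≤ r < 1.25 → *plateau*, r < 0.75 →
*partial* (still DE late but well below peak). The thresholds bracket the
three pictured trajectory archetypes — recovered scales the planted effect
by (1, 0.5, 0) across timepoints, plateau by (1, 1, 1), continued by
(1, 1.5, 2), whose true late/peak ratios are 0, 1 and 4/3 — and *partial*
makes the label set exhaustive. The rare gene DE only at 132 h has no early
peak and is labeled continued (its expression is still departing from
baseline at the last observation). The per-condition recovery percentage is
100 × recovered / (early-responsive and not sign-flip).

## Ordination

PCA runs on replicate-level samples of log2(TMM-normalized CPM + 1),
per-gene centered, unscaled (the source does not state its transform;
replicate-level log-CPM is the conventional choice and the prior is
configurable). Scores and loadings come from the SVD of the centered
matrix; variance fractions are sigma_i^2 / sum(sigma^2). Each loading
column's largest-magnitude element is made positive, so outputs are
deterministic across platforms. Top contributing genes per component are
ranked by |loading| with ties broken by input gene order.

## Motif scanning and enrichment

Promoters are scanned for an exact IUPAC-consensus match (default
TGCCACGT) at every offset, on both strands; overlapping matches count
individually, and when a match and its reverse complement occupy identical
coordinates (palindromes) only the plus-strand hit is reported. Consensus
matching is used instead of PWM log-odds because the motif is published as
a consensus string; a PWM threshold would require invented numbers. An `N`
in the motif matches any base; an `N` in the sequence matches nothing else.
Enrichment of motif-bearing genes in a target set uses the upper-tail
hypergeometric test. For i.i.d. background with GC content g, the expected
both-strand hit count per promoter is 2(L − m + 1)·prod p(base), the
closed form the simulator's background rate is validated against.

## Synthetic data: what it emulates and what it does not

The generator plants known structure on top of NB noise:

| parameter | default | rationale |
|---|---|---|
| n_genes | 2,000 | statistics are per-gene and scale-free; keeps tests in seconds |
| lib_size mean, CV | 2×10⁶, 0.1 | moderate depth; mean count ≈ 10³/gene |
| baseline log-abundance | Normal(0, 1.0), natural log | ~30-fold abundance spread between ±1.7 SD genes |
| dispersion phi_g | 0.01 + 2/mu_g | BCV ≈ 0.1 at high expression — realistic for pooled samples of inbred animals — with the usual low-count uptick |
| class fractions | core_up 6%, core_down 3%, unique 10%, wound 2%, heat-killed 2%, signflip 1% | ≈2:1 up:down core split as observed in fly infection data; 1% sign-flips per the published exclusion rate; fractions large enough for stable Monte-Carlo scoring |
| core_support | 8 | a core gene responds to 8 of 10 bacteria |
| lfc_magnitude | 2.0 | strong but realistic infection response |
| trajectory mix | recovered 0.5, plateau 0.25, continued 0.25 | at least half of responding genes recover, as reported for these infections |

Planted log2 fold changes act on expected proportions before depth scaling,
so library-size variation is orthogonal to effects. Unique genes are
assigned round-robin across bacteria; wound/heat-killed genes respond only
in their control conditions; sign-flip genes respond +lfc at 12 h and −lfc
at 36 h in 3 full-course bacteria.

Deliberately **not** modeled: read-level effects (the generator draws
counts, not reads), 3′ bias, batch effects, correlated genes, wound
responses embedded within live infections, and bacteria-specific response
magnitudes. Passing the recovery benchmarks therefore demonstrates that the
pipeline's statistics and set logic are correct under the NB model and this
design — not that biological confounders of real experiments are handled.

## Numerical choices and degenerate inputs

- Exact-test ties included with relative tolerance 1e−12; p capped at 1;
  total s = 0 gives p = 1.
- TMM factor geometric-mean-1 constraint asserted to 1e−9; all-zero
  matrices and zero libraries are rejected with errors.
- Dispersion floor at 0 applied after pooling across groups; groups with
  zero mean contribute nothing.
- BH is the standard step-up with stable sorting; input p outside [0, 1]
  is an error.
- Tie-breaks are deterministic everywhere (first-in-canonical-order for
  reference choice, earliest timepoint for direction, input gene order for
  loading ranks), so a fixed seed yields byte-identical outputs.
- Benchmark problem sizes (4,000-gene null, 2,000-gene power and pipeline
  runs, 500 × 4 kb promoters, 3 seeds) were chosen as the package's
  standard validation suite; each completes in seconds to ~1 minute.

## Known limitations

- The exact test assumes a common dispersion per gene across groups and
  exchangeability after library rescaling; strong mean-dispersion trends
  within a gene's groups are not modeled.
- Moment dispersion estimation is noisy at 3 replicates; the 0.7 shrinkage
  makes per-gene tests borrow heavily from the experiment-wide mean, which
  can under-correct genuinely hyper-variable genes.
- BH within contrast controls FDR per contrast, not study-wide.
- Recovery classification trusts DE flags; a gene hovering at the
  significance boundary at 132 h can oscillate between recovered and
  partial.
- Consensus motif matching has no mismatch tolerance; degenerate
  regulatory elements are underdetected relative to PWM scoring.
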