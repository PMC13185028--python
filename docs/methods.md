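# Methods

## Screen design assumed by the package

The library targets ~1,551 genes with exactly one sgRNA per gene in each of
two sets (SET1, SET2; two guides per gene total) plus a panel of safe-harbor
control guides (default 100) cutting phenotypically neutral loci. Safe harbors
are carried under the pseudo-gene `SAFE_HARBOR` in a `CONTROL` set; they are
used for normalization and as the empirical null, and are never eligible for
gene-level calls. Designs are unbalanced by default: 3 baseline vs 2 late
samples for time-course contrasts, 4 control vs 2 treated for chemical
contrasts. Group labels for a contrast are the sample's timepoint when
present, else its condition.

## Quantification

Reads are assigned by exact spacer matching: offsets `o_min..o_max`
(default 0..30, 0-based, substring `[o, o+L)`) are scanned in increasing
order and the first hit wins; when reverse-complement scanning is enabled the
forward scan completes first, and a read hitting distinct guides in the two
orientations is `AMBIGUOUS`. No mismatch tolerance, trimming, or quality use —
counting is sequence-identity based, and the conservation invariant
`mapped + unmapped + ambiguous = reads` holds for every input. Reads shorter
than `o_min + L` are unmapped, not errors; malformed FASTQ records raise an
error carrying the offending line number.

## Differential selection

Counts are modeled as `K_ij ~ NB(s_j q_ig, alpha_i)`.

**Size factors.** Median-of-ratios restricted to safe-harbor guides with
strictly positive counts in every sample (controls containing zeros are
excluded; below 20 usable controls a warning is recorded, with an error only
when none is usable). Note the estimator is ratio-equivariant, not
scale-equivariant: multiplying one sample by `c` multiplies the *ratio* of its
factor to any other sample's by exactly `c`, while the factors themselves
move by `c^(1-1/n)` and `c^(-1/n)`.

**Dispersion.** Three stages, empirical-Bayes in structure:

1. *Gene-wise*: maximize the Cox–Reid adjusted profile likelihood
   (`-0.5 log det(X'WX)`, which for a group design factors into per-group
   sums of the GLM weights `mu/(1+alpha*mu)`) over `alpha` in
   `[1e-8, 10]`, with group means profiled out by Newton iteration in
   `log q`. The adjustment matters: the unadjusted MLE at 3-vs-2 replicates
   is biased low enough to visibly break Wald calibration. Optimization is a
   coarse log-grid (36 points) plus two local refinements (~1% resolution),
   vectorized across all guides.
2. *Trend*: `alpha(mu) = a1/mu + a0` fit by bounded least squares on the log
   scale, with an explicit bias correction `psi(df/2) − log(df/2)` (df =
   samples − groups) because the log of a chi-square-like dispersion estimate
   is median-biased low; points off the trend by a ratio outside
   `[1e-4, 15]` are excluded iteratively. Fewer than 10 usable guides falls
   back to a constant (debiased median) trend with a warning.
3. *Final (MAP)*: maximize adjusted likelihood plus a normal prior on
   `log alpha` centered at the trend, prior variance
   `max(var(log alpha_hat / trend) − trigamma(df/2), 0.25)`. Gene-wise
   estimates more than `2 s_lr` above the trend (log residual spread) are
   kept unshrunk: that far out, the excess is real extra variability and
   shrinking it would inflate the test statistic.

**Wald test.** The two-group NB regression with offsets `log s_j` has a
separable MLE (per-group means), so `log2FC = log2(q_B/q_A)` exactly; the SE
comes from observed Fisher information (`Var(beta_1) = 1/sum_A w + 1/sum_B w`
with `w_j = (K_j + 1/alpha) alpha m_j / (1+alpha m_j)^2`). Because the
plugged-in dispersion is itself an estimate, `z = log2FC/SE` is referred to a
**moderated t** distribution with
`df = (samples − groups) + d0`, where the prior's information content `d0`
solves `trigamma(d0/2) = sigma_prior^2` (the quasi-likelihood view of the
dispersion prior). With a normal reference, pure-null screens at this design
show ~2x too many p-values below 1e-3 and the gene-level false discovery rate
exceeds its nominal target even when the true dispersion is supplied; the
moderated t restores calibration (measured KS distance to uniform ≤ 0.04
across seeds) at no cost in power at these effect sizes. A group with
complete dropout receives a half-count abundance floor so the (large) fold
change stays finite. Guides with all-zero counts in both groups are untested
and can never become hits. Safe harbors are tested and included in the BH
family — the null and test families stay consistent — and excluded only at
gene calling. SET1 and SET2 form one joint family per comparison.

**FDR.** Benjamini–Hochberg over the tested guides of the comparison
(statsmodels implementation; the direct step-up formula is the oracle in the
test suite).

## Empirical null and calling

Per comparison, the lower/upper effect-size cutoffs are the
`(1−mass)/2` and `1−(1−mass)/2` quantiles (default mass 0.95 → 2.5%/97.5%) of
the *tested* safe-harbor log2FC values, using linear interpolation between
order statistics (type 7 — fixed so cutoffs are bit-reproducible); at least
20 tested controls are required. Cutoffs are recomputed for every comparison,
never reused. A guide is DEPLETED iff `FDR < 0.05` and `log2FC < lower`
(ENRICHED symmetrically), both strict. Genes follow the
at-least-one-of-two-guides rule; the gene-level log2FC is that of the
supporting guide with the largest |log2FC| (the representative printed per
gene per timepoint), and opposite significant guides yield `DISCORDANT`,
reported but excluded from downstream counts.

## Time-course classification

Exactly two time points against a shared baseline. TDE requires DEPLETED at
both and `lfc_t2 ≤ lfc_t1`; TDGI requires ENRICHED at both and
`lfc_t2 ≥ lfc_t1`. Monotonicity is non-strict because published classifications
include exact ties, and it is evaluated on the gene-level representative
log2FC (not per guide). TDE and TDGI are mutually exclusive by construction.

## Simulator

The generator reproduces the count-generating structure the analysis assumes,
with defaults at the study design: 1,551 genes, 100 safe harbors, 500
cells/guide at the founder bottleneck, 5e6 expected reads/sample, log-normal
baseline abundances (sdlog 0.8), NB dispersion 0.05, 3-vs-2 replicates.
Pipeline: log-normal pre-bottleneck proportions → one multinomial founder
draw of `coverage × n_guides` cells **shared by all samples** (one transduced
pool split into arms) → multiplicative `2^effect` selection on the late
group's abundances → per-sample Poisson depth and gamma-Poisson counts. The
dispersion default 0.05 is a stated assumption (no empirical estimate exists
for this design), and selection is collapsed into a single epoch so a gene's
true effect *is* a log2FC — growth over multiple doublings is absorbed into
the effect size. Seeds are mandatory; identical configs and seeds give
identical matrices.

What it does not emulate: PCR jackpotting and amplification bias, guide-
specific cutting efficiency, off-target effects, cell-line heterogeneity or
3D-specific biology (gradients, contact inhibition), and between-replicate
founder divergence (the shared founder makes bottleneck noise common-mode —
so passing recovery tests says the *inference* is sound under the assumed
noise model, not that real screens meet that model).

`simulate_reads` emits exactly `count_i` reads per guide with the spacer at a
uniform random offset, random flanks and constant quality, so quantification
can be validated by exact round trip.

## Overlap statistics

`overlap_test` is a one-sided (enrichment) hypergeometric tail,
`P(X ≥ n_overlap)`, with the universe defaulting to the library's gene set —
a screen can only call library genes, and a genome-wide universe would
inflate significance. External gene lists are plain text, one symbol per line.

## Numerical choices and problem sizes

* Dispersion bounds `[1e-8, 10]`; grid + refinement resolution ~1% in
  `log alpha`; Newton steps clipped to ±3 with 40-iteration cap.
* Strict inequalities everywhere the calling rule is applied.
* Untested propagates as NaN + `tested=False`, never as a silent zero.
* Count files are TSV with `#unmapped`/`#ambiguous` header comments so round
  trips are byte-stable; no scientific notation.
* The test suite and the acceptance script run the full default design
  (3,202 guides × 5 samples): ten pure-null screens for calibration, five
  spiked screens (50 genes at −2, 50 at +2) for recovery, smaller fixtures
  elsewhere; a full screen analysis takes about one second, the whole suite
  under a minute.

## Known limitations

* Two-group contrasts only: no multi-factor designs, covariates, or
  likelihood-ratio tests.
* Exactly two time points; more would need a monotonicity policy the
  classifier does not define.
* No outlier-count handling (Cook's-style) or independent filtering; with two
  guides per gene every guide is kept and conflicts surface as DISCORDANT.
* Exact matching only; reads whose spacer is mutated or truncated are lost to
  `unmapped` rather than rescued.
* The empirical null needs enough safe harbors (≥20 tested) to make tail
  quantiles meaningful; below ~50 the cutoffs themselves are noisy, and the
  band coverage guarantee is only `mass − 2/n`.
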